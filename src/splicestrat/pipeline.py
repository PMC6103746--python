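"""End-to-end orchestration: simulate/read -> CSS -> classify -> insolubility
-> differential splicing -> clinical association, with a machine-readable
report.

Stages communicate only through files in the output directory, so any stage
can be re-run on real data files of the same format.  Stages whose inputs
are absent are skipped and noted in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clinical, diffsplice, insolubility, splicing
from . import io as sio
from .simulate import DEFAULT_EXON_PANEL, SimConfig, simulate_cohort, write_cohort

__version__ = "0.1.0"


@dataclass
class RunReport:
    """Summary of one pipeline run; every number is recomputable from the
    stage output files listed in ``outputs``."""

    config: dict
    seed: int | None
    outputs: dict[str, str] = field(default_factory=dict)
    stages_run: list[str] = field(default_factory=list)
    stages_skipped: dict[str, str] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "outputs": self.outputs,
            "stages_run": self.stages_run,
            "stages_skipped": self.stages_skipped,
            "summary": self.summary,
        }


def _validate_thresholds(cfg: dict) -> None:
    checks = {
        "fdr": (0.0, 1.0),
        "dpsi": (0.0, 1.0),
        "k_sd": (0.0, 100.0),
        "ds_threshold": (0.0, 1.0),
    }
    for key, (lo, hi) in checks.items():
        if key in cfg and not (lo <= float(cfg[key]) <= hi):
            raise ValueError(f"config: {key}={cfg[key]} outside [{lo}, {hi}]")
    for key in ("min_cluster_reads", "max_intron_len", "min_sample_reads", "min_exons"):
        if key in cfg and int(cfg[key]) < 0:
            raise ValueError(f"config: {key} must be >= 0")


def run_all(config: dict | str | Path) -> RunReport:
    """Run every applicable stage; see the module docstring for the order.

    ``config`` is a dict or a YAML path.  Keys: ``out_dir`` (required),
    ``simulate`` (SimConfig overrides; triggers cohort generation) or
    ``inputs`` (paths: clinical, psi, densitometry, junctions), plus
    thresholds ``k_sd`` (3), ``min_exons`` (10), ``fdr`` (0.1), ``dpsi``
    (0.1), ``min_cluster_reads`` (50), ``max_intron_len`` (500000),
    ``min_sample_reads`` (10), ``ds_threshold`` (0.5), ``psi_scale``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    _validate_thresholds(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed")
    report = RunReport(config=cfg, seed=seed)

    # --- stage 0: obtain inputs -------------------------------------------
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        if seed is not None:
            sim_kwargs.setdefault("seed", int(seed))
        cohort = simulate_cohort(SimConfig(**sim_kwargs))
        inputs_dir = out_dir / "inputs"
        paths = write_cohort(cohort, inputs_dir, force=True)
        inputs = {
            "clinical": paths["clinical"],
            "psi": paths["psi"],
            "densitometry": paths["densitometry"],
            "junctions": paths["junctions"],
        }
        cfg.setdefault("psi_scale", "fraction")
        report.stages_run.append("simulate")
        report.outputs["inputs"] = str(inputs_dir)
    else:
        inputs = {k: Path(v) for k, v in cfg.get("inputs", {}).items()}
        if "clinical" not in inputs or "psi" not in inputs:
            raise ValueError("config must provide a simulate block or clinical+psi inputs")

    metadata = sio.read_clinical(inputs["clinical"])
    annotation = DEFAULT_EXON_PANEL
    measurements = sio.read_psi_table(
        inputs["psi"], annotation, scale=cfg.get("psi_scale", "percent")
    )

    # --- stage 1: CSS and classification ----------------------------------
    matrix = splicing.build_psi_matrix(measurements, annotation)
    css = splicing.compute_css(matrix, min_exons=int(cfg.get("min_exons", 10)))
    labels = splicing.classify_patients(
        css["css"], metadata, k=float(cfg.get("k_sd", 3.0))
    )
    sio.write_table(
        labels.reset_index(),
        out_dir / "css_scores.tsv",
        percent_columns=["css", "cutoff", "control_mean", "control_sd"],
    )
    report.outputs["css_scores"] = str(out_dir / "css_scores.tsv")
    tests = splicing.group_compare(matrix, labels, alpha=float(cfg.get("alpha", 0.05)))
    sio.write_table(
        tests.reset_index(),
        out_dir / "exon_group_tests.tsv",
        percent_columns=["mean_like_control", "mean_like_c9"],
    )
    report.outputs["exon_group_tests"] = str(out_dir / "exon_group_tests.tsv")
    report.stages_run += ["css", "classify"]
    counts = labels["label"].value_counts().to_dict()
    rve = splicing.repressed_vs_enhanced_fit(matrix)
    report.summary["classification"] = {
        "n_per_label": {k: int(v) for k, v in sorted(counts.items())},
        "cutoff": float(labels["cutoff"].iloc[0]),
        "control_mean": float(labels["control_mean"].iloc[0]),
        "control_sd": float(labels["control_sd"].iloc[0]),
        "repressed_vs_enhanced_slope": rve.slope,
        "repressed_vs_enhanced_r2": rve.r_squared,
    }

    # --- stage 2: insolubility ---------------------------------------------
    ds_groups = None
    ins_matrix = None
    dens_path = inputs.get("densitometry")
    if dens_path and Path(dens_path).exists():
        records = sio.read_densitometry(dens_path)
        ins_matrix = insolubility.build_insolubility_matrix(records, "g180k", metadata)
        ins_21k = insolubility.build_insolubility_matrix(records, "g21k", metadata)
        sio.write_table(
            ins_matrix.values.reset_index(),
            out_dir / "insolubility.tsv",
            percent_columns=list(ins_matrix.values.columns),
        )
        spearman = insolubility.pairwise_spearman({"g180k": ins_matrix, "g21k": ins_21k})
        spearman.index.name = "feature"
        sio.write_table(spearman.reset_index(), out_dir / "pairwise_spearman.tsv", sort_by=[])
        ds_groups = insolubility.assign_ds_groups(
            ins_matrix.values.get("hnRNPH", pd.Series(dtype=float)),
            metadata,
            threshold=float(cfg.get("ds_threshold", 0.5)),
        )
        sio.write_table(
            ds_groups.reset_index(), out_dir / "ds_groups.tsv",
            percent_columns=["hnrnph_insoluble"],
        )
        report.outputs.update(
            {
                "insolubility": str(out_dir / "insolubility.tsv"),
                "pairwise_spearman": str(out_dir / "pairwise_spearman.tsv"),
                "ds_groups": str(out_dir / "ds_groups.tsv"),
            }
        )
        report.stages_run.append("insolubility")
        summary: dict[str, Any] = {}
        if "hnRNPH" in ins_matrix.values.columns:
            try:
                cls = insolubility.class_summary(ins_matrix, labels, "hnRNPH")
                summary["hnRNPH_mean_like_control"] = cls.mean_like_control
                summary["hnRNPH_mean_like_c9"] = cls.mean_like_c9
                summary["hnRNPH_fold"] = round(cls.fold, 2)
                summary["hnRNPH_t_p"] = cls.p
            except ValueError as exc:
                summary["hnRNPH_class_summary"] = f"skipped: {exc}"
            fit = insolubility.insolubility_css_fit(ins_matrix, css["css"], "hnRNPH")
            summary["hnRNPH_css_slope"] = fit.slope
            summary["hnRNPH_css_r2"] = fit.r_squared
        summary["ds_group_sizes"] = {
            k: int(v) for k, v in sorted(ds_groups["ds_group"].value_counts().items())
        }
        report.summary["insolubility"] = summary
    else:
        report.stages_skipped["insolubility"] = "no densitometry input"

    # --- stage 3: differential splicing ------------------------------------
    junc_path = inputs.get("junctions")
    if junc_path and Path(junc_path).exists() and ds_groups is not None:
        rows, samples = sio.read_junction_counts(junc_path)
        clusters = diffsplice.cluster_junctions(
            rows,
            samples,
            min_cluster_reads=int(cfg.get("min_cluster_reads", 50)),
            max_intron_len=int(cfg.get("max_intron_len", 500_000)),
        )
        control_samples = ds_groups.index[ds_groups["ds_group"] == "control"].tolist()
        groups = {
            g: ds_groups.index[ds_groups["ds_group"] == g].tolist()
            for g in ("ALSlow", "ALShigh", "FTD", "C9")
        }
        groups = {g: s for g, s in groups.items() if len(s) >= 2}
        events = diffsplice.call_events(
            clusters,
            groups,
            control_samples,
            fdr_cutoff=float(cfg.get("fdr", 0.1)),
            dpsi_cutoff=float(cfg.get("dpsi", 0.1)),
            min_sample_reads=int(cfg.get("min_sample_reads", 10)),
        )
        all_events = pd.concat(
            [df.assign(group=g) for g, df in events.items()], ignore_index=True
        )
        sio.write_table(
            all_events, out_dir / "ds_events.tsv", allow_empty=True, sort_by=["group", "event"]
        )
        sig_sets = {
            g: set(df.loc[df["significant"], "event"]) for g, df in events.items()
        }
        regions, per_group = diffsplice.overlap_sets(sig_sets)
        sio.write_table(regions, out_dir / "venn_counts.tsv", allow_empty=True, sort_by=[])
        union_events = sorted(set().union(*sig_sets.values())) if sig_sets else []
        report.summary["diffsplice"] = {
            "n_clusters": len(clusters),
            "n_significant_events": {g: len(s) for g, s in sorted(sig_sets.items())},
            "n_union_events": len(union_events),
        }
        report.outputs.update(
            {
                "ds_events": str(out_dir / "ds_events.tsv"),
                "venn_counts": str(out_dir / "venn_counts.tsv"),
            }
        )
        if union_events:
            psi_frames = []
            for cluster in clusters:
                psi = diffsplice.psi_from_counts(
                    cluster, int(cfg.get("min_sample_reads", 10))
                )
                hit = psi.loc[psi.index.isin(union_events)]
                if not hit.empty:
                    psi_frames.append(hit)
            if psi_frames:
                event_psi = pd.concat(psi_frames)
                zmat = diffsplice.zscore_matrix(event_psi)
                zmat.index.name = "event"
                sio.write_table(
                    zmat.reset_index(), out_dir / "zscores.tsv", allow_empty=True, sort_by=[]
                )
                report.outputs["zscores"] = str(out_dir / "zscores.tsv")
                if ins_matrix is not None and "hnRNPH" in ins_matrix.values.columns:
                    ranking = diffsplice.correlate_events_to_insolubility(
                        event_psi, ins_matrix.values["hnRNPH"]
                    )
                    sio.write_table(
                        ranking,
                        out_dir / "event_insolubility_rank.tsv",
                        allow_empty=True,
                        sort_by=[],
                    )
                    report.outputs["event_insolubility_rank"] = str(
                        out_dir / "event_insolubility_rank.tsv"
                    )
        report.stages_run.append("diffsplice")
    else:
        reason = "no junction counts input" if ds_groups is not None else "no insolubility groups"
        report.stages_skipped["diffsplice"] = reason

    # --- stage 4: clinical association -------------------------------------
    assoc = clinical.ftd_association(labels, metadata)
    sio.write_table(assoc, out_dir / "ftd_association.tsv", sort_by=[])
    report.outputs["ftd_association"] = str(out_dir / "ftd_association.tsv")
    report.stages_run.append("clinical")
    report.summary["clinical"] = {
        k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
        for k, v in assoc.iloc[0].to_dict().items()
    }

    # --- report -------------------------------------------------------------
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=_json_default, sort_keys=True)
    _write_text_summary(report, out_dir / "report.txt")
    report.outputs["report"] = str(out_dir / "report.json")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_text_summary(report: RunReport, path: Path) -> None:
    lines = [f"splicestrat {report.version} run report", ""]
    lines.append(f"stages run: {', '.join(report.stages_run)}")
    for stage, reason in report.stages_skipped.items():
        lines.append(f"stage skipped: {stage} ({reason})")
    for section, values in report.summary.items():
        lines.append("")
        lines.append(f"[{section}]")
        for key, value in values.items():
            lines.append(f"  {key}: {value}")
    path.write_text("\n".join(lines) + "\n")
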