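"""Synthetic ALS/FTD cohort generator.

A single latent per-patient scalar ("burden") drives every modality:
inclusion of hnRNP H-enhanced exons falls with burden while repressed-exon
inclusion rises; protein insolubility rises with burden; responsive intron
clusters shift their usage with burden; and the probability of FTD symptoms
grows logistically with burden.  Controls (neurologically normal and SOD1)
carry near-zero burden; sporadic cases are a mixture of a control-like and
a high-burden component, and C9 carriers draw from the high component.

Ground-truth burden and class labels are stored for parameter-recovery
tests only and are never read by any analysis stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BandIntensities, ExonAnnotation, JunctionRow, Patient, PSIMeasurement

#: 14 hnRNP H-enhanced and 4 hnRNP H-repressed target exons.  Gene symbols
#: marked with a trailing "x" are synthetic placeholders filling out the
#: panel to its documented size.
DEFAULT_EXON_PANEL: tuple[ExonAnnotation, ...] = tuple(
    [
        ExonAnnotation(f"{g}_e", g, "enhanced")
        for g in (
            "KIF1C", "ARRB2", "PPP1R12C", "GABBR1", "DOLPP1", "PAN2", "PCBP2",
            "ENHx1", "ENHx2", "ENHx3", "ENHx4", "ENHx5", "ENHx6", "ENHx7",
        )
    ]
    + [ExonAnnotation(f"{g}_e", g, "repressed") for g in ("RPL10", "OS9", "HNRPDL", "REPx1")]
)

#: (baseline insoluble fraction, burden slope) per assayed protein at
#: 180,000 x g.  hnRNP H and TDP-43 aggregate strongly with burden, FUS and
#: hnRNP A1 follow, GAPDH is the non-aggregating loading control.
DEFAULT_PROTEINS: dict[str, tuple[float, float]] = {
    "hnRNPH": (0.35, 0.50),
    "TDP43": (0.22, 0.65),
    "FUS": (0.02, 0.55),
    "hnRNPA1": (0.25, 0.55),
    "GAPDH": (0.01, 0.00),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate the studied cohort.

    Cohort composition mirrors the 56-case series: ~6 neurologically normal
    controls, 2 SOD1-ALS, 4 C9 carriers and 50 sporadic ALS/FTD cases, with
    half the sporadics in the high-burden component.
    """

    n_controls: int = 6
    n_sod1: int = 2
    n_c9: int = 4
    n_sporadic: int = 50
    burden_mixture: float = 0.5
    high_burden_low: float = 0.3
    high_burden_high: float = 1.0
    control_burden_sd: float = 0.03
    enhanced_slope: float = 0.35
    repressed_slope: float = 0.25
    psi_noise_sd: float = 0.04
    n_replicates: int = 2
    proteins: tuple[tuple[str, float, float], ...] = tuple(
        (name, base, slope) for name, (base, slope) in DEFAULT_PROTEINS.items()
    )
    insolubility_noise_sd: float = 0.06
    g21k_offset: float = 0.15
    motor_cortex_missing_rate: float = 0.2
    ftd_logit_intercept: float = -2.2
    ftd_logit_slope: float = 3.0
    n_clusters: int = 300
    frac_responsive_clusters: float = 0.1
    cluster_shift: float = 0.3
    reads_per_sample_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_sod1", "n_c9", "n_sporadic", "n_clusters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("burden_mixture", "frac_responsive_clusters", "motor_cortex_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    metadata: list[Patient]
    truth: pd.DataFrame  # patient_id, burden, true_class
    psi: list[PSIMeasurement]
    densitometry: list[BandIntensities]
    junctions: list[JunctionRow]
    samples: list[str]
    annotation: tuple[ExonAnnotation, ...]
    responsive_clusters: set[str]
    config: SimConfig


def _clip01(x, lo=0.0, hi=1.0):
    return np.clip(x, lo, hi)


def simulate_cohort(config: SimConfig | None = None, **overrides) -> SyntheticCohort:
    """Draw a complete cohort (metadata, PSI, densitometry, junction counts)."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)

    # --- latent burden and clinical metadata -------------------------------
    patients: list[Patient] = []
    burdens: list[float] = []
    true_class: list[str] = []

    def control_burden() -> float:
        return abs(rng.normal(0.0, config.control_burden_sd))

    def high_burden() -> float:
        return rng.uniform(config.high_burden_low, config.high_burden_high)

    for i in range(config.n_controls):
        patients.append(Patient(f"N{i + 1:02d}", "neuro-normal", "none", False, _sex(rng)))
        burdens.append(control_burden())
        true_class.append("control")
    for i in range(config.n_sod1):
        patients.append(Patient(f"S{i + 1:02d}", "ALS", "SOD1", False, _sex(rng)))
        burdens.append(control_burden())
        true_class.append("control")
    for i in range(config.n_c9):
        b = high_burden()
        ftd = bool(rng.random() < _logistic(config.ftd_logit_intercept + config.ftd_logit_slope * b))
        patients.append(
            Patient(f"C{i + 1:02d}", "ALS-FTD" if ftd else "ALS", "C9", ftd, _sex(rng))
        )
        burdens.append(b)
        true_class.append("like-C9")
    for i in range(config.n_sporadic):
        is_high = bool(rng.random() < config.burden_mixture)
        b = high_burden() if is_high else control_burden()
        ftd = bool(rng.random() < _logistic(config.ftd_logit_intercept + config.ftd_logit_slope * b))
        diagnosis = "ALS"
        if ftd:
            diagnosis = "FTD-MND" if rng.random() < 0.5 else "ALS-FTD"
        patients.append(
            Patient(
                f"P{i + 1:02d}",
                diagnosis,
                "none",
                ftd,
                _sex(rng),
                has_motor_cortex=bool(rng.random() >= config.motor_cortex_missing_rate),
            )
        )
        burdens.append(b)
        true_class.append("like-C9" if is_high else "like-control")

    truth = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "burden": burdens,
            "true_class": true_class,
        }
    ).set_index("patient_id")

    # --- exon inclusion (two replicates per measurement) -------------------
    annotation = DEFAULT_EXON_PANEL
    base_psi = {}
    for a in annotation:
        if a.regulation == "enhanced":
            base_psi[a.exon_id] = rng.uniform(0.4, 0.9)
        else:
            base_psi[a.exon_id] = rng.uniform(0.1, 0.5)
    psi: list[PSIMeasurement] = []
    for p, b in zip(patients, burdens):
        for a in annotation:
            if a.regulation == "enhanced":
                mean = base_psi[a.exon_id] - config.enhanced_slope * b
            else:
                mean = base_psi[a.exon_id] + config.repressed_slope * b
            mean = float(_clip01(mean, 0.01, 0.99))  # clamp before noise
            for rep in range(1, config.n_replicates + 1):
                value = float(_clip01(mean + rng.normal(0.0, config.psi_noise_sd)))
                psi.append(PSIMeasurement(p.patient_id, a.exon_id, rep, value))

    # --- fractionation densitometry (both speeds, two replicates) ----------
    densitometry: list[BandIntensities] = []
    for p, b in zip(patients, burdens):
        if not p.has_motor_cortex:
            continue
        for protein, base, slope in config.proteins:
            for speed in ("g180k", "g21k"):
                offset = config.g21k_offset if speed == "g21k" else 0.0
                for rep in range(1, config.n_replicates + 1):
                    frac = base + slope * b - offset + rng.normal(0.0, config.insolubility_noise_sd)
                    frac = float(_clip01(frac))
                    total = float(rng.uniform(50.0, 200.0))
                    si = frac * total
                    sol_share = float(rng.uniform(0.2, 0.8))
                    sol = (1.0 - frac) * total * sol_share
                    ss = (1.0 - frac) * total * (1.0 - sol_share)
                    densitometry.append(
                        BandIntensities(p.patient_id, protein, speed, rep, sol, ss, si)
                    )

    # --- junction counts ---------------------------------------------------
    samples = [p.patient_id for p in patients]
    junctions: list[JunctionRow] = []
    responsive: set[str] = set()
    n_responsive = int(round(config.frac_responsive_clusters * config.n_clusters))
    responsive_idx = set(
        rng.choice(config.n_clusters, size=n_responsive, replace=False).tolist()
        if n_responsive
        else []
    )
    for k in range(config.n_clusters):
        cid = f"clu_{k + 1}"
        start = 10_000 * (k + 1)
        n_introns = int(rng.integers(2, 4))  # 2 or 3 introns sharing a donor
        ends = start + 500 + np.sort(rng.integers(1, 5000, size=n_introns))
        ends = np.unique(ends)
        while len(ends) < n_introns:
            ends = np.unique(np.append(ends, ends[-1] + int(rng.integers(100, 1000))))
        base_usage = rng.dirichlet(np.full(n_introns, 5.0))
        direction = 1.0 if rng.random() < 0.5 else -1.0
        is_responsive = k in responsive_idx
        if is_responsive:
            responsive.add(cid)
        counts_matrix = np.zeros((n_introns, len(samples)), dtype=np.int64)
        for j, b in enumerate(burdens):
            usage = base_usage.copy()
            if is_responsive:
                shift = direction * config.cluster_shift * b
                u0 = float(np.clip(usage[0] + shift, 0.01, 0.97))
                rest = usage[1:] / usage[1:].sum()
                usage = np.concatenate([[u0], (1.0 - u0) * rest])
            total = int(rng.poisson(config.reads_per_sample_mean))
            if total > 0:
                counts_matrix[:, j] = rng.multinomial(total, usage)
        for i in range(n_introns):
            junctions.append(
                JunctionRow("chr1", start, int(ends[i]), cid, tuple(counts_matrix[i]))
            )

    return SyntheticCohort(
        metadata=patients,
        truth=truth,
        psi=psi,
        densitometry=densitometry,
        junctions=junctions,
        samples=samples,
        annotation=annotation,
        responsive_clusters=responsive,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | os.PathLike, force: bool = False) -> dict[str, Path]:
    """Write the cohort as the file set every reader in the package accepts.

    Emits clinical.tsv, psi_long.tsv, densitometry.tsv, junction_counts.txt
    and truth/truth.tsv (ground truth segregated from analysis inputs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    paths = {
        "clinical": out / "clinical.tsv",
        "psi": out / "psi_long.tsv",
        "densitometry": out / "densitometry.tsv",
        "junctions": out / "junction_counts.txt",
        "truth": out / "truth" / "truth.tsv",
    }
    existing = [p for p in paths.values() if p.exists()]
    if existing and not force:
        raise FileExistsError(f"refusing to overwrite {existing[0]} (pass force=True)")

    meta = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "diagnosis": p.diagnosis,
                "genotype": p.genotype,
                "ftd_symptoms": str(p.ftd_symptoms).lower(),
                "sex": p.sex,
                "has_motor_cortex": str(p.has_motor_cortex).lower(),
                "has_insolubility": str(p.has_insolubility).lower(),
            }
            for p in cohort.metadata
        ]
    )
    meta.to_csv(paths["clinical"], sep="\t", index=False)

    psi = pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "exon_id": m.exon_id,
                "replicate": m.replicate,
                "value": f"{m.inclusion_fraction:.9f}",
            }
            for m in cohort.psi
        ]
    )
    psi.to_csv(paths["psi"], sep="\t", index=False)

    dens_rows = []
    for r in cohort.densitometry:
        for fraction, value in (("SOL", r.sol), ("SS", r.ss), ("SI", r.si)):
            dens_rows.append(
                {
                    "patient_id": r.patient_id,
                    "protein": r.protein,
                    "speed": r.speed,
                    "replicate": r.replicate,
                    "fraction": fraction,
                    "intensity": f"{value:.9f}",
                }
            )
    pd.DataFrame(dens_rows).to_csv(paths["densitometry"], sep="\t", index=False)

    with open(paths["junctions"], "w") as fh:
        fh.write("junction " + " ".join(cohort.samples) + "\n")
        for row in cohort.junctions:
            fh.write(row.key + " " + " ".join(str(c) for c in row.counts) + "\n")

    cohort.truth.reset_index().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _sex(rng: np.random.Generator) -> str:
    return "F" if rng.random() < 0.5 else "M"
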