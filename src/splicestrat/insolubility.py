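"""Protein insolubility from sarkosyl fractionation densitometry.

Sequential detergent extraction splits each lysate into soluble (SOL),
sarkosyl-soluble (SS) and sarkosyl-insoluble (SI) fractions; the insoluble
share of a protein is SI / (SOL + SS + SI), computed per replicate and then
replicate-averaged.  Two centrifugation speeds are modeled: 180,000 x g
("g180k") and the gentler 21,000 x g ("g21k").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BandIntensities, Patient
from .splicing import LIKE_C9, LIKE_CONTROL, RegressionFit, _ols

DS_GROUPS = ("control", "ALSlow", "ALShigh", "FTD", "C9", "unassigned")


@dataclass
class InsolubilityMatrix:
    """Replicate-averaged insoluble fractions, patients x proteins, one speed."""

    values: pd.DataFrame
    n_replicates: pd.DataFrame
    speed: str

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ClassSummary:
    protein: str
    mean_like_control: float
    mean_like_c9: float
    fold: float          # like-C9 / like-control; nan when undefined
    t: float
    p: float
    n_like_control: int
    n_like_c9: int


def percent_insoluble(record: BandIntensities) -> float:
    """Insoluble fraction SI / (SOL + SS + SI) for one lane set."""
    total = record.sol + record.ss + record.si
    if total <= 0:
        raise ValueError("all-zero fractionation record")
    return record.si / total


def build_insolubility_matrix(
    records: Sequence[BandIntensities],
    speed: str,
    metadata: Sequence[Patient] | None = None,
) -> InsolubilityMatrix:
    """Average replicate insoluble fractions per (patient, protein) at one speed.

    Patients flagged without motor-cortex tissue are excluded when metadata
    is supplied — those cases cannot be fractionated.
    """
    if speed not in ("g180k", "g21k"):
        raise ValueError(f"speed must be g180k/g21k, got {speed!r}")
    available = None
    if metadata is not None:
        available = {p.patient_id for p in metadata if p.has_motor_cortex and p.has_insolubility}
    rows = [
        {
            "patient_id": r.patient_id,
            "protein": r.protein,
            "value": percent_insoluble(r),
        }
        for r in records
        if r.speed == speed and (available is None or r.patient_id in available)
    ]
    if not rows:
        empty = pd.DataFrame()
        return InsolubilityMatrix(values=empty, n_replicates=empty, speed=speed)
    df = pd.DataFrame(rows)
    values = df.pivot_table(index="patient_id", columns="protein", values="value", aggfunc="mean")
    nrep = df.pivot_table(index="patient_id", columns="protein", values="value", aggfunc="count")
    return InsolubilityMatrix(
        values=values.sort_index(),
        n_replicates=nrep.fillna(0).astype(int).sort_index(),
        speed=speed,
    )


def class_summary(
    matrix: InsolubilityMatrix, labels: pd.DataFrame, protein: str
) -> ClassSummary:
    """Group means, Welch t-test and fold ratio for one protein.

    ``fold`` is mean(like-C9) / mean(like-control); reports round it to two
    decimals.  A zero like-control mean leaves the fold undefined (NaN).
    """
    if protein not in matrix.values.columns:
        raise KeyError(f"protein {protein!r} not in matrix")
    col = matrix.values[protein]
    lc = col[col.index.isin(labels.index[labels["label"] == LIKE_CONTROL])].dropna()
    c9 = col[col.index.isin(labels.index[labels["label"] == LIKE_C9])].dropna()
    if len(lc) < 2 or len(c9) < 2:
        raise ValueError("both classes need >= 2 patients with values")
    t, p = stats.ttest_ind(c9, lc, equal_var=False)
    mean_lc, mean_c9 = float(lc.mean()), float(c9.mean())
    fold = mean_c9 / mean_lc if mean_lc > 0 else float("nan")
    return ClassSummary(
        protein=protein,
        mean_like_control=mean_lc,
        mean_like_c9=mean_c9,
        fold=fold,
        t=float(t),
        p=float(p),
        n_like_control=len(lc),
        n_like_c9=len(c9),
    )


def fold_ratio(mean_like_c9: float, mean_like_control: float) -> float:
    """Fold difference in insolubility between the two classes."""
    if mean_like_control <= 0:
        return float("nan")
    return mean_like_c9 / mean_like_control


def insolubility_css_fit(
    matrix: InsolubilityMatrix, css: pd.Series, protein: str
) -> RegressionFit:
    """OLS of a protein's insoluble fraction (y) on the CSS (x).

    On burden-structured cohorts the slope is negative: more aggregated
    protein in patients with more severe splicing dysregulation (lower CSS).
    """
    if protein not in matrix.values.columns:
        raise KeyError(f"protein {protein!r} not in matrix")
    joined = pd.concat([css.rename("css"), matrix.values[protein].rename("y")], axis=1)
    return _ols(joined["css"].to_numpy(dtype=float), joined["y"].to_numpy(dtype=float))


def pairwise_spearman(
    matrices: Mapping[str, InsolubilityMatrix] | pd.DataFrame,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Symmetric Spearman correlation matrix across protein/speed columns.

    Accepts either a mapping speed -> InsolubilityMatrix (columns are named
    ``protein@speed``) or a prebuilt patients x features frame.  Each pair
    uses its pairwise-complete patients; pairs with fewer than
    ``min_overlap`` shared patients are left missing.  Ties get average
    ranks; the diagonal is 1.
    """
    if isinstance(matrices, pd.DataFrame):
        wide = matrices
    else:
        pieces = []
        for speed, mat in sorted(matrices.items()):
            renamed = mat.values.rename(columns=lambda c: f"{c}@{speed}")
            pieces.append(renamed)
        wide = pd.concat(pieces, axis=1)
    cols = list(wide.columns)
    out = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, a in enumerate(cols):
        out.loc[a, a] = 1.0
        for b in cols[i + 1:]:
            pair = wide[[a, b]].dropna()
            if len(pair) < min_overlap:
                continue
            if pair[a].nunique() < 2 or pair[b].nunique() < 2:
                continue  # constant vector: rank correlation undefined
            rho = stats.spearmanr(pair[a], pair[b]).statistic
            out.loc[a, b] = rho
            out.loc[b, a] = rho
    return out


def assign_ds_groups(
    hnrnph: pd.Series,
    metadata: Sequence[Patient],
    threshold: float = 0.50,
) -> pd.DataFrame:
    """Assign RNA-seq analysis groups from clinical status and hnRNP H insolubility.

    Precedence: C9 genotype -> C9; control (neuro-normal or SOD1) -> control;
    clinical FTD symptoms -> FTD; remaining sporadic pure-ALS patients split
    at ``threshold`` insoluble hnRNP H into ALSlow (<) and ALShigh (>=);
    anything left without an insolubility value is unassigned.
    """
    rows = []
    for p in metadata:
        value = hnrnph.get(p.patient_id, np.nan)
        if p.genotype == "C9":
            group = "C9"
        elif p.is_control:
            group = "control"
        elif p.ftd_symptoms:
            group = "FTD"
        elif np.isfinite(value):
            group = "ALSlow" if value < threshold else "ALShigh"
        else:
            group = "unassigned"
        rows.append({"patient_id": p.patient_id, "ds_group": group, "hnrnph_insoluble": value})
    return pd.DataFrame(rows).set_index("patient_id")
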