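"""Composite splicing score (CSS), patient classification and exon-level fits.

The CSS of a patient is the mean inclusion fraction over a panel of exons
whose inclusion is enhanced by hnRNP H; when functional hnRNP H is scarce,
inclusion of these exons drops and the CSS falls.  Patients are classified
against controls (neurologically normal plus SOD1-ALS cases) with a
one-sided rule: a CSS more than ``k`` control standard deviations below the
control mean is called "like-C9", anything else "like-control".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExonAnnotation, Patient, PSIMeasurement

LIKE_C9 = "like-C9"
LIKE_CONTROL = "like-control"
CONTROL = "control"


@dataclass
class PSIMatrix:
    """Replicate-averaged exon inclusion, patients x exons.

    ``values`` holds fractions in [0,1] with NaN for missing cells;
    ``n_replicates`` holds the per-cell replicate count (0 where missing).
    """

    values: pd.DataFrame
    n_replicates: pd.DataFrame
    annotation: tuple[ExonAnnotation, ...]

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    @property
    def enhanced_exons(self) -> list[str]:
        return [a.exon_id for a in self.annotation if a.regulation == "enhanced"]

    @property
    def repressed_exons(self) -> list[str]:
        return [a.exon_id for a in self.annotation if a.regulation == "repressed"]


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares simple linear fit."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def percent_inclusion(inclusion_intensity: float, exclusion_intensity: float) -> float:
    """Inclusion fraction from inclusion/exclusion band intensities."""
    if inclusion_intensity < 0 or exclusion_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    total = inclusion_intensity + exclusion_intensity
    if total <= 0:
        raise ValueError("unquantifiable lane: both band intensities are zero")
    return inclusion_intensity / total


def build_psi_matrix(
    measurements: Sequence[PSIMeasurement], annotation: Sequence[ExonAnnotation]
) -> PSIMatrix:
    """Average replicates into a patients x exons inclusion matrix.

    Missing (patient, exon) pairs remain NaN — never 0.
    """
    if not measurements:
        raise ValueError("no measurements")
    df = pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in measurements],
            "exon_id": [m.exon_id for m in measurements],
            "value": [m.inclusion_fraction for m in measurements],
        }
    )
    values = df.pivot_table(index="patient_id", columns="exon_id", values="value", aggfunc="mean")
    nrep = df.pivot_table(index="patient_id", columns="exon_id", values="value", aggfunc="count")
    # keep annotated exons as explicit columns even if unmeasured, in panel order
    panel = [a.exon_id for a in annotation]
    extra = [c for c in values.columns if c not in panel]
    cols = panel + sorted(extra)
    values = values.reindex(columns=cols).sort_index()
    nrep = nrep.reindex(columns=cols).fillna(0).astype(int).sort_index()
    return PSIMatrix(values=values, n_replicates=nrep, annotation=tuple(annotation))


def compute_css(
    matrix: PSIMatrix,
    exon_subset: Sequence[str] | str = "all-enhanced",
    min_exons: int = 10,
) -> pd.DataFrame:
    """Per-patient composite splicing score over a subset of enhanced exons.

    Returns a frame with columns ``css`` (NaN where the patient has fewer
    than ``min_exons`` non-missing values in the subset), ``n_exons`` and
    ``flagged``.
    """
    enhanced = set(matrix.enhanced_exons)
    if isinstance(exon_subset, str):
        if exon_subset != "all-enhanced":
            raise ValueError(f"unknown subset spec {exon_subset!r}")
        subset = sorted(enhanced)
    else:
        subset = list(exon_subset)
        if not set(subset) <= enhanced:
            raise ValueError("exon_subset must be a subset of the enhanced exons")
    if not subset:
        raise ValueError("empty exon subset")
    sub = matrix.values.reindex(columns=subset)
    n = sub.notna().sum(axis=1)
    css = sub.mean(axis=1, skipna=True)
    flagged = n < min_exons
    css = css.where(~flagged)
    return pd.DataFrame({"css": css, "n_exons": n, "flagged": flagged})


def classify_patients(
    css: pd.Series,
    metadata: Sequence[Patient],
    k: float = 3.0,
    control_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One-sided k-SD classification of cases against the control CSS range.

    Controls default to neurologically normal and SOD1 patients; the control
    set can be overridden with ``control_ids``.  The cutoff is
    ``mean - k * sd`` (sample SD, n-1 denominator); only a CSS strictly
    below the cutoff yields "like-C9".  Controls keep the label "control".
    No control is trimmed, however far from the mean.
    """
    by_id = {p.patient_id: p for p in metadata}
    if control_ids is None:
        control_ids = [p.patient_id for p in metadata if p.is_control]
    controls = [pid for pid in control_ids if pid in css.index and np.isfinite(css[pid])]
    if len(controls) < 3:
        raise ValueError(f"need >= 3 controls with a CSS, have {len(controls)}")
    control_mean = float(css[controls].mean())
    control_sd = float(css[controls].std(ddof=1))
    cutoff = control_mean - k * control_sd
    rows = []
    control_set = set(control_ids)
    for pid in css.index:
        value = css[pid]
        if pid in control_set:
            label = CONTROL
        elif not np.isfinite(value):
            label = "unscored"
        else:
            label = LIKE_C9 if value < cutoff else LIKE_CONTROL
        rows.append(
            {
                "patient_id": pid,
                "css": value,
                "label": label,
                "cutoff": cutoff,
                "control_mean": control_mean,
                "control_sd": control_sd,
                "k": k,
                "diagnosis": by_id[pid].diagnosis if pid in by_id else "",
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, have {n}")
    if np.ptp(x) == 0:
        # degenerate predictor: slope undefined; report flat fit, flag r^2
        return RegressionFit(slope=0.0, intercept=float(np.mean(y)), r_squared=float("nan"), n=n)
    res = stats.linregress(x, y)
    if np.ptp(y) == 0:
        r2 = 0.0
    else:
        r2 = float(res.rvalue**2)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2, n=n)


def loo_regression(matrix: PSIMatrix) -> pd.DataFrame:
    """Leave-one-out fit for each enhanced exon.

    For exon g, x is the per-patient mean inclusion of the other enhanced
    exons (the CSS recomputed without g) and y is the patient's inclusion of
    g; the fit is ordinary least squares.  A tight fit for every exon means
    each panel member tracks the shared splicing trend.
    """
    enhanced = matrix.enhanced_exons
    if len(enhanced) < 2:
        raise ValueError("need >= 2 enhanced exons for leave-one-out fits")
    sub = matrix.values.reindex(columns=enhanced)
    rows = []
    for exon in enhanced:
        others = [e for e in enhanced if e != exon]
        x = sub[others].mean(axis=1, skipna=True).to_numpy(dtype=float)
        y = sub[exon].to_numpy(dtype=float)
        fit = _ols(x, y)
        rows.append(
            {
                "exon_id": exon,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows).set_index("exon_id")


def repressed_vs_enhanced_fit(matrix: PSIMatrix) -> RegressionFit:
    """OLS of mean repressed-exon inclusion (y) on the enhanced-exon CSS (x).

    On burden-structured cohorts the slope is negative: the patients with
    the lowest enhanced-exon CSS have the highest repressed-exon inclusion.
    """
    if not matrix.repressed_exons:
        raise ValueError("annotation has no repressed exons")
    x = matrix.values.reindex(columns=matrix.enhanced_exons).mean(axis=1, skipna=True)
    y = matrix.values.reindex(columns=matrix.repressed_exons).mean(axis=1, skipna=True)
    return _ols(x.to_numpy(dtype=float), y.to_numpy(dtype=float))


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def group_compare(
    matrix: PSIMatrix, labels: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch t-test per exon between like-control and like-C9 patients.

    ``labels`` is the classify_patients output.  A group with fewer than two
    patients leaves p undefined (NaN) and the exon flagged.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    a_ids = labels.index[labels["label"] == LIKE_CONTROL]
    b_ids = labels.index[labels["label"] == LIKE_C9]
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError("both classification groups must be non-empty")
    rows = []
    for exon in matrix.values.columns:
        a = matrix.values.loc[matrix.values.index.isin(a_ids), exon].dropna()
        b = matrix.values.loc[matrix.values.index.isin(b_ids), exon].dropna()
        if len(a) < 2 or len(b) < 2:
            t, p = float("nan"), float("nan")
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "exon_id": exon,
                "mean_like_control": float(a.mean()) if len(a) else float("nan"),
                "mean_like_c9": float(b.mean()) if len(b) else float("nan"),
                "t": float(t),
                "p": float(p),
                "significant": bool(np.isfinite(p) and p < alpha),
                "stars": significance_stars(float(p)),
            }
        )
    return pd.DataFrame(rows).set_index("exon_id")
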