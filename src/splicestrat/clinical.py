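"""Clinical association between splicing classification and FTD symptoms.

The central question: are like-C9 patients more likely to carry symptoms of
frontotemporal dementia than like-control patients?  Answered with a 2x2
odds ratio and Fisher's exact test over the non-control cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .io import Patient
from .splicing import LIKE_C9, LIKE_CONTROL


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: like-C9 / like-control.  Columns: FTD symptoms / none.

    a = like-C9 with FTD, b = like-C9 without, c = like-control with FTD,
    d = like-control without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def build_contingency(
    labels: pd.DataFrame, metadata: Sequence[Patient]
) -> ContingencyTable2x2:
    """Tally classification against FTD symptoms over non-control patients."""
    ftd = {p.patient_id: p.ftd_symptoms for p in metadata}
    a = b = c = d = 0
    for pid, row in labels.iterrows():
        label = row["label"]
        if label not in (LIKE_C9, LIKE_CONTROL):
            continue
        has_ftd = bool(ftd.get(pid, False))
        if label == LIKE_C9:
            if has_ftd:
                a += 1
            else:
                b += 1
        else:
            if has_ftd:
                c += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio(table: ContingencyTable2x2, haldane: bool = False) -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    A zero b*c with positive a*d gives +inf; the Haldane-Anscombe 0.5
    continuity correction is available but off by default.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_exact(table: ContingencyTable2x2, sided: str = "two") -> float:
    """Fisher's exact test on the 2x2 table.

    ``sided="two"`` uses the minimum-likelihood summation convention (all
    tables with point hypergeometric probability <= the observed one);
    ``sided="greater"`` is the one-sided tail toward larger ``a``.
    """
    if sided not in ("two", "greater"):
        raise ValueError(f"sided must be 'two' or 'greater', got {sided!r}")
    alternative = "two-sided" if sided == "two" else "greater"
    return float(stats.fisher_exact(table.as_array(), alternative=alternative).pvalue)


def normal_within_k_sd(k: float) -> float:
    """Percent of a normal distribution lying within +/- k SD of its mean.

    Documents the nominal specificity of the k-SD classification cutoff
    (k=3 covers 99.7% of a normal control population).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    return 100.0 * (stats.norm.cdf(k) - stats.norm.cdf(-k))


def ftd_association(
    labels: pd.DataFrame, metadata: Sequence[Patient]
) -> pd.DataFrame:
    """One-row summary: table cells, odds ratio, one- and two-sided p."""
    table = build_contingency(labels, metadata)
    return pd.DataFrame(
        [
            {
                "like_c9_ftd": table.a,
                "like_c9_no_ftd": table.b,
                "like_control_ftd": table.c,
                "like_control_no_ftd": table.d,
                "odds_ratio": odds_ratio(table),
                "p_two_sided": fisher_exact(table, "two"),
                "p_greater": fisher_exact(table, "greater"),
            }
        ]
    )
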