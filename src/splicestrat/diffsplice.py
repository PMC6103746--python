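"""Intron-cluster differential splicing over junction counts.

Introns sharing a splice site compete for usage within a cluster; an
intron's PSI in a sample is its share of the cluster's junction reads.
Group differences are tested per cluster with a multinomial
likelihood-ratio test on counts pooled within each group — a deliberately
simple stand-in for a Dirichlet-multinomial GLM that preserves the
cluster-level testing structure (see the methods note for the trade-offs).
Cluster p-values are BH-adjusted; an intron is a significant event when its
cluster passes the FDR cutoff and its own |dPSI| passes the magnitude
cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import JunctionRow

logger = logging.getLogger("splicestrat")

MIN_CLUSTER_READS = 50
MAX_INTRON_LEN = 500_000
MIN_SAMPLE_READS = 10
FDR_CUTOFF = 0.1
DPSI_CUTOFF = 0.1


@dataclass
class IntronCluster:
    """A set of competing introns with a per-sample count matrix."""

    cluster_id: str
    introns: tuple[JunctionRow, ...]
    counts: pd.DataFrame  # introns (key) x samples

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def total_per_sample(self) -> pd.Series:
        return self.counts.sum(axis=0)


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_junctions(
    rows: Sequence[JunctionRow],
    samples: Sequence[str],
    min_cluster_reads: int = MIN_CLUSTER_READS,
    max_intron_len: int = MAX_INTRON_LEN,
) -> list[IntronCluster]:
    """Group introns into clusters and apply the support filters.

    Input cluster ids are honored when present; otherwise introns are
    grouped per chromosome by connected components of shared start or end
    coordinates.  Clusters are dropped when their summed count over all
    samples and introns is below ``min_cluster_reads``, when any member
    intron exceeds ``max_intron_len``, or when they contain a single intron
    (no alternative usage to test).
    """
    has_ids = any(r.cluster_id for r in rows)
    groups: dict[str, list[JunctionRow]] = {}
    if has_ids:
        for r in rows:
            if not r.cluster_id:
                continue  # unclustered rows cannot join given clusters
            groups.setdefault(f"{r.chrom}:{r.cluster_id}", []).append(r)
    else:
        uf = _UnionFind()
        for i, r in enumerate(rows):
            uf.union(("row", i), (r.chrom, "s", r.start))
            uf.union(("row", i), (r.chrom, "e", r.end))
        comp: dict = {}
        for i, r in enumerate(rows):
            comp.setdefault(uf.find(("row", i)), []).append(r)
        for members in comp.values():
            first = min(members, key=lambda r: (r.chrom, r.start, r.end))
            groups[f"{first.chrom}:clu@{first.start}"] = members
    clusters: list[IntronCluster] = []
    for cid in sorted(groups):
        members = sorted(groups[cid], key=lambda r: (r.start, r.end))
        if len(members) < 2:
            continue
        if any(m.length > max_intron_len for m in members):
            continue
        counts = pd.DataFrame(
            [m.counts for m in members],
            index=[m.key for m in members],
            columns=list(samples),
            dtype=np.int64,
        )
        if int(counts.to_numpy().sum()) < min_cluster_reads:
            continue
        clusters.append(IntronCluster(cluster_id=cid, introns=tuple(members), counts=counts))
    return clusters


def psi_from_counts(
    cluster: IntronCluster, min_sample_reads: int = MIN_SAMPLE_READS
) -> pd.DataFrame:
    """Per-intron PSI per sample: each intron's share of the cluster total.

    Samples whose cluster total is below ``min_sample_reads`` get NaN for
    every intron (too few reads to estimate usage); otherwise the PSIs of a
    sample sum to 1 over the cluster.
    """
    totals = cluster.total_per_sample()
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = cluster.counts.div(totals, axis=1)
    psi.loc[:, totals < min_sample_reads] = np.nan
    return psi


def _multinomial_ll(counts: np.ndarray, probs: np.ndarray) -> float:
    """Log-likelihood kernel sum(n_i * log p_i), with 0*log(0) = 0."""
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(probs[mask])))


def cluster_test(
    cluster: IntronCluster,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_sample_reads: int = MIN_SAMPLE_READS,
) -> tuple[float, pd.Series, float]:
    """Multinomial LRT for differential intron usage between two groups.

    Counts are pooled within each group over samples passing the per-sample
    read cutoff; the statistic is 2*(ll_separate - ll_shared) against a
    chi-square with (n_introns - 1) degrees of freedom.  Returns
    ``(p, delta_psi, statistic)`` where delta_psi is the per-intron
    difference in mean PSI, group A minus group B.  Requires >= 2 usable
    samples per group; a degenerate cluster (all counts on one intron in
    both groups) gives statistic 0 and p = 1.
    """
    psi = psi_from_counts(cluster, min_sample_reads)
    usable_a = [s for s in group_a if s in psi.columns and psi[s].notna().all()]
    usable_b = [s for s in group_b if s in psi.columns and psi[s].notna().all()]
    if len(usable_a) < 2 or len(usable_b) < 2:
        raise ValueError(
            f"cluster {cluster.cluster_id}: need >= 2 usable samples per group "
            f"(have {len(usable_a)}, {len(usable_b)})"
        )
    na = cluster.counts[usable_a].sum(axis=1).to_numpy(dtype=float)
    nb = cluster.counts[usable_b].sum(axis=1).to_numpy(dtype=float)
    pooled = na + nb
    p_shared = pooled / pooled.sum()
    p_a = na / na.sum()
    p_b = nb / nb.sum()
    ll_shared = _multinomial_ll(na, p_shared) + _multinomial_ll(nb, p_shared)
    ll_sep = _multinomial_ll(na, p_a) + _multinomial_ll(nb, p_b)
    statistic = max(0.0, 2.0 * (ll_sep - ll_shared))
    df = cluster.n_introns - 1
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    delta_psi = psi[usable_a].mean(axis=1) - psi[usable_b].mean(axis=1)
    return p, delta_psi, statistic


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_events(
    clusters: Sequence[IntronCluster],
    groups: Mapping[str, Sequence[str]],
    control_samples: Sequence[str],
    fdr_cutoff: float = FDR_CUTOFF,
    dpsi_cutoff: float = DPSI_CUTOFF,
    min_sample_reads: int = MIN_SAMPLE_READS,
) -> dict[str, pd.DataFrame]:
    """Differential-splicing events per comparison group versus control.

    For each group, every testable cluster is LRT-tested against the
    control samples; cluster p-values are BH-adjusted across clusters and
    the cluster q propagates to its introns.  An intron is a significant
    event iff its cluster q <= ``fdr_cutoff`` and its |dPSI| >=
    ``dpsi_cutoff`` (pass ``dpsi_cutoff=0`` for the unfiltered analysis).
    """
    if not list(control_samples):
        raise ValueError("control group is empty")
    results: dict[str, pd.DataFrame] = {}
    for group_name, group_samples in groups.items():
        records = []
        tested = []
        for cluster in clusters:
            try:
                p, delta_psi, statistic = cluster_test(
                    cluster, group_samples, control_samples, min_sample_reads
                )
            except ValueError:
                continue  # not enough usable samples; cluster untestable
            tested.append((cluster, p, delta_psi, statistic))
        qvals = bh_fdr([t[1] for t in tested]) if tested else np.array([])
        for (cluster, p, delta_psi, statistic), q in zip(tested, qvals):
            for intron_key, dpsi in delta_psi.items():
                significant = bool(
                    q <= fdr_cutoff and np.isfinite(dpsi) and abs(dpsi) >= dpsi_cutoff
                )
                records.append(
                    {
                        "cluster_id": cluster.cluster_id,
                        "event": intron_key,
                        "delta_psi": float(dpsi),
                        "p": p,
                        "q": float(q),
                        "statistic": statistic,
                        "significant": significant,
                    }
                )
        df = pd.DataFrame(
            records,
            columns=["cluster_id", "event", "delta_psi", "p", "q", "statistic", "significant"],
        )
        results[group_name] = df.sort_values(["cluster_id", "event"]).reset_index(drop=True)
    return results


def stratified_cluster_test(
    cluster: IntronCluster,
    group_a: Sequence[str],
    group_b: Sequence[str],
    strata: Mapping[str, str],
    min_sample_reads: int = MIN_SAMPLE_READS,
) -> float:
    """Covariate-stratified test: LRT within each stratum, Fisher-combined.

    ``strata`` maps sample -> stratum label (e.g. sex).  Strata without
    enough usable samples in both groups are skipped; the remaining
    per-stratum p-values are combined with Fisher's method.
    """
    pvals = []
    levels = sorted(set(strata.values()))
    for level in levels:
        sub_a = [s for s in group_a if strata.get(s) == level]
        sub_b = [s for s in group_b if strata.get(s) == level]
        try:
            p, _, _ = cluster_test(cluster, sub_a, sub_b, min_sample_reads)
        except ValueError:
            continue
        pvals.append(p)
    if not pvals:
        raise ValueError("no stratum with enough usable samples in both groups")
    return float(stats.combine_pvalues(pvals, method="fisher").pvalue)


def overlap_sets(event_sets: Mapping[str, set]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Venn-style membership-pattern counts over per-group event sets.

    Returns (regions, per_group) where ``regions`` counts every non-empty
    membership pattern (region counts sum to the union size) and
    ``per_group`` reports each group's total and unique-event fraction.
    """
    names = sorted(event_sets)
    universe = set().union(*event_sets.values()) if event_sets else set()
    patterns: dict[tuple[str, ...], int] = {}
    for event in universe:
        members = tuple(n for n in names if event in event_sets[n])
        patterns[members] = patterns.get(members, 0) + 1
    regions = pd.DataFrame(
        [{"groups": "&".join(k), "n_groups": len(k), "count": v} for k, v in sorted(patterns.items())]
    )
    per_group_rows = []
    for n in names:
        total = len(event_sets[n])
        unique = patterns.get((n,), 0)
        per_group_rows.append(
            {
                "group": n,
                "total": total,
                "unique": unique,
                "unique_fraction": unique / total if total else float("nan"),
            }
        )
    return regions, pd.DataFrame(per_group_rows).set_index("group")


def zscore_matrix(psi: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores (n-1 SD) over non-missing samples.

    Rows with fewer than two non-missing values or zero variance are
    dropped with a warning — they carry no contrast to display.
    """
    means = psi.mean(axis=1, skipna=True)
    sds = psi.std(axis=1, ddof=1, skipna=True)
    keep = (psi.notna().sum(axis=1) >= 2) & (sds > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("zscore_matrix: dropping %d constant/under-measured rows", dropped)
    return psi.loc[keep].sub(means[keep], axis=0).div(sds[keep], axis=0)


@dataclass
class ClusterOrdering:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None


def order_and_cluster(
    zmat: pd.DataFrame,
    mode: str = "cluster",
    subtype: pd.Series | None = None,
    insolubility: pd.Series | None = None,
    subtype_order: Sequence[str] = ("control", "ALSlow", "ALShigh", "C9", "FTD"),
) -> ClusterOrdering:
    """Row/column orderings for an events x samples Z-score matrix.

    mode "fixed": columns sorted by subtype (given category order) then
    increasing insolubility, ties broken by sample id; rows stay
    hierarchically clustered.  mode "cluster": agglomerative average
    linkage for both axes — correlation distance (1 - Pearson) for events,
    Euclidean for samples.  Inputs are pre-sorted by identifier so the
    linkage is deterministic.
    """
    if zmat.shape[0] < 2 or zmat.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    zmat = zmat.sort_index(axis=0).sort_index(axis=1)
    filled = zmat.fillna(0.0)

    row_linkage = hierarchy.linkage(
        pdist(filled.to_numpy(), metric="correlation"), method="average"
    )
    row_order = [zmat.index[i] for i in hierarchy.leaves_list(row_linkage)]

    if mode == "fixed":
        if subtype is None or insolubility is None:
            raise ValueError("fixed mode needs subtype and insolubility series")
        rank = {s: i for i, s in enumerate(subtype_order)}
        cols = sorted(
            zmat.columns,
            key=lambda c: (
                rank.get(subtype.get(c), len(subtype_order)),
                float(insolubility.get(c, np.inf)),
                c,
            ),
        )
        return ClusterOrdering(row_order=row_order, col_order=cols, row_linkage=row_linkage)
    if mode != "cluster":
        raise ValueError(f"unknown mode {mode!r}")
    col_linkage = hierarchy.linkage(
        pdist(filled.to_numpy().T, metric="euclidean"), method="average"
    )
    col_order = [zmat.columns[i] for i in hierarchy.leaves_list(col_linkage)]
    return ClusterOrdering(
        row_order=row_order, col_order=col_order, row_linkage=row_linkage, col_linkage=col_linkage
    )


def cut_columns(ordering: ClusterOrdering, zmat: pd.DataFrame, k: int) -> pd.Series:
    """Flat k-group cut of the sample dendrogram (cluster mode only)."""
    if ordering.col_linkage is None:
        raise ValueError("no column linkage: ordering was built in fixed mode")
    labels = hierarchy.fcluster(ordering.col_linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=sorted(zmat.columns))


def correlate_events_to_insolubility(
    psi: pd.DataFrame,
    insolubility: pd.Series,
    top_n: int = 100,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Rank events by |Spearman rho| of their PSI against protein insolubility.

    Each event uses its pairwise-complete samples; events with fewer than
    ``min_samples`` complete pairs or constant PSI are excluded.  Ties in
    |rho| are broken by event key, the sign of rho is retained, and the
    ``top_n`` events are returned.
    """
    rows = []
    for event, values in psi.iterrows():
        pair = pd.concat([values.rename("psi"), insolubility.rename("ins")], axis=1).dropna()
        if len(pair) < min_samples:
            continue
        if pair["psi"].nunique() < 2 or pair["ins"].nunique() < 2:
            continue
        rho = stats.spearmanr(pair["psi"], pair["ins"]).statistic
        if not np.isfinite(rho):
            continue
        rows.append({"event": event, "rho": float(rho), "n": len(pair)})
    if not rows:
        return pd.DataFrame(columns=["event", "rho", "n", "abs_rho", "rank"])
    df = pd.DataFrame(rows)
    df["abs_rho"] = df["rho"].abs()
    df = df.sort_values(["abs_rho", "event"], ascending=[False, True], kind="mergesort")
    df = df.head(top_n).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
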