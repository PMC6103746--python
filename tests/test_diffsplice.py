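"""Intron clustering, the multinomial usage test, filters and rankings."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicestrat import diffsplice
from splicestrat.io import JunctionRow


def jr(start, end, counts, chrom="chr1", cluster=""):
    return JunctionRow(chrom, start, end, cluster, tuple(counts))


def make_cluster(count_rows, samples=None, start=100):
    rows = [jr(start, start + 500 + i, c) for i, c in enumerate(count_rows)]
    samples = samples or [f"s{i}" for i in range(len(count_rows[0]))]
    counts = pd.DataFrame(
        [r.counts for r in rows], index=[r.key for r in rows], columns=samples, dtype=np.int64
    )
    return diffsplice.IntronCluster("clu_t", tuple(rows), counts)


class TestClusterJunctions:
    def test_shared_donor_groups_and_support_filter(self):
        rows = [jr(100, 600, [30, 10]), jr(100, 900, [15, 5])]  # total 60
        (cluster,) = diffsplice.cluster_junctions(rows, ["s1", "s2"])
        assert cluster.n_introns == 2
        low = [jr(100, 600, [25, 10]), jr(100, 900, [10, 4])]  # total 49
        assert diffsplice.cluster_junctions(low, ["s1", "s2"]) == []

    def test_long_intron_drops_whole_cluster(self):
        rows = [jr(100, 600, [40, 40]), jr(100, 700_000, [40, 40])]
        assert diffsplice.cluster_junctions(rows, ["s1", "s2"]) == []

    def test_singleton_cluster_dropped(self):
        rows = [jr(100, 600, [100, 100])]
        assert diffsplice.cluster_junctions(rows, ["s1", "s2"]) == []

    def test_given_cluster_ids_honored(self):
        rows = [
            jr(100, 600, [40, 40], cluster="clu_1"),
            jr(5000, 5600, [40, 40], cluster="clu_1"),  # no shared coordinate
            jr(9000, 9600, [40, 40], cluster="clu_2"),
        ]
        clusters = diffsplice.cluster_junctions(rows, ["s1", "s2"])
        assert len(clusters) == 1  # clu_2 is a singleton
        assert clusters[0].n_introns == 2

    def test_shared_acceptor_chains_components(self):
        # a-b share an end, b-c share a start: one connected component of 3
        rows = [jr(100, 900, [20, 20]), jr(300, 900, [20, 20]), jr(300, 1200, [20, 20])]
        (cluster,) = diffsplice.cluster_junctions(rows, ["s1", "s2"])
        assert cluster.n_introns == 3


class TestPsiFromCounts:
    def test_shares_within_cluster(self):
        psi = diffsplice.psi_from_counts(make_cluster([[3], [1]]), min_sample_reads=4)
        assert list(psi["s0"]) == pytest.approx([0.75, 0.25])

    def test_zero_count_intron(self):
        psi = diffsplice.psi_from_counts(make_cluster([[0], [5], [5]]), min_sample_reads=10)
        assert list(psi["s0"]) == pytest.approx([0.0, 0.5, 0.5])

    def test_low_coverage_sample_is_missing(self):
        psi = diffsplice.psi_from_counts(make_cluster([[3, 30], [1, 10]]), min_sample_reads=10)
        assert psi["s0"].isna().all()
        assert psi["s1"].notna().all()

    def test_psis_sum_to_one_per_usable_sample(self, default_cohort):
        clusters = diffsplice.cluster_junctions(default_cohort.junctions, default_cohort.samples)
        for cluster in clusters[:20]:
            psi = diffsplice.psi_from_counts(cluster)
            sums = psi.sum(axis=0, skipna=False).dropna()
            assert np.allclose(sums, 1.0)


def oracle_lrt(counts_a, counts_b):
    """Closed-form multinomial log-likelihood ratio, written independently."""
    def ll(n, p):
        return sum(ni * math.log(pi) for ni, pi in zip(n, p) if ni > 0)

    na, nb = np.asarray(counts_a, float), np.asarray(counts_b, float)
    pa, pb = na / na.sum(), nb / nb.sum()
    ps = (na + nb) / (na.sum() + nb.sum())
    return 2.0 * (ll(na, pa) + ll(nb, pb) - ll(na, ps) - ll(nb, ps))


class TestClusterTest:
    def test_identical_profiles_give_p_one(self):
        cluster = make_cluster([[50, 50, 50, 50], [50, 50, 50, 50]])
        p, dpsi, stat = diffsplice.cluster_test(cluster, ["s0", "s1"], ["s2", "s3"])
        assert stat == 0.0
        assert p == 1.0
        assert np.allclose(dpsi, 0.0)

    def test_opposite_usage_is_highly_significant(self):
        a = [[90] * 6 + [10] * 6, [10] * 6 + [90] * 6]
        cluster = make_cluster(a)
        group_a = [f"s{i}" for i in range(6)]
        group_b = [f"s{i}" for i in range(6, 12)]
        p, dpsi, stat = diffsplice.cluster_test(cluster, group_a, group_b)
        assert p < 1e-6
        # statistic matches the independent closed-form oracle on pooled counts
        pooled_a = [90 * 6, 10 * 6]
        pooled_b = [10 * 6, 90 * 6]
        assert stat == pytest.approx(oracle_lrt(pooled_a, pooled_b), rel=1e-12)
        assert dpsi.iloc[0] == pytest.approx(0.8)

    def test_statistic_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 40, size=(3, 8)).tolist()
        cluster = make_cluster(counts)
        a, b = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        p1, _, s1 = diffsplice.cluster_test(cluster, a, b, min_sample_reads=1)
        p2, _, s2 = diffsplice.cluster_test(cluster, b, a, min_sample_reads=1)
        assert s1 >= 0
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_cluster_gives_p_one(self):
        cluster = make_cluster([[50, 50, 50, 50], [0, 0, 0, 0]])
        p, _, stat = diffsplice.cluster_test(cluster, ["s0", "s1"], ["s2", "s3"])
        assert stat == 0.0 and p == 1.0

    def test_too_few_usable_samples_is_error(self):
        cluster = make_cluster([[50, 2, 50, 50], [50, 2, 50, 50]])
        with pytest.raises(ValueError, match="usable"):
            diffsplice.cluster_test(cluster, ["s0", "s1"], ["s2", "s3"])

    def test_sex_stratified_combination(self):
        a = [[90] * 6 + [10] * 6, [10] * 6 + [90] * 6]
        cluster = make_cluster(a)
        strata = {f"s{i}": ("F" if i % 2 else "M") for i in range(12)}
        p = diffsplice.stratified_cluster_test(
            cluster, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)], strata
        )
        assert p < 1e-6


def oracle_bh(pvals):
    """Hand step-up: q_(i) = min_{j>=i} m * p_(j) / j, capped at 1."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


class TestBhFdr:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_examples(self, pvals, expected):
        assert diffsplice.bh_fdr(pvals) == pytest.approx(expected)

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            diffsplice.bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_matches_step_up_oracle(self, pvals):
        assert diffsplice.bh_fdr(pvals) == pytest.approx(oracle_bh(pvals), abs=1e-12)


class TestCallEvents:
    @pytest.fixture()
    def called(self, default_cohort):
        clusters = diffsplice.cluster_junctions(default_cohort.junctions, default_cohort.samples)
        truth = default_cohort.truth
        cases = truth.index[truth["true_class"] == "like-C9"].tolist()
        controls = truth.index[truth["true_class"] == "control"].tolist()
        return clusters, cases, controls

    def test_unfiltered_calls_superset_of_filtered(self, called):
        clusters, cases, controls = called
        filtered = diffsplice.call_events(clusters, {"case": cases}, controls, dpsi_cutoff=0.1)
        unfiltered = diffsplice.call_events(clusters, {"case": cases}, controls, dpsi_cutoff=0.0)
        sig_f = set(filtered["case"].loc[filtered["case"]["significant"], "event"])
        sig_u = set(unfiltered["case"].loc[unfiltered["case"]["significant"], "event"])
        assert sig_f <= sig_u
        assert len(sig_u) > 0

    def test_control_vs_control_split_finds_almost_nothing(self, default_cohort):
        """Splitting the burden-free samples should yield ~no events, the
        analog of comparing neurologically normal against SOD1 cases."""
        clusters = diffsplice.cluster_junctions(default_cohort.junctions, default_cohort.samples)
        truth = default_cohort.truth
        quiet = truth.index[truth["true_class"].isin(["control", "like-control"])].tolist()
        half_a, half_b = quiet[::2], quiet[1::2]
        events = diffsplice.call_events(clusters, {"split": half_a}, half_b)
        n_sig = int(events["split"]["significant"].sum())
        assert n_sig <= 3

    def test_empty_control_group_is_error(self, called):
        clusters, cases, _ = called
        with pytest.raises(ValueError, match="control"):
            diffsplice.call_events(clusters, {"case": cases}, [])


class TestOverlapSets:
    def test_two_set_example(self):
        regions, per_group = diffsplice.overlap_sets({"A": {"a", "b"}, "B": {"b", "c"}})
        lookup = dict(zip(regions["groups"], regions["count"]))
        assert lookup == {"A": 1, "B": 1, "A&B": 1}
        assert per_group.loc["A", "unique"] == 1
        assert per_group.loc["A", "unique_fraction"] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "sets",
        [
            {"A": {"a", "b"}, "B": {"a", "b"}},
            {"A": {"a"}, "B": {"b"}, "C": {"c", "d"}},
            {"A": set("abcdef"), "B": set("defgh"), "C": set("fghij")},
        ],
    )
    def test_region_counts_sum_to_union(self, sets):
        regions, _ = diffsplice.overlap_sets(sets)
        assert regions["count"].sum() == len(set().union(*sets.values()))


class TestZscoreMatrix:
    def test_row_standardization_n_minus_1(self):
        psi = pd.DataFrame({"s1": [0.2], "s2": [0.4], "s3": [0.6]}, index=["e1"])
        z = diffsplice.zscore_matrix(psi)
        assert list(z.loc["e1"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_dropped(self):
        psi = pd.DataFrame(
            {"s1": [0.2, 0.5], "s2": [0.4, 0.5], "s3": [0.6, 0.5]}, index=["e1", "e2"]
        )
        z = diffsplice.zscore_matrix(psi)
        assert list(z.index) == ["e1"]

    def test_missing_cells_excluded_from_row_stats(self):
        psi = pd.DataFrame({"s1": [0.2], "s2": [0.4], "s3": [0.6], "s4": [np.nan]}, index=["e1"])
        z = diffsplice.zscore_matrix(psi)
        assert list(z.loc["e1", ["s1", "s2", "s3"]]) == pytest.approx([-1.0, 0.0, 1.0])
        assert np.isnan(z.loc["e1", "s4"])


class TestOrderAndCluster:
    def test_identical_patients_merge_first(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame(rng.normal(size=(5, 4)), index=[f"e{i}" for i in range(5)],
                         columns=["s1", "s2", "s3", "s4"])
        z["s2"] = z["s1"]
        ordering = diffsplice.order_and_cluster(z, mode="cluster")
        first_merge = ordering.col_linkage[0]
        cols = sorted(z.columns)
        merged = {cols[int(first_merge[0])], cols[int(first_merge[1])]}
        assert merged == {"s1", "s2"}
        assert first_merge[2] == pytest.approx(0.0)

    def test_fixed_order_sorts_by_insolubility_within_subtype(self):
        z = pd.DataFrame(
            np.arange(6, dtype=float).reshape(2, 3),
            index=["e1", "e2"],
            columns=["sample1", "sample2", "sample3"],
        )
        subtype = pd.Series("ALShigh", index=z.columns)
        insol = pd.Series({"sample1": 0.3, "sample2": 0.1, "sample3": 0.2})
        ordering = diffsplice.order_and_cluster(z, mode="fixed", subtype=subtype, insolubility=insol)
        assert ordering.col_order == ["sample2", "sample3", "sample1"]

    def test_block_structure_recovered_at_k2(self):
        rng = np.random.default_rng(1)
        low = rng.normal(-1.0, 0.1, size=(30, 8))
        high = rng.normal(1.0, 0.1, size=(30, 8))
        z = pd.DataFrame(
            np.hstack([low, high]),
            index=[f"e{i}" for i in range(30)],
            columns=[f"L{i}" for i in range(8)] + [f"H{i}" for i in range(8)],
        )
        ordering = diffsplice.order_and_cluster(z, mode="cluster")
        labels = diffsplice.cut_columns(ordering, z, k=2)
        low_labels = {labels[c] for c in labels.index if c.startswith("L")}
        high_labels = {labels[c] for c in labels.index if c.startswith("H")}
        assert len(low_labels) == 1 and len(high_labels) == 1
        assert low_labels != high_labels

    def test_too_small_matrix_is_error(self):
        z = pd.DataFrame({"s1": [0.1], "s2": [0.2]}, index=["e1"])
        with pytest.raises(ValueError):
            diffsplice.order_and_cluster(z)


class TestCorrelateEventsToInsolubility:
    def test_monotone_event_ranks_first(self):
        ins = pd.Series(np.linspace(0.1, 0.9, 10), index=[f"s{i}" for i in range(10)])
        rng = np.random.default_rng(2)
        psi = pd.DataFrame(
            {
                "up": ins.values,                      # perfectly tracks insolubility
                "noise": rng.uniform(size=10),
                "const": np.full(10, 0.5),             # excluded: no variation
            },
            index=ins.index,
        ).T
        out = diffsplice.correlate_events_to_insolubility(psi, ins, top_n=5)
        assert out.iloc[0]["event"] == "up"
        assert out.iloc[0]["rho"] == pytest.approx(1.0)
        assert "const" not in set(out["event"])

    def test_ties_broken_by_event_key(self):
        ins = pd.Series(np.linspace(0.1, 0.9, 8), index=[f"s{i}" for i in range(8)])
        psi = pd.DataFrame({"b_ev": ins.values, "a_ev": ins.values}, index=ins.index).T
        out = diffsplice.correlate_events_to_insolubility(psi, ins)
        assert list(out["event"]) == ["a_ev", "b_ev"]
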