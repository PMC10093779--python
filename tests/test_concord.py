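import numpy as np
import pandas as pd
import pytest

from scnakit.concord import (
    SegmentTable,
    binned_median_cn,
    cluster_samples,
    correlation_matrix,
    window_concordance,
)


def _cn(states):
    return np.asarray(states, dtype=np.int64)


class TestWindowConcordance:
    def test_identical_samples_give_one(self, small_bins):
        cn = _cn([(1, 1)] * 8 + [(2, 0), (3, 1)])
        res = window_concordance(cn, cn, small_bins)
        assert res.prop_identical == 1.0
        assert res.n_windows_considered == 2

    def test_enumerated_example(self):
        from scnakit.genome import make_bins

        bins = make_bins({"chr1": 3_000_000}, 1_000_000)
        a = _cn([(1, 1), (2, 1), (2, 0)])
        b = _cn([(1, 1), (2, 1), (1, 1)])
        res = window_concordance(a, b, bins)
        # qualifying windows: bins 2 and 3; identical only in bin 2
        assert res.n_windows_considered == 2
        assert res.prop_identical == pytest.approx(0.5)

    def test_all_diploid_undefined_not_zero(self, small_bins):
        cn = _cn([(1, 1)] * 10)
        res = window_concordance(cn, cn, small_bins)
        assert res.prop_identical is None
        assert not res.defined
        assert res.n_windows_considered == 0

    def test_unordered_pair_comparison(self, small_bins):
        a = _cn([(2, 0)] + [(1, 1)] * 9)
        b = _cn([(0, 2)] + [(1, 1)] * 9)
        res = window_concordance(a, b, small_bins)
        assert res.prop_identical == 1.0

    def test_wgd_profile_halved_against_undoubled_partner(self, small_bins):
        base = _cn([(2, 1)] * 5 + [(1, 1)] * 5)
        doubled = base * 2
        res = window_concordance(base, doubled, small_bins,
                                 wgd_a=False, wgd_b=True)
        assert res.prop_identical == 1.0

    def test_total_mode(self, small_bins):
        a = _cn([(2, 0)] + [(1, 1)] * 9)
        b = _cn([(1, 1)] * 10)
        b[0] = (0, 2)
        res = window_concordance(a, b, small_bins, mode="total")
        assert res.prop_identical == 1.0


class TestBinnedMedianCn:
    def _table(self, rows):
        return SegmentTable("s", pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn"]))

    def test_single_segment_covers_chromosome(self):
        seg = self._table([("chr1", 0, 10_000, 3)])
        _, values = binned_median_cn(seg, {"chr1": 10_000}, bin_size=1000)
        assert np.all(values == 3)

    def test_half_covered_bin_takes_midpoint(self):
        seg = self._table([("chr1", 0, 500, 2), ("chr1", 500, 1000, 4)])
        _, values = binned_median_cn(seg, {"chr1": 1000}, bin_size=1000)
        assert values[0] == pytest.approx(3.0)

    def test_uncovered_bin_is_missing(self):
        seg = self._table([("chr1", 0, 1000, 2)])
        _, values = binned_median_cn(seg, {"chr1": 3000}, bin_size=1000)
        assert values[0] == 2
        assert np.isnan(values[1]) and np.isnan(values[2])

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            self._table([("chr1", 0, 1000, 2), ("chr1", 500, 1500, 3)])

    def test_segment_outside_genome_rejected(self):
        seg = self._table([("chr1", 0, 99_999, 2)])
        with pytest.raises(ValueError, match="outside"):
            binned_median_cn(seg, {"chr1": 10_000}, bin_size=1000)


class TestCorrelationMatrix:
    def test_self_correlation_unity(self, rng):
        v = rng.normal(size=200)
        corr = correlation_matrix({"a": v, "b": rng.normal(size=200)})
        assert corr.loc["a", "a"] == 1.0

    def test_affine_invariance(self, rng):
        v = rng.normal(size=200)
        corr = correlation_matrix({"a": v, "b": 2 * v + 1})
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_permutation_null_low_correlation(self, rng):
        v = rng.normal(size=10_000)
        w = rng.permutation(v)
        corr = correlation_matrix({"a": v, "b": w})
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_matches_textbook_pearson(self, rng):
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        corr = correlation_matrix({"x": x, "y": y})
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert corr.loc["x", "y"] == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_sample_warns_and_is_missing(self, rng):
        with pytest.warns(UserWarning, match="zero variance"):
            corr = correlation_matrix({"a": rng.normal(size=200),
                                       "b": np.full(200, 2.0)})
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0

    def test_pairwise_complete_handling(self, rng):
        v = rng.normal(size=300)
        w = v + 0.1 * rng.normal(size=300)
        w2 = w.copy()
        w2[:50] = np.nan
        corr = correlation_matrix({"a": v, "b": w2})
        expected = np.corrcoef(v[50:], w[50:])[0, 1]
        assert corr.loc["a", "b"] == pytest.approx(expected)


class TestClusterSamples:
    def test_identical_pair_plus_outlier(self, rng):
        v = rng.normal(size=300)
        u = rng.normal(size=300)
        corr = correlation_matrix({"a": v, "b": v.copy(), "c": u})
        labels, _, newick = cluster_samples(corr, threshold=0.5)
        assert labels["a"] == labels["b"] != labels["c"]
        assert newick.endswith(";")

    def test_threshold_zero_separates_distinct_samples(self, rng):
        vecs = {k: rng.normal(size=300) for k in "abc"}
        corr = correlation_matrix(vecs)
        labels, _, _ = cluster_samples(corr, threshold=0.0)
        assert len(set(labels.values())) == 3

    def test_related_samples_cluster_over_seeds(self, genome_bins):
        """Clone pairs sharing truncal events group together against an
        unrelated sample, across seeds."""
        from scnakit.simulate import simulate_clonal_truth

        for seed in range(10):
            rel = simulate_clonal_truth(
                genome_bins, 2, 12, 3, 0.0, 0.6, seed=seed, min_event_bins=3)
            unrel = simulate_clonal_truth(
                genome_bins, 1, 12, 0, 0.0, 0.6, seed=1000 + seed, min_event_bins=3)
            vecs = {
                "rel_a": rel.clone_profiles["clone_1"].sum(axis=1).astype(float),
                "rel_b": rel.clone_profiles["clone_2"].sum(axis=1).astype(float),
                "other": unrel.clone_profiles["clone_1"].sum(axis=1).astype(float),
            }
            corr = correlation_matrix(vecs)
            labels, _, _ = cluster_samples(corr, threshold=0.6)
            assert labels["rel_a"] == labels["rel_b"] != labels["other"]


def test_concordance_decreases_with_private_events(genome_bins):
    """Identical-window concordance between founder and derived clone is
    monotone non-increasing in the number of private events (strictly
    decreasing overall), across seeds."""
    from scnakit.simulate import simulate_clonal_truth

    for seed in range(10):
        props = []
        for k in (1, 4, 8):
            truth = simulate_clonal_truth(
                genome_bins, 2, 10, k, 0.0, 0.6, seed=seed, min_event_bins=2)
            res = window_concordance(
                truth.clone_profiles["clone_1"], truth.clone_profiles["clone_2"],
                genome_bins)
            props.append(res.prop_identical)
        assert props[0] >= props[1] >= props[2]
        assert props[0] > props[2]
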