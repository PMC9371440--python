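"""Fine-time binning, pseudobulk profiles, onset estimation."""

import numpy as np
import pytest
import scipy.sparse as sp

import embryochron as ec
from embryochron.chrono import _bin_edges


class TestFineBins:
    def test_floor_rule(self):
        assert ec.fine_bins(np.array([1.51]), 5.0)[0] == 18  # floor(90.6/5)

    def test_edges_and_closure(self):
        bins = ec.fine_bins(np.array([0.0, 2.0, 2.1, -0.1]), 5.0, (0.0, 2.0))
        assert bins[0] == 0
        assert bins[1] == 23          # range end closes into the last bin
        assert bins[2] == -1 and bins[3] == -1

    def test_bad_increment(self):
        with pytest.raises(ValueError):
            ec.fine_bins(np.array([1.0]), -5.0)
        with pytest.raises(ValueError):
            ec.fine_bins(np.array([1.0]), 7.0, (0.0, 2.0))  # does not divide


class TestPseudobulk:
    def test_normalized_log_arithmetic(self):
        # one bin; feature sums [5, 5] over two cells, bin total 10
        X = sp.csr_matrix(np.array([[2, 3], [3, 2]]))
        prof = ec.pseudobulk_profile(X, ["a", "b"], np.array([0, 0]),
                                     increment_min=120.0, range_h=(0.0, 2.0))
        assert prof.values[0, 0] == pytest.approx(np.log(1 + 5e3))

    def test_absent_feature_is_log1(self):
        X = sp.csr_matrix(np.array([[2, 0], [3, 0]]))
        prof = ec.pseudobulk_profile(X, ["a", "b"], np.array([0, 0]),
                                     increment_min=120.0, range_h=(0.0, 2.0))
        assert prof.values[1, 0] == pytest.approx(0.0)

    def test_cell_order_invariance(self, rng):
        X = rng.poisson(2.0, size=(30, 4))
        bins = rng.integers(0, 6, size=30)
        p1 = ec.pseudobulk_profile(sp.csr_matrix(X), list("abcd"), bins,
                                   20.0, (0.0, 2.0))
        perm = rng.permutation(30)
        p2 = ec.pseudobulk_profile(sp.csr_matrix(X[perm]), list("abcd"),
                                   bins[perm], 20.0, (0.0, 2.0))
        np.testing.assert_allclose(p1.values, p2.values)

    def test_empty_bins_are_missing_not_zero(self):
        X = sp.csr_matrix(np.array([[1, 2]]))
        prof = ec.pseudobulk_profile(X, ["a", "b"], np.array([0]),
                                     increment_min=60.0, range_h=(0.0, 2.0))
        assert np.isfinite(prof.values[:, 0]).all()
        assert np.isnan(prof.values[:, 1]).all()

    def test_all_empty_errors(self):
        X = sp.csr_matrix(np.array([[1, 2]]))
        with pytest.raises(ValueError):
            ec.pseudobulk_profile(X, ["a", "b"], np.array([-1]), 60.0, (0.0, 2.0))

    def test_window_width_bins_reproduce_per_window_averages(self, rng):
        """Pseudobulk on bins as wide as a whole collection window equals a
        direct per-window normalized average (oracle identity)."""
        X = rng.poisson(3.0, size=(50, 5))
        ages = rng.uniform(0, 2, size=50)
        bins = ec.fine_bins(ages, 120.0, (0.0, 2.0))
        prof = ec.pseudobulk_profile(sp.csr_matrix(X), list("abcde"), bins,
                                     120.0, (0.0, 2.0))
        sums = X.sum(axis=0).astype(float)
        expected = np.log(1 + sums * 1e4 / sums.sum())
        np.testing.assert_allclose(prof.values[:, 0], expected)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        prof = ec.TemporalProfile(["a"], _bin_edges(60.0, (0, 5)),
                                  np.full((1, 5), 2.0))
        np.testing.assert_allclose(ec.smooth_profile(prof, 3).values, 2.0)

    def test_window_one_is_identity(self, rng):
        vals = rng.normal(size=(3, 8))
        prof = ec.TemporalProfile(list("abc"), _bin_edges(60.0, (0, 8)), vals)
        np.testing.assert_allclose(ec.smooth_profile(prof, 1).values, vals)

    def test_centered_average(self):
        prof = ec.TemporalProfile(["a"], _bin_edges(60.0, (0, 3)),
                                  np.array([[0.0, 3.0, 0.0]]))
        assert ec.smooth_profile(prof, 3).values[0, 1] == pytest.approx(1.0)

    def test_missing_bins_skipped(self):
        prof = ec.TemporalProfile(["a"], _bin_edges(60.0, (0, 3)),
                                  np.array([[1.0, np.nan, 3.0]]))
        sm = ec.smooth_profile(prof, 3)
        assert sm.values[0, 1] == pytest.approx(2.0)

    def test_even_window_rejected(self):
        prof = ec.TemporalProfile(["a"], _bin_edges(60.0, (0, 3)),
                                  np.zeros((1, 3)))
        with pytest.raises(ValueError):
            ec.smooth_profile(prof, 2)


class TestAggregateRegions:
    def test_single_region_equals_peak_profile(self, rng):
        X = sp.csr_matrix(rng.poisson(2.0, size=(40, 3)))
        bins = rng.integers(0, 4, size=40)
        peak = ec.pseudobulk_profile(X, ["p0", "p1", "p2"], bins, 30.0,
                                     (0.0, 2.0), log=False)
        gene = ec.aggregate_region_accessibility(
            X, ["p0", "p1", "p2"], {"g": ["p1"]}, bins, 30.0, (0.0, 2.0),
            log=False)
        np.testing.assert_allclose(gene.values[0], peak.values[1])

    def test_two_identical_regions_double(self, rng):
        counts = rng.poisson(2.0, size=(40, 1))
        X = sp.csr_matrix(np.hstack([counts, counts]))
        bins = np.zeros(40, dtype=int)
        gene = ec.aggregate_region_accessibility(
            X, ["p0", "p1"], {"g": ["p0", "p1"]}, bins, 120.0, (0.0, 2.0),
            log=False)
        single = ec.aggregate_region_accessibility(
            X, ["p0", "p1"], {"g": ["p0"]}, bins, 120.0, (0.0, 2.0), log=False)
        np.testing.assert_allclose(gene.values, 2 * single.values)

    def test_hand_summed_toy(self):
        X = sp.csr_matrix(np.array([[4, 1, 0], [0, 1, 4]]))
        bins = np.array([0, 1])
        gene = ec.aggregate_region_accessibility(
            X, ["p0", "p1", "p2"], {"g": ["p0", "p1"]}, bins, 60.0, (0.0, 2.0),
            scale=10.0, log=False)
        # bin 0 total 5 -> normalized [8, 2, 0]; bin 1 total 5 -> [0, 2, 8]
        np.testing.assert_allclose(gene.values[0], [10.0, 2.0])

    def test_empty_region_set_drops_gene(self, rng):
        X = sp.csr_matrix(rng.poisson(1.0, size=(10, 2)))
        with pytest.warns(UserWarning, match="dropped"):
            out = ec.aggregate_region_accessibility(
                X, ["p0", "p1"], {"g": ["absent"], "h": ["p0"]},
                np.zeros(10, dtype=int), 120.0, (0.0, 2.0))
        assert out.feature_ids == ["h"]


class TestOnset:
    def test_step_function(self):
        edges = _bin_edges(30.0, (0.0, 2.0))
        vals = np.array([0, 0, 1, 1], dtype=float)
        assert ec.onset_time(vals, edges) == pytest.approx(1.0)

    def test_monotone_decreasing_onsets_at_start(self):
        edges = _bin_edges(30.0, (0.0, 2.0))
        assert ec.onset_time(np.array([4.0, 3.0, 2.0, 1.0]), edges) == 0.0

    def test_all_zero_errors(self):
        edges = _bin_edges(30.0, (0.0, 2.0))
        with pytest.raises(ValueError):
            ec.onset_time(np.zeros(4), edges)

    def test_logistic_onset_recovered_within_one_bin(self):
        k = ec.KineticParams("g", "zygotic", onset_h=1.2, rate=8.0, amplitude=1.0)
        edges = _bin_edges(5.0, (0.0, 2.0))
        centers = 0.5 * (edges[:-1] + edges[1:])
        vals = ec.expression_mean(k, centers)
        assert abs(ec.onset_time(vals, edges) - 1.2) <= 5.0 / 60 + 1e-9


class TestTemporalClusters:
    def test_two_planted_onset_groups_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score
        edges = _bin_edges(5.0, (0.0, 3.0))
        centers = 0.5 * (edges[:-1] + edges[1:])
        rows, truth = [], []
        for i in range(30):
            onset = 0.5 if i < 15 else 1.5
            truth.append(0 if i < 15 else 1)
            k = ec.KineticParams(f"g{i}", "zygotic", onset_h=onset, rate=6.0,
                                 amplitude=1.0)
            rows.append(ec.expression_mean(k, centers)
                        + rng.normal(0, 0.01, size=len(centers)))
        prof = ec.TemporalProfile([f"g{i}" for i in range(30)], edges,
                                  np.array(rows))
        labels = ec.temporal_gene_clusters(prof, k=2, seed=0)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
        # cluster 1 must be the earlier-onset group
        assert set(labels.iloc[:15]) == {1}

    def test_k_exceeding_features_errors(self):
        prof = ec.TemporalProfile(["a", "b"], _bin_edges(60.0, (0, 3)),
                                  np.random.default_rng(0).normal(size=(2, 3)))
        with pytest.raises(ValueError):
            ec.temporal_gene_clusters(prof, k=3)

    def test_identical_features_degenerate(self):
        prof = ec.TemporalProfile(["a", "b", "c"], _bin_edges(60.0, (0, 4)),
                                  np.tile([0.0, 1.0, 2.0, 3.0], (3, 1)))
        with pytest.raises(ValueError):
            ec.temporal_gene_clusters(prof, k=2, smooth_window=1)
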