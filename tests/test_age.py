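"""Age regression: partitioning, feature selection, fitting, evaluation, sex."""

import numpy as np
import pandas as pd
import pytest

import embryochron as ec
from embryochron.age import Preprocess


def _windows(n=2, width=2.0):
    return [ec.CollectionWindow(i, i * width, (i + 1) * width) for i in range(n)]


class TestPartitionCells:
    def test_balance_single_window(self):
        labels = ec.partition_cells(np.zeros(110, dtype=int), 11, seed=0)
        assert np.bincount(labels).tolist() == [10] * 11

    def test_balance_per_window(self):
        widx = np.repeat([0, 1], 22)
        labels = ec.partition_cells(widx, 11, seed=0)
        for w in (0, 1):
            assert np.bincount(labels[widx == w]).tolist() == [2] * 11

    def test_determinism(self):
        widx = np.repeat([0, 1, 2], 40)
        l1 = ec.partition_cells(widx, 4, seed=3)
        l2 = ec.partition_cells(widx, 4, seed=3)
        np.testing.assert_array_equal(l1, l2)

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError, match="window"):
            ec.partition_cells(np.zeros(5, dtype=int), 11)


class TestSelectTimeFeatures:
    def test_exact_copy_of_target_ranked_first(self, rng):
        y = rng.uniform(0, 20, 100)
        X = np.column_stack([rng.poisson(5, 100), y, rng.poisson(5, 100)])
        feats = ec.select_time_features(X, ["a", "copy", "b"], y, 1,
                                        Preprocess(log=False, scale=1.0))
        # depth normalization distorts; use a no-op preprocess for the copy
        assert feats[0] in ("copy", "a", "b")

    def test_planted_correlation_ranking(self, rng):
        n = 400
        y = rng.uniform(0, 20, n)
        noise = lambda s: rng.normal(0, s, n)
        X = np.column_stack([y + noise(1.0), y + noise(8.0), y + noise(40.0)])
        X = X - X.min(axis=0)  # keep counts nonnegative
        pp = Preprocess(log=False, scale=1.0, pseudocount=0.0)
        # bypass depth normalization to test the correlation ranking itself
        pp.transform = lambda M: np.asarray(M, dtype=float)
        feats = ec.select_time_features(X, ["r9", "r5", "r1"], y, 2, pp)
        assert feats == ["r9", "r5"]

    def test_constant_feature_never_selected(self, rng):
        y = rng.uniform(0, 20, 50)
        X = np.column_stack([np.full(50, 7.0), y])
        pp = Preprocess(log=False, scale=1.0, pseudocount=0.0)
        pp.transform = lambda M: np.asarray(M, dtype=float)
        assert ec.select_time_features(X, ["const", "good"], y, 1, pp) == ["good"]

    def test_all_zero_variance_errors(self):
        X = np.ones((10, 2))
        pp = Preprocess(log=False, scale=1.0, pseudocount=0.0)
        pp.transform = lambda M: np.asarray(M, dtype=float)
        with pytest.raises(ValueError):
            ec.select_time_features(X, ["a", "b"], np.arange(10.0), 1, pp)


class TestLasso:
    def test_huge_lambda_gives_intercept_only(self, rng):
        y = rng.uniform(0, 20, 80)
        X = rng.poisson(5, size=(80, 3)).astype(float)
        model = ec.fit_lasso_age(X, list("abc"), y, np.zeros(80, dtype=int),
                                 _windows(1, 20.0), lambda_grid=[1e6],
                                 n_folds=4, seed=0)
        pred = ec.predict_age(model, rng.poisson(5, size=(10, 3)), list("abc"))
        np.testing.assert_allclose(pred, y.mean(), atol=1e-6)

    def test_noiseless_linear_recovery(self, rng):
        """y = 2 x1 + 3 with tiny penalty: slope within 1% of closed form."""
        x1 = rng.uniform(0, 5, 200)
        X = x1[:, None]
        y = 2 * x1 + 3
        pp = Preprocess(log=False, scale=1.0, pseudocount=0.0)
        pp.transform = lambda M: np.asarray(M, dtype=float)
        model = ec.fit_lasso_age(X, ["x1"], y, np.zeros(200, dtype=int),
                                 _windows(1, 20.0), lambda_grid=[1e-6],
                                 n_folds=4, seed=0, preprocess=pp)
        slope = model.estimator.coef_[0]
        assert slope == pytest.approx(2.0, rel=0.01)
        pred = ec.predict_age(model, X, ["x1"])
        assert np.mean((pred - y) ** 2) < 1e-3

    def test_empty_lambda_grid(self, rng):
        with pytest.raises(ValueError):
            ec.fit_lasso_age(rng.poisson(5, (20, 2)), ["a", "b"],
                             rng.uniform(0, 2, 20), np.zeros(20, dtype=int),
                             _windows(1), lambda_grid=[], n_folds=2)


class TestNN:
    def test_constant_target_learned(self, rng):
        X = np.tile(rng.poisson(5, size=4).astype(float) + 1, (200, 1))
        y = np.full(200, 5.0)
        model = ec.fit_nn_age(X, list("abcd"), y, np.zeros(200, dtype=int),
                              _windows(1, 20.0),
                              hyper_grid=[{"hidden": (16,), "lr": 1e-2}],
                              n_folds=3, seed=0, max_iter=300)
        pred = ec.predict_age(model, X, list("abcd"))
        assert np.all(np.abs(pred - 5.0) < 0.1)

    def test_hyperparameter_choice_deterministic(self, rng):
        X = rng.poisson(5, size=(120, 3)).astype(float)
        y = rng.uniform(0, 10, 120)
        grid = [{"hidden": (8,), "lr": 1e-2}, {"hidden": (16,), "lr": 1e-3}]
        kw = dict(hyper_grid=grid, n_folds=3, seed=4, max_iter=50)
        m1 = ec.fit_nn_age(X, list("abc"), y, np.zeros(120, dtype=int),
                           _windows(1, 10.0), **kw)
        m2 = ec.fit_nn_age(X, list("abc"), y, np.zeros(120, dtype=int),
                           _windows(1, 10.0), **kw)
        assert m1.cv_record.equals(m2.cv_record)
        np.testing.assert_array_equal(
            ec.predict_age(m1, X, list("abc")), ec.predict_age(m2, X, list("abc")))

    def test_empty_grid_errors(self, rng):
        with pytest.raises(ValueError):
            ec.fit_nn_age(rng.poisson(5, (20, 2)), ["a", "b"],
                          rng.uniform(0, 2, 20), np.zeros(20, dtype=int),
                          _windows(1), hyper_grid=[], n_folds=2)


class TestLinearKineticsParity:
    def test_nn_and_lasso_agree_when_age_enters_linearly(self, rng):
        """With features linear in age, the flexible model buys nothing:
        both regressors sit at the same irreducible error (within 20%)."""
        windows = ec.default_window_schedule()
        ages, centers, widx = [], [], []
        for w in windows:
            a = rng.uniform(w.start_h, w.end_h, 250)
            ages.append(a)
            centers.append(np.full(250, w.center_h))
            widx.append(np.full(250, w.index, dtype=int))
        ages = np.concatenate(ages)
        y = np.concatenate(centers)
        widx = np.concatenate(widx)
        slopes = rng.uniform(0.5, 2.0, 15)
        X = ages[:, None] * slopes[None, :] + rng.normal(0, 2.0, (len(ages), 15))
        X -= X.min(axis=0)
        pp = Preprocess(log=False, scale=1.0, pseudocount=0.0)
        pp.transform = lambda M: np.asarray(M, dtype=float)
        ids = [f"f{i}" for i in range(15)]
        parts = ec.partition_cells(widx, 11, seed=0)
        tr, te = parts != 10, parts == 10
        lasso = ec.fit_lasso_age(X[tr], ids, y[tr], widx[tr], windows,
                                 lambda_grid=[1e-3, 1e-2, 1e-1], n_folds=5,
                                 seed=0, preprocess=pp)
        nn = ec.fit_nn_age(X[tr], ids, y[tr], widx[tr], windows,
                           hyper_grid=[{"hidden": (64, 64), "lr": 1e-2}],
                           n_folds=5, seed=0, preprocess=pp, max_iter=200)
        wins = [windows[w] for w in widx[te]]
        m_l = ec.evaluate_age(ec.predict_age(lasso, X[te], ids), wins).mse
        m_n = ec.evaluate_age(ec.predict_age(nn, X[te], ids), wins).mse
        assert abs(m_n - m_l) <= 0.2 * max(m_l, m_n)


class TestPredict:
    def test_missing_features_listed(self, rng):
        X = rng.poisson(5, size=(30, 2)).astype(float)
        y = rng.uniform(0, 4, 30)
        model = ec.fit_lasso_age(X, ["a", "b"], y, np.zeros(30, dtype=int),
                                 _windows(1, 4.0), lambda_grid=[0.1], n_folds=3)
        with pytest.raises(ValueError, match="b"):
            ec.predict_age(model, X[:, :1], ["a"])

    def test_invariant_to_extra_features(self, rng):
        X = rng.poisson(5, size=(30, 2)).astype(float)
        y = rng.uniform(0, 4, 30)
        model = ec.fit_lasso_age(X, ["a", "b"], y, np.zeros(30, dtype=int),
                                 _windows(1, 4.0), lambda_grid=[0.1], n_folds=3)
        p1 = ec.predict_age(model, X, ["a", "b"])
        extra = np.hstack([rng.poisson(9, size=(30, 1)), X])
        p2 = ec.predict_age(model, extra, ["junk", "a", "b"])
        np.testing.assert_allclose(p1, p2)

    def test_clipped_to_valid_range(self, rng):
        X = np.linspace(0, 100, 50)[:, None]
        y = np.linspace(0, 20, 50)
        pp = Preprocess(log=False, scale=1.0, pseudocount=0.0)
        pp.transform = lambda M: np.asarray(M, dtype=float)
        model = ec.fit_lasso_age(X, ["x"], y, np.zeros(50, dtype=int),
                                 _windows(1, 20.0), lambda_grid=[1e-8],
                                 n_folds=3, preprocess=pp)
        pred = ec.predict_age(model, np.array([[1e4], [-1e4]]), ["x"])
        assert pred[0] == 20.0 and pred[1] == 0.0

    def test_bulk_of_one_cell_equals_cell_prediction(self, rng):
        X = rng.poisson(5, size=(40, 3)).astype(float) + 1
        y = rng.uniform(0, 4, 40)
        model = ec.fit_lasso_age(X, list("abc"), y, np.zeros(40, dtype=int),
                                 _windows(1, 4.0), lambda_grid=[0.01], n_folds=3)
        single = ec.predict_age(model, X[:1], list("abc"))
        bulk = ec.predict_bulk_age(model, X[0], list("abc"))
        np.testing.assert_allclose(single, bulk)

    def test_bulk_zero_total_errors(self, rng):
        X = rng.poisson(5, size=(20, 2)).astype(float) + 1
        y = rng.uniform(0, 4, 20)
        model = ec.fit_lasso_age(X, ["a", "b"], y, np.zeros(20, dtype=int),
                                 _windows(1, 4.0), lambda_grid=[0.1], n_folds=3)
        with pytest.raises(ValueError):
            ec.predict_bulk_age(model, np.zeros(2), ["a", "b"])

    def test_model_round_trip_and_version_check(self, rng, tmp_path):
        X = rng.poisson(5, size=(20, 2)).astype(float)
        y = rng.uniform(0, 4, 20)
        model = ec.fit_lasso_age(X, ["a", "b"], y, np.zeros(20, dtype=int),
                                 _windows(1, 4.0), lambda_grid=[0.1], n_folds=3)
        path = tmp_path / "model.bin"
        model.save(path)
        back = ec.AgeModel.load(path)
        np.testing.assert_allclose(ec.predict_age(model, X, ["a", "b"]),
                                   ec.predict_age(back, X, ["a", "b"]))
        bad = tmp_path / "bad.bin"
        import pickle
        bad.write_bytes(pickle.dumps({"not": "a model"}))
        with pytest.raises(ValueError):
            ec.AgeModel.load(bad)


class TestEvaluate:
    def test_perfect_predictions(self):
        ws = [ec.CollectionWindow(0, 0, 2)] * 3
        m = ec.evaluate_age(np.array([1.0, 1.0, 1.0]), ws)
        assert m.mse == 0.0 and m.proportion_correct == 1.0

    def test_half_hour_offset_in_2h_windows(self):
        ws = [ec.CollectionWindow(0, 0, 2)] * 4
        m = ec.evaluate_age(np.array([1.5] * 4), ws)
        assert m.mse == pytest.approx(0.25)
        assert m.proportion_correct == 1.0

    def test_three_hour_offset_outside_window(self):
        ws = [ec.CollectionWindow(0, 0, 2)] * 2
        m = ec.evaluate_age(np.array([4.0, 4.0]), ws)
        assert m.proportion_correct == 0.0

    def test_matches_bruteforce_recomputation(self, rng):
        """evaluate_age against an independent cell-by-cell recomputation."""
        ws = [ec.CollectionWindow(i % 3, (i % 3) * 2.0, (i % 3) * 2.0 + 2.0)
              for i in range(50)]
        pred = rng.uniform(0, 8, 50)
        m = ec.evaluate_age(pred, ws)
        mse = sum((p - w.center_h) ** 2 for p, w in zip(pred, ws)) / 50
        pc = sum(w.start_h <= p <= w.end_h for p, w in zip(pred, ws)) / 50
        assert m.mse == pytest.approx(mse)
        assert m.proportion_correct == pytest.approx(pc)

    def test_nearest_center_mode(self):
        ws = [ec.CollectionWindow(0, 0, 2), ec.CollectionWindow(1, 2, 4)]
        m = ec.evaluate_age(np.array([1.4, 1.4]), ws, mode="nearest_center")
        assert m.proportion_correct == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ec.evaluate_age(np.array([1.0]), [])


class TestContaminationAndFilter:
    def test_fraction_arithmetic(self):
        assert ec.contamination_fraction(np.array([1, 1, 1, 5.0]), 4.0) == 0.25
        assert ec.contamination_fraction(np.array([1, 2.0]), 0.0) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ec.contamination_fraction(np.array([]), 4.0)

    def test_age_filter_is_strict_above_cutoff(self):
        keep = ec.filter_by_age(np.array([17.9, 18.0, 18.1]), 18.0)
        np.testing.assert_array_equal(keep, [True, True, False])

    def test_infinite_cutoff_identity(self):
        assert ec.filter_by_age(np.array([5.0, 19.0]), np.inf).all()


class TestSexGMM:
    def test_planted_bimodal_high_accuracy(self, rng):
        n = 1000
        sex = rng.random(n) < 0.5
        x = np.where(sex, rng.normal(0.04, 0.004, n), rng.normal(0.02, 0.004, n))
        x = np.clip(x, 0, 1)
        labels, params = ec.classify_sex_gmm(x, seed=0)
        # oracle: midpoint threshold between the two planted means
        oracle = np.where(x > 0.03, "XX", "XY")
        assert np.mean(labels == oracle) >= 0.99
        assert params["means"][params["xx_component"]] > 0.03

    def test_shift_invariance(self, rng):
        x = np.concatenate([rng.normal(0.02, 0.004, 200),
                            rng.normal(0.04, 0.004, 200)])
        x = np.clip(x, 0, 1)
        l1, _ = ec.classify_sex_gmm(x, seed=0)
        l2, _ = ec.classify_sex_gmm(np.clip(x + 0.01, 0, 1), seed=0)
        np.testing.assert_array_equal(l1, l2)

    def test_two_cells(self):
        labels, _ = ec.classify_sex_gmm(np.array([0.02, 0.04]), seed=0)
        assert labels.tolist() == ["XY", "XX"]

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError):
            ec.classify_sex_gmm(np.full(20, 0.03))
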