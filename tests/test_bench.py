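"""Benchmark protocol: MLR diagnostics, ML fits, CV, calibration, ablation."""

import numpy as np
import pandas as pd
import pytest

from acidbase import bench


def _linear_frame(n=120, p=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    beta = np.arange(1, p + 1, dtype=float)
    y = pd.Series(X.to_numpy() @ beta + rng.normal(0, noise, n), name="y")
    return X, y


class TestMLR:
    def test_exact_linear_data_fits_perfectly(self):
        X, y = _linear_frame(noise=0.0)
        report = bench.fit_mlr(X, y)
        assert report.r2 == pytest.approx(1.0, abs=1e-12)
        assert report.adjusted_r2 == pytest.approx(1.0, abs=1e-12)
        assert report.rmse == pytest.approx(0.0, abs=1e-9)
        for j, name in enumerate(X.columns):
            c = report.coefficients[name]
            assert c["coef"] == pytest.approx(j + 1, abs=1e-9)
            assert c["ci_low"] <= c["coef"] <= c["ci_high"]

    def test_r2_equals_one_minus_sse_over_sst(self):
        X, y = _linear_frame(noise=0.7, seed=3)
        report = bench.fit_mlr(X, y)
        pred = bench.predict_with(report, X)
        sse = np.sum((y - pred) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert report.r2 == pytest.approx(1 - sse / sst, abs=1e-12)
        assert report.adjusted_r2 <= report.r2

    def test_durbin_watson_matches_quotient_formula(self):
        X, y = _linear_frame(noise=0.5, seed=4)
        report = bench.fit_mlr(X, y)
        resid = np.asarray(y) - bench.predict_with(report, X)
        dw = np.sum(np.diff(resid) ** 2) / np.sum(resid**2)
        assert report.durbin_watson == pytest.approx(dw, abs=1e-9)

    def test_alternating_residuals_push_durbin_watson_to_four(self):
        # the quotient's closed form on (1,-1,1,-1,...) is 4(n-1)/n
        from statsmodels.stats.stattools import durbin_watson

        resid = np.tile([1.0, -1.0], 500)
        assert durbin_watson(resid) == pytest.approx(4 * 999 / 1000, abs=1e-12)

    def test_single_predictor_importance_is_one(self):
        X, y = _linear_frame(p=1, noise=0.2, seed=5)
        report = bench.fit_mlr(X, y)
        assert report.predictor_importance["x0"] == pytest.approx(1.0)

    def test_importance_shares_sum_to_one(self):
        X, y = _linear_frame(p=4, noise=0.5, seed=6)
        report = bench.fit_mlr(X, y)
        assert sum(report.predictor_importance.values()) == pytest.approx(1.0, abs=1e-9)

    def test_rank_deficient_design_rejected(self):
        X, y = _linear_frame(noise=0.1)
        X = X.assign(dup=X["x0"] * 2.0)
        with pytest.raises(np.linalg.LinAlgError):
            bench.fit_mlr(X, y)

    def test_too_few_rows_rejected(self):
        X, y = _linear_frame(n=4, p=3)
        with pytest.raises(ValueError):
            bench.fit_mlr(X, y)


class TestML:
    def test_target_leaked_as_feature_is_found(self):
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(size=400))
        X = pd.DataFrame({"leak": y, "noise": rng.normal(size=400)})
        report = bench.fit_ml("xgb", X, y, seed=0)
        assert report.r2 > 0.99

    def test_pure_noise_target_is_not_explained(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(2000, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=2000))
        report = bench.fit_ml("xgb", X, y, seed=0)
        assert report.r2 <= 0.1

    def test_same_seed_gives_identical_reports(self):
        X, y = _linear_frame(n=300, noise=0.3, seed=7)
        a = bench.fit_ml("rf", X, y, seed=11)
        b = bench.fit_ml("rf", X, y, seed=11)
        a_d, b_d = a.to_dict(), b.to_dict()
        assert a_d == b_d

    def test_unknown_algorithm_rejected(self):
        X, y = _linear_frame()
        with pytest.raises(ValueError):
            bench.fit_ml("mlp", X, y)

    def test_svr_reports_permutation_importance(self):
        X, y = _linear_frame(n=300, noise=0.3, seed=8)
        report = bench.fit_ml("svr", X, y, seed=0)
        imp = report.importance["permutation"]
        # strongest true coefficient should show the largest R2 drop
        assert max(imp, key=imp.get) == "x2"


class TestCrossValidation:
    def test_fold_sizes_differ_by_at_most_one(self):
        from sklearn.model_selection import KFold

        sizes = [len(test) for _, test in KFold(10, shuffle=True, random_state=0).split(
            np.empty((1819, 1))
        )]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 1819

    def test_exact_linear_data_gives_perfect_cv(self):
        X, y = _linear_frame(n=200, noise=0.0, seed=9)
        cv = bench.crossvalidate("mlr", X, y, k=10, seed=0)
        assert cv.r2_mean == pytest.approx(1.0, abs=1e-9)
        assert cv.r2_sd == pytest.approx(0.0, abs=1e-9)

    def test_shuffled_labels_destroy_cv_performance(self):
        X, y = _linear_frame(n=300, noise=0.3, seed=10)
        rng = np.random.default_rng(0)
        y_shuffled = pd.Series(rng.permutation(y.to_numpy()))
        cv = bench.crossvalidate("mlr", X, y_shuffled, k=10, seed=0)
        assert cv.r2_mean <= 0.0

    def test_invalid_fold_counts_rejected(self):
        X, y = _linear_frame(n=8)
        with pytest.raises(ValueError):
            bench.crossvalidate("mlr", X, y, k=9)
        with pytest.raises(ValueError):
            bench.crossvalidate("mlr", X, y, k=1)


class TestCalibration:
    def test_identity_predictions(self):
        obs = np.array([7.2, 7.3, 7.4, 7.5])
        cal = bench.calibration_metrics(obs, obs)
        assert (cal.in_the_large, cal.slope, cal.intercept, cal.brier_mse) == (
            0.0, 1.0, 0.0, 0.0,
        )

    def test_constant_shift(self):
        obs = np.linspace(7.2, 7.5, 20)
        cal = bench.calibration_metrics(obs, obs - 0.05)
        assert cal.in_the_large == pytest.approx(0.05)

    def test_shrunken_predictions_invert_to_slope_two(self):
        obs = np.linspace(7.0, 7.6, 50)
        cal = bench.calibration_metrics(obs, 0.5 * obs + 3.7)
        assert cal.slope == pytest.approx(2.0, abs=1e-9)

    def test_constant_predictions_have_undefined_slope(self):
        obs = np.linspace(7.2, 7.5, 10)
        cal = bench.calibration_metrics(obs, np.full(10, 7.35))
        assert cal.slope is None and cal.intercept is None
        assert cal.brier_mse > 0


class TestCompositeImportance:
    def test_identical_vectors_pass_through(self):
        v = np.array([0.5, 0.3, 0.2])
        assert np.allclose(bench.composite_importance(v, v), v)

    def test_disjoint_vectors_average_symmetrically(self):
        out = bench.composite_importance([1.0, 0.0], [0.0, 1.0])
        assert np.allclose(out, [0.5, 0.5])

    def test_normalized_output_sums_to_one(self):
        out = bench.composite_importance([3.0, 1.0, 2.0], [0.02, 0.05, 0.01])
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_raw_mean_reproduces_published_combined_column(self):
        # published traditional/RF block: TreeImp and SHAP columns -> Combined
        tree = np.array([0.632, 0.358, 0.008])
        shap = np.array([0.066, 0.048, 0.00075])
        combined = bench.composite_importance(tree, shap, normalize=False)
        assert np.allclose(np.round(combined, 3), [0.349, 0.203, 0.004])

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            bench.composite_importance([0.0, 0.0], [0.1, 0.9])


class TestAblation:
    def test_near_irrelevant_feature_changes_little(self, dev_features):
        res = bench.run_ablation(
            "traditional", "xgb", dev_features, dev_features["ph"], seed=0
        )
        assert abs(res.delta_r2) < 0.02

    def test_unmeasured_ion_index_is_load_bearing(self, dev_features):
        res = bench.run_ablation(
            "partitioned_be", "xgb", dev_features, dev_features["ph"], seed=0
        )
        assert res.delta_r2 > 0.15
        assert res.full_r2 - res.ablated_r2 == pytest.approx(res.delta_r2)

    def test_paired_folds_and_determinism(self, dev_features):
        a = bench.run_ablation("stewart", "xgb", dev_features, dev_features["ph"], seed=3)
        b = bench.run_ablation("stewart", "xgb", dev_features, dev_features["ph"], seed=3)
        assert a == b
        assert a.fold_hash == b.fold_hash

    def test_invalid_removals_rejected(self, dev_features):
        with pytest.raises(ValueError):
            bench.run_ablation("traditional", "xgb", dev_features,
                               dev_features["ph"], removed="begap")


def test_begap_leads_combined_importance_in_partitioned_framework(dev_features):
    X = dev_features[bench.FRAMEWORKS["partitioned_be"]]
    report = bench.fit_ml("xgb", X, dev_features["ph"], seed=42)
    combined = report.importance["combined"]
    assert max(combined, key=combined.get) == "begap"


def test_external_evaluation_matches_internal_on_same_data(dev_features):
    X = dev_features[bench.FRAMEWORKS["traditional"]]
    report = bench.fit_mlr(X, dev_features["ph"])
    replay = bench.evaluate_external(report, X, dev_features["ph"])
    assert replay["r2"] == pytest.approx(report.r2, abs=1e-12)
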