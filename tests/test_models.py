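"""Regression harness: splits, CV, grid search, metrics, importance."""

import numpy as np
import pandas as pd
import pytest

from dropmetry.models import (
    ALGORITHMS,
    FEATURES,
    TARGET,
    ConfigError,
    LSTMRegressor,
    ModelSpec,
    compare_algorithms,
    default_spec,
    evaluate,
    feature_importance,
    fit,
    grid_search,
    kfold_cv,
    split_dataset,
)


def feature_frame(rng, n, low=0.5, high=2.0):
    return pd.DataFrame(rng.uniform(low, high, (n, 5)), columns=FEATURES)


@pytest.fixture(scope="module")
def linear_frame():
    rng = np.random.default_rng(0)
    df = feature_frame(rng, 120)
    df[TARGET] = (
        1.0 + 2.0 * df["printing_time_s"] - 0.5 * df["nozzle_id_mm"]
    )
    return df


class TestSplit:
    def test_design_split_sizes(self, design_dataset):
        split = split_dataset(design_dataset, fraction=0.7, seed=42)
        assert len(split.train_records) == 1230
        assert len(split.test_records) == 528

    def test_small_split(self, linear_frame):
        split = split_dataset(linear_frame.head(10), fraction=0.7, seed=0)
        assert (len(split.train_records), len(split.test_records)) == (7, 3)

    def test_split_is_deterministic_and_partitions(self, linear_frame):
        s1 = split_dataset(linear_frame, seed=5)
        s2 = split_dataset(linear_frame, seed=5)
        pd.testing.assert_frame_equal(s1.train_records, s2.train_records)
        combined = pd.concat([s1.train_records, s1.test_records])
        assert len(combined) == len(linear_frame)
        assert len(combined.drop_duplicates()) == len(
            linear_frame.drop_duplicates()
        )

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_bad_fraction_rejected(self, linear_frame, fraction):
        with pytest.raises(ConfigError):
            split_dataset(linear_frame, fraction=fraction)


class TestKFold:
    def test_folds_partition_training_set(self, linear_frame):
        cv = kfold_cv(linear_frame.head(100), default_spec("decision_tree"), k=10)
        sizes = [len(f) for f in cv.fold_indices]
        assert sizes == [10] * 10
        all_idx = np.concatenate(cv.fold_indices)
        assert sorted(all_idx) == list(range(100))

    def test_perfect_linear_fit_has_unit_validation_r2(self, linear_frame):
        spec = ModelSpec("polynomial_regression", {"degree": 1})
        cv = kfold_cv(linear_frame, spec, k=10)
        assert cv.means["val_r2"] == pytest.approx(1.0, abs=1e-9)

    def test_reported_means_match_hand_average(self, linear_frame):
        cv = kfold_cv(linear_frame, default_spec("decision_tree"), k=5)
        assert cv.means["val_rmse"] == pytest.approx(
            cv.per_fold["val_rmse"].mean(), rel=1e-12
        )

    def test_invalid_k_rejected(self, linear_frame):
        with pytest.raises(ConfigError):
            kfold_cv(linear_frame, default_spec("decision_tree"), k=1)
        with pytest.raises(ConfigError):
            kfold_cv(linear_frame.head(5), default_spec("decision_tree"), k=10)


class TestGridSearch:
    def test_single_point_grid_returned(self, linear_frame):
        best, trace = grid_search(
            linear_frame, "decision_tree", {"max_depth": [4]}, k=5
        )
        assert best.hyperparameters["max_depth"] == 4
        assert len(trace) == 1

    def test_recovers_tree_complexity(self):
        """A depth-3 step-function target selects depth in [3, 5]."""
        rng = np.random.default_rng(7)
        df = feature_frame(rng, 400, 0.0, 1.0)
        df[TARGET] = (
            1.0
            + 4.0 * (df["printing_time_s"] > 0.5)
            + 2.0 * (df["nozzle_id_mm"] > 0.5)
            + 1.0 * (df["pressure_psi"] > 0.5)
            + rng.normal(0, 0.1, 400)
        )
        best, trace = grid_search(
            df, "decision_tree", {"max_depth": list(range(1, 20))}, k=10, seed=7
        )
        assert 3 <= best.hyperparameters["max_depth"] <= 5
        assert trace["val_rmse"].idxmin() == trace["max_depth"].tolist().index(
            best.hyperparameters["max_depth"]
        )

    def test_polynomial_overfitting_is_visible(self):
        """Validation error on noisy cubic data is non-monotone in degree."""
        rng = np.random.default_rng(7)
        df = feature_frame(rng, 300)
        x = df["printing_time_s"]
        df[TARGET] = 5.0 + 8.0 * (x - 1.2) ** 3 + rng.normal(0, 0.05, 300)
        best, trace = grid_search(
            df, "polynomial_regression", {"degree": list(range(1, 10))}, k=10, seed=7
        )
        chosen = best.hyperparameters["degree"]
        assert chosen >= 3
        val = trace.set_index("degree")["val_rmse"]
        assert val[9] > val[chosen]

    def test_empty_grid_rejected(self, linear_frame):
        with pytest.raises(ConfigError):
            grid_search(linear_frame, "decision_tree", {})


class TestFitAndEvaluate:
    def test_linear_data_recovered_exactly(self, linear_frame):
        model = fit(linear_frame, ModelSpec("polynomial_regression", {"degree": 1}))
        report = evaluate(model, linear_frame)
        assert report.rmse == pytest.approx(0.0, abs=1e-6)
        assert report.r2 == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("algorithm", ["decision_tree", "lstm"])
    def test_same_seed_gives_identical_predictions(self, linear_frame, algorithm):
        spec = default_spec(algorithm, seed=3)
        if algorithm == "lstm":
            spec = ModelSpec("lstm", dict(spec.hyperparameters, epochs=5), 3)
        probe, _ = (
            linear_frame.head(20)[FEATURES].to_numpy(float),
            None,
        )
        p1 = fit(linear_frame, spec).predict(probe)
        p2 = fit(linear_frame, spec).predict(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_worked_metrics_example(self):
        """Hand-computed MAE/MSE/RMSE/R^2 on the three-point example."""
        df = pd.DataFrame({f: [1.0, 1.0, 1.0] for f in FEATURES})
        df[TARGET] = [1.0, 2.0, 3.0]
        model = fit(df, default_spec("decision_tree"))
        model.estimator.predict = lambda X: np.array([1.0, 2.0, 4.0])
        report = evaluate(model, df)
        assert report.mae == pytest.approx(1 / 3, abs=1e-4)
        assert report.mse == pytest.approx(1 / 3, abs=1e-4)
        assert report.rmse == pytest.approx(0.5774, abs=1e-4)
        assert report.r2 == pytest.approx(0.5, abs=1e-9)

    def test_perfect_and_constant_predictor_limits(self, linear_frame):
        y = linear_frame[TARGET].to_numpy()
        model = fit(linear_frame, default_spec("decision_tree"))
        model.estimator.predict = lambda X: y
        perfect = evaluate(model, linear_frame)
        assert (perfect.mae, perfect.mse, perfect.rmse) == (0, 0, 0)
        assert perfect.r2 == 1.0
        model.estimator.predict = lambda X: np.full(len(y), y.mean())
        assert evaluate(model, linear_frame).r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_target_warns_nan_r2(self, linear_frame):
        df = linear_frame.copy()
        df[TARGET] = 2.0
        model = fit(df, default_spec("decision_tree"))
        with pytest.warns(UserWarning):
            report = evaluate(model, df)
        assert np.isnan(report.r2)

    def test_metric_identities_hold_for_fitted_models(self, linear_frame):
        for algorithm in ("decision_tree", "polynomial_regression"):
            model = fit(linear_frame, default_spec(algorithm))
            r = evaluate(model, linear_frame.tail(30))
            assert r.rmse**2 == pytest.approx(r.mse, rel=1e-12)
            assert r.mae <= r.rmse + 1e-12
            assert r.r2 <= 1.0

    def test_train_error_below_validation_error(self, design_dataset):
        """Depth-7 trees generalize: training MAE <= validation MAE on
        average across seeds."""
        df = pd.DataFrame(
            [{f: getattr(r, f) for f in FEATURES} | {TARGET: r.volume_uL}
             for r in design_dataset[:400]]
        )
        diffs = []
        for seed in range(10):
            cv = kfold_cv(df, default_spec("decision_tree", seed), k=5, seed=seed)
            diffs.append(cv.means["val_mae"] - cv.means["train_mae"])
        assert np.mean(diffs) >= 0


class TestSpecValidation:
    def test_missing_required_hyperparameter_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec("decision_tree", {})
        with pytest.raises(ConfigError):
            ModelSpec("random_forest", {"n_estimators": 10})

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ConfigError):
            default_spec("svm")

    def test_all_defaults_are_valid(self):
        for algorithm in ALGORITHMS:
            default_spec(algorithm)


class TestLSTM:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 5))
        y = rng.normal(size=6)
        est = LSTMRegressor(hidden_units=4, seed=0)
        xseq = est._as_sequences(X)
        p = est._init_params(5, np.random.default_rng(1))
        yhat, caches = est._forward(xseq, p)
        grads = est._backward(caches, yhat, y, p)

        def loss():
            pred, _ = est._forward(xseq, p)
            return np.mean((pred - y) ** 2)

        eps = 1e-6
        for key in p:
            flat = p[key].reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 3)):
                flat[idx] += eps
                up = loss()
                flat[idx] -= 2 * eps
                down = loss()
                flat[idx] += eps
                numeric = (up - down) / (2 * eps)
                analytic = grads[key].reshape(-1)[idx]
                assert numeric == pytest.approx(analytic, abs=1e-6, rel=1e-4)

    def test_learns_simple_function(self, linear_frame):
        spec = ModelSpec(
            "lstm",
            {"epochs": 60, "learning_rate": 1e-2, "batch_size": 16,
             "hidden_units": 16},
            seed=0,
        )
        model = fit(linear_frame, spec)
        assert evaluate(model, linear_frame).r2 > 0.95

    def test_accepts_explicit_sequences(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3, 2))
        y = X.sum(axis=(1, 2))
        est = LSTMRegressor(hidden_units=8, epochs=30, learning_rate=1e-2, seed=0)
        est.fit(X, y)
        assert est.predict(X).shape == (40,)


class TestImportance:
    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(3)
        df = feature_frame(rng, 400)
        df[TARGET] = 3.0 * df["printing_time_s"] + rng.normal(0, 0.01, 400)
        report = feature_importance(df)
        assert report.weights["printing_time_s"] >= 0.95

    def test_weights_sum_to_one(self, design_dataset):
        report = feature_importance(design_dataset[:300])
        assert sum(report.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(w >= 0 for w in report.weights.values())

    def test_constant_target_reports_uniform(self):
        df = pd.DataFrame({f: np.linspace(1, 2, 50) for f in FEATURES})
        df[TARGET] = 1.0
        with pytest.warns(UserWarning):
            report = feature_importance(df)
        assert all(w == pytest.approx(0.2) for w in report.weights.values())


class TestCompare:
    def test_table_structure_and_zero_sd_for_single_repeat(self, linear_frame):
        specs = [default_spec("decision_tree"), default_spec("polynomial_regression")]
        table = compare_algorithms(linear_frame, specs, repeats=1)
        assert list(table["algorithm"]) == [
            "decision_tree", "polynomial_regression",
        ]
        assert (table["mae_sd"] == 0).all()
        assert (table["status"] == "OK").all()

    def test_one_failure_does_not_abort_others(self, linear_frame):
        bad = ModelSpec(
            "mlp",
            {"epochs": 0, "learning_rate": 1e-3, "batch_size": 32,
             "hidden_layer_sizes": (8,)},
        )
        table = compare_algorithms(
            linear_frame, [bad, default_spec("decision_tree")], repeats=1
        )
        statuses = dict(zip(table["algorithm"], table["status"]))
        assert statuses["decision_tree"] == "OK"
        assert statuses["mlp"] != "OK"
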