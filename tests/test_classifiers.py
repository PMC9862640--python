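import json

import numpy as np
import pytest

from cocoonsort import (
    ConfusionMatrix,
    LogisticModel,
    Standardizer,
    StandardizationError,
    ValidationError,
    balance_binary,
    fit_logistic,
    format_percent,
    load_model_bundle,
    metrics,
    monte_carlo_cv,
    save_model_bundle,
    stratified_split,
)
from cocoonsort.classifiers import round_half_up


class TestStandardizer:
    def test_symmetric_pair_maps_to_unit_values(self):
        std = Standardizer.fit(np.array([[-1.0], [1.0]]))
        assert np.allclose(std.apply(np.array([[-1.0], [1.0]])), [[-1.0], [1.0]])

    def test_fitted_set_has_zero_mean_unit_sd(self, rng):
        x = rng.normal(3.0, 7.0, size=(50, 4))
        std = Standardizer.fit(x)
        z = std.apply(x)
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0) - 1.0).max() < 1e-9

    def test_constant_column_raises_with_name(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(StandardizationError, match="col_b"):
            Standardizer.fit(x, feature_names=["col_a", "col_b"])

    def test_constant_column_dropped_when_requested(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 2.0), np.arange(5.0) ** 2])
        std = Standardizer.fit(x, on_constant="drop")
        assert std.kept_columns.tolist() == [0, 2]
        assert std.apply(x).shape == (5, 2)


class TestBalanceAndSplit:
    def test_imbalanced_set_balances_to_twice_minority(self, rng):
        x = rng.normal(size=(951, 3))
        y = np.array(["well"] * 773 + ["bad"] * 178)
        xb, yb = balance_binary(x, y, seed=0)
        assert len(yb) == 356
        assert (yb == "bad").sum() == 178 and (yb == "well").sum() == 178

    def test_balanced_set_unchanged_in_size(self, rng):
        x = rng.normal(size=(40, 2))
        y = np.array([0] * 20 + [1] * 20)
        xb, yb = balance_binary(x, y, seed=1)
        assert len(yb) == 40

    def test_same_seed_same_selection(self, rng):
        x = rng.normal(size=(100, 2))
        y = np.array([0] * 70 + [1] * 30)
        a = balance_binary(x, y, seed=9)
        b = balance_binary(x, y, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_split_sizes_round_half_up(self):
        y = np.array(["a"] * 178 + ["b"] * 178)
        tr, te = stratified_split(y, 0.7, seed=0)
        assert (tr.size, te.size) == (249, 107)
        y2 = np.array(["alive"] * 183 + ["dead"] * 183)
        tr2, te2 = stratified_split(y2, 0.8, seed=0)
        assert (tr2.size, te2.size) == (293, 73)

    def test_split_disjoint_exhaustive_stratified(self, rng):
        y = rng.choice(["p", "n"], size=200, p=[0.3, 0.7])
        tr, te = stratified_split(y, 0.7, seed=3)
        assert np.intersect1d(tr, te).size == 0
        assert np.union1d(tr, te).size == 200
        # stratification keeps both classes in the 30% test partition
        assert len(np.unique(y[te])) == 2

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValidationError):
            stratified_split(np.array([0, 1, 0, 1]), 0.999, seed=0)


class TestLogistic:
    def test_null_model_gives_half_probability_and_positive_tie(self):
        model = LogisticModel(
            weights=np.zeros(3), intercept=0.0, positive_label="bad", negative_label="good"
        )
        x = np.ones((4, 3))
        assert np.allclose(model.predict_proba(x), 0.5)
        assert list(model.predict(x)) == ["bad"] * 4  # tie at 0.5 -> positive

    def test_separable_data_fit_near_perfectly(self, rng):
        import warnings

        n = 200
        x = np.vstack([rng.normal(-3, 0.5, (n, 2)), rng.normal(3, 0.5, (n, 2))])
        y = np.array([0] * n + [1] * n)
        with warnings.catch_warnings():
            # perfect separation may trigger the documented ridge fallback
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_logistic(x, y, positive_label=1)
        acc = np.mean(model.predict(x) == y)
        assert acc >= 0.99

    def test_planted_coefficients_recovered(self, rng):
        n, p = 5000, 35
        true_w = rng.normal(0.0, 0.5, p)
        x = rng.normal(size=(n, p))
        prob = 1.0 / (1.0 + np.exp(-(x @ true_w)))
        y = (rng.uniform(size=n) < prob).astype(int)
        model = fit_logistic(x, y, positive_label=1)
        # standard errors from the inverse Fisher information at the fit
        phat = model.predict_proba(x)
        w = phat * (1 - phat)
        xd = np.column_stack([x, np.ones(n)])
        cov = np.linalg.inv(xd.T @ (xd * w[:, None]))
        se = np.sqrt(np.diag(cov))[:p]
        assert np.all(np.abs(model.weights - true_w) <= 3 * se)

    def test_affine_feature_rescaling_is_absorbed(self, rng):
        x = rng.normal(size=(300, 4))
        y = (x[:, 0] - 0.5 * x[:, 2] + rng.normal(0, 0.5, 300) > 0).astype(int)

        def pipeline_predictions(features):
            std = Standardizer.fit(features)
            model = fit_logistic(std.apply(features), y, positive_label=1)
            return model.predict(std.apply(features))

        x_scaled = x.copy()
        x_scaled[:, 1] *= 10.0
        assert np.array_equal(pipeline_predictions(x), pipeline_predictions(x_scaled))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(np.ones((5, 2)), np.zeros(5))


class TestMetrics:
    def test_top_camera_confusion_counts(self):
        cm = ConfusionMatrix(tp=287, tn=785, fp=67, fn=85)
        acc, rec = metrics(cm)
        assert format_percent(acc) == "87.6"
        assert round_half_up(rec, 2) == 0.77

    def test_bottom_camera_confusion_counts(self):
        cm = ConfusionMatrix(tp=294, tn=808, fp=51, fn=77)
        acc, rec = metrics(cm)
        assert format_percent(acc) == "89.6"
        assert round_half_up(rec, 2) == 0.79

    def test_perfect_classifier(self):
        acc, rec = metrics(ConfusionMatrix(tp=10, tn=20, fp=0, fn=0))
        assert acc == 1.0 and rec == 1.0

    def test_agrees_with_per_sample_counting(self, rng):
        y_true = rng.choice([0, 1], size=500)
        y_pred = rng.choice([0, 1], size=500)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, positive_label=1)
        acc, rec = metrics(cm)
        assert acc == pytest.approx(np.mean(y_true == y_pred))
        assert rec == pytest.approx(np.mean(y_pred[y_true == 1] == 1))

    def test_recall_undefined_without_positives(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionMatrix(tp=0, tn=5, fp=2, fn=0))


class TestMonteCarloCV:
    @pytest.fixture
    def dataset(self, rng):
        n = 300
        x = rng.normal(size=(n, 4))
        y = (x[:, 0] + rng.normal(0, 1.0, n) > 0).astype(int)
        return x, y

    def test_report_shape_and_mean_identity(self, dataset):
        x, y = dataset
        report = monte_carlo_cv(x, y, 0.7, n_iter=20, seed=5, balance="once")
        assert report.n_iterations == 20
        assert report.train_accuracies.shape == (20,)
        assert report.mean_test == pytest.approx(np.mean(report.test_accuracies))

    def test_deterministic_under_fixed_seed(self, dataset):
        x, y = dataset
        a = monte_carlo_cv(x, y, 0.7, n_iter=10, seed=11)
        b = monte_carlo_cv(x, y, 0.7, n_iter=10, seed=11)
        assert np.array_equal(a.test_accuracies, b.test_accuracies)

    def test_per_iteration_balancing_mode_runs(self, dataset):
        x, y = dataset
        report = monte_carlo_cv(x, y, 0.7, n_iter=5, seed=2, balance="per_iteration")
        assert report.test_accuracies.shape == (5,)


class TestPersistence:
    def test_bundle_round_trip(self, tmp_path, rng):
        x = rng.normal(size=(50, 3))
        y = (x[:, 0] > 0).astype(int)
        std = Standardizer.fit(x)
        model = fit_logistic(std.apply(x), y, positive_label=1, feature_schema=["a", "b", "c"])
        path = tmp_path / "model.json"
        save_model_bundle(path, model, std, metadata={"k_truncation": 4})
        model2, std2, meta = load_model_bundle(path)
        assert meta["k_truncation"] == 4
        assert np.allclose(model2.weights, model.weights)
        assert np.allclose(std2.means, std.means)
        probe = rng.normal(size=(5, 3))
        assert np.array_equal(
            model.predict(std.apply(probe)), model2.predict(std2.apply(probe))
        )

    def test_versioned_schema(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"version": 99}))
        with pytest.raises(ValidationError):
            load_model_bundle(path)
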