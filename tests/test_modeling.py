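"""F2 arithmetic, scaling, SMOTE properties, PR curves, the train/eval
protocol, and importance normalization."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

import cogstates as cs
from cogstates.errors import RangeError, UnsupportedModelError
from cogstates.modeling import ExperimentConfig


class TestFBeta:
    @pytest.mark.parametrize("p,r,expected", [
        (1.0, 1.0, 1.0), (0.0, 0.0, 0.0), (1.0, 0.0, 0.0),
    ])
    def test_edge_values(self, p, r, expected):
        assert cs.fbeta(p, r) == pytest.approx(expected)

    def test_published_imbalanced_baseline(self):
        assert cs.fbeta(202 / 1360, 1.0) == pytest.approx(0.46587, abs=1e-4)

    def test_matches_confusion_matrix_oracle(self, rng):
        # oracle: compute precision/recall from TP/FP/FN on random predictions
        # and compare against the closed-form F2
        from sklearn.metrics import fbeta_score
        for _ in range(20):
            y = rng.integers(0, 2, size=200)
            pred = rng.integers(0, 2, size=200)
            tp = np.sum((y == 0) & (pred == 0))
            fp = np.sum((y == 1) & (pred == 0))
            fn = np.sum((y == 0) & (pred == 1))
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            assert cs.fbeta(p, r) == pytest.approx(
                fbeta_score(y, pred, beta=2.0, pos_label=0, zero_division=0),
                abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            cs.fbeta(1.2, 0.5)


class TestBaselineF2:
    def test_published_counts(self):
        assert cs.baseline_f2(202, 1158) == pytest.approx(0.4659, abs=5e-4)

    def test_pure_class_extremes(self):
        assert cs.baseline_f2(50, 0) == 1.0
        assert cs.baseline_f2(0, 50) == 0.0

    def test_no_samples_rejected(self):
        with pytest.raises(RangeError):
            cs.baseline_f2(0, 0)


class TestScaling:
    def test_standard_scaling_normalizes_training_columns(self, rng):
        train = pd.DataFrame(rng.normal(5, 3, size=(100, 4)))
        scaled, _, _ = cs.scale_features(train, "standard")
        np.testing.assert_allclose(scaled.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(scaled.std(ddof=0), 1.0, atol=1e-9)

    def test_robust_scaling_centers_on_median_iqr(self, rng):
        train = pd.DataFrame(rng.exponential(2, size=(101, 3)))
        scaled, _, _ = cs.scale_features(train, "robust")
        np.testing.assert_allclose(scaled.median(), 0.0, atol=1e-9)
        q = scaled.quantile([0.25, 0.75])
        np.testing.assert_allclose(q.loc[0.75] - q.loc[0.25], 1.0, atol=1e-6)

    def test_test_rows_use_training_statistics(self, rng):
        train = pd.DataFrame(rng.normal(size=(50, 2)))
        test = pd.DataFrame(rng.normal(10, 1, size=(50, 2)))
        _, scaled_test, scaler = cs.scale_features(train, "standard", test)
        # a shifted test set keeps its shift: no refit happened
        assert scaled_test.mean().min() > 5.0
        np.testing.assert_allclose(scaler.mean_, train.mean(), atol=1e-12)

    def test_constant_feature_passes_through_centered(self, rng):
        train = pd.DataFrame({"a": rng.normal(size=20), "b": np.full(20, 7.0)})
        scaled, _, _ = cs.scale_features(train, "standard")
        np.testing.assert_allclose(scaled["b"], 0.0)


class TestSmote:
    def test_parity_after_balancing(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.array([0] * 10 + [1] * 50)
        Xb, yb = cs.smote_balance(X, y, seed=0)
        assert np.bincount(yb).tolist() == [50, 50]

    def test_original_rows_are_preserved_verbatim(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0] * 8 + [1] * 32)
        Xb, _ = cs.smote_balance(X, y, seed=0)
        np.testing.assert_array_equal(Xb[:40], X)

    def test_synthetic_points_lie_between_minority_points(self, rng):
        # minority points on a 1-d line embedded in 3-d: every interpolant
        # must stay on the line, inside the minority hull
        t = rng.uniform(size=12)
        direction = np.array([1.0, 2.0, -1.0])
        X_min = np.outer(t, direction)
        X_maj = rng.normal(10, 1, size=(40, 3))
        X = np.vstack([X_min, X_maj])
        y = np.array([0] * 12 + [1] * 40)
        Xb, yb = cs.smote_balance(X, y, seed=3)
        synth = Xb[52:]
        coords = synth @ direction / (direction @ direction)
        np.testing.assert_allclose(np.outer(coords, direction), synth,
                                   atol=1e-9)
        assert coords.min() >= t.min() - 1e-9
        assert coords.max() <= t.max() + 1e-9

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array([0] * 6 + [1] * 24)
        a, _ = cs.smote_balance(X, y, seed=11)
        b, _ = cs.smote_balance(X, y, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_tiny_minority_falls_back(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] + [1] * 9)
        Xb, yb = cs.smote_balance(X, y, seed=0)
        assert np.bincount(yb).tolist() == [9, 9]
        np.testing.assert_array_equal(Xb[10:], np.repeat(X[:1], 8, axis=0))

    def test_small_minority_reduces_k_with_warning(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 4 + [1] * 16)
        with pytest.warns(UserWarning, match="reducing k"):
            _, yb = cs.smote_balance(X, y, k=5, seed=0)
        assert np.bincount(yb).tolist() == [16, 16]


class TestPRCurve:
    def test_perfect_scores_reach_the_corner(self):
        y = np.array([0, 0, 1, 1, 1])
        scores = np.array([0.9, 0.8, 0.1, 0.2, 0.3])  # P(class 0)
        curve, ap = cs.pr_curve(y, scores)
        assert (1.0, 1.0) in [(round(r, 9), round(p, 9)) for r, p in curve]
        assert ap == pytest.approx(1.0)

    def test_reversed_scores_have_prevalence_level_ap(self, rng):
        y = rng.integers(0, 2, size=400)
        scores = np.where(y == 0, 0.1, 0.9)  # anti-informative
        _, ap = cs.pr_curve(y, scores)
        prevalence = (y == 0).mean()
        assert ap <= prevalence + 0.05

    def test_single_class_rejected(self):
        with pytest.raises(RangeError):
            cs.pr_curve(np.zeros(10), np.linspace(0, 1, 10))


def _separable_problem(rng, n=300):
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 6))
    X[:, 0] += 4.0 * y
    return pd.DataFrame(X), y


class TestTrainEval:
    def test_separable_problem_is_solved(self, rng):
        X, y = _separable_problem(rng)
        cfg = ExperimentConfig(cv_folds=3, seed=0,
                               models={"rf": [{"n_estimators": 50}]})
        report = cs.train_eval(cfg, X, y)
        assert report.metrics.f2 >= 0.95
        assert report.model_name == "rf"
        assert 0.0 <= report.metrics.cv_mean <= 1.0

    def test_grid_reports_best_by_cv(self, rng):
        X, y = _separable_problem(rng)
        cfg = ExperimentConfig(cv_folds=3, seed=0, balance="smote",
                               models={"rf": [{"n_estimators": 20}],
                                       "knn": [{"n_neighbors": 5}]})
        report = cs.train_eval(cfg, X, y)
        assert report.model_name in ("rf", "knn")
        assert report.metrics.f2 >= 0.9

    def test_nan_rows_are_dropped_before_modeling(self, rng):
        X, y = _separable_problem(rng, n=200)
        X.iloc[0, 0] = np.nan
        cfg = ExperimentConfig(cv_folds=2, seed=0,
                               models={"logreg": [{}]})
        report = cs.train_eval(cfg, X, y)
        assert report.n_train + report.n_test == 199

    def test_single_class_target_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)))
        with pytest.raises(RangeError):
            cs.train_eval(ExperimentConfig(cv_folds=2), X, np.zeros(30))

    def test_fixed_seed_reproduces_metrics_exactly(self, rng):
        X, y = _separable_problem(rng)
        cfg = ExperimentConfig(cv_folds=3, seed=7, balance="smote",
                               models={"rf": [{"n_estimators": 30}]})
        a = cs.train_eval(cfg, X, y)
        b = cs.train_eval(cfg, X, y)
        assert a.metrics == b.metrics


class TestImportances:
    def test_normalized_and_sorted(self, rng):
        X, y = _separable_problem(rng)
        model = cs.make_model("rf", n_estimators=30).fit(X, y)
        report = cs.importance_report(model, X.columns, k=6)
        assert report.sum() == pytest.approx(1.0, abs=1e-9)
        assert (report.values[:-1] >= report.values[1:]).all()
        assert report.index[0] == 0  # the informative column dominates

    def test_k_larger_than_feature_count_returns_all(self, rng):
        X, y = _separable_problem(rng, n=100)
        model = cs.make_model("extra_trees", n_estimators=10).fit(X, y)
        assert len(cs.importance_report(model, X.columns, k=50)) == 6

    def test_model_without_importances_is_unsupported(self, rng):
        X, y = _separable_problem(rng, n=80)
        model = LogisticRegression().fit(X, y)
        with pytest.raises(UnsupportedModelError):
            cs.importance_report(model, X.columns)

    def test_presets_name_published_best_models(self):
        name, params = cs.modeling.PRESETS["engagement_60s"]
        model = cs.make_model(name, **params)
        assert model.n_estimators == 1000 and model.criterion == "gini"
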