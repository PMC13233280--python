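import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from deltarad.modeling import (ModelConfig, dichotomize, fit_logistic, k_sweep,
                               resample_evaluate, threshold_metrics)
from deltarad.preprocess import ParameterError
from deltarad.selection import RankingResult


def _cohort(rng, n=43, shift=0.0, n_features=3, prevalence=15 / 43):
    n_pos = round(n * prevalence)
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    X = rng.normal(size=(n, n_features))
    X[:, 0] += np.where(y == 1, shift, 0.0)
    data = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)],
                        index=[f"P{i:03d}" for i in range(n)])
    return data, pd.Series(y, index=data.index)


class TestFitLogistic:
    def test_separable_feature_gives_auc_one(self):
        X = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        fit = fit_logistic(X, y)
        assert roc_auc_score(y, fit.predict_proba(X)) == 1.0

    def test_null_feature_large_n(self, rng):
        X = rng.normal(size=(10_000, 1))
        y = rng.integers(0, 2, size=10_000)
        fit = fit_logistic(X, y)
        assert abs(fit.model.coef_[0][0]) < 0.05
        assert roc_auc_score(y, fit.predict_proba(X)) == pytest.approx(0.5, abs=0.02)

    def test_intercept_only_predicts_prevalence(self):
        y = np.array([1] * 15 + [0] * 28)
        X = np.zeros((43, 1))
        fit = fit_logistic(X, y)
        np.testing.assert_allclose(fit.predict_proba(X), 15 / 43, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            fit_logistic(np.zeros((5, 1)), np.zeros(5, int))


class TestResampleEvaluate:
    def test_perfect_predictor_has_degenerate_ci(self, rng):
        data, y = _cohort(rng, shift=50.0, n_features=1)
        cfg = ModelConfig(n_iterations=50, seed=1)
        res = resample_evaluate(data, y, ["f0"], cfg)
        assert res.mean_auc == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_reproducible_under_seed(self, rng):
        data, y = _cohort(rng, shift=0.5)
        cfg = ModelConfig(n_iterations=30, seed=9)
        a = resample_evaluate(data, y, ["f0", "f1"], cfg)
        b = resample_evaluate(data, y, ["f0", "f1"], cfg)
        np.testing.assert_array_equal(a.aucs, b.aucs)

    def test_iteration_count_exact_despite_redraws(self, rng):
        # tiny cohort with few positives forces occasional single-class draws
        data, y = _cohort(rng, n=9, prevalence=2 / 9)
        cfg = ModelConfig(n_iterations=200, seed=2)
        res = resample_evaluate(data, y, ["f0"], cfg)
        assert len(res.aucs) == 200
        assert res.n_redrawn > 0

    def test_auc_invariant_to_monotone_transform_of_probabilities(self, rng):
        p = rng.random(43)
        y = (rng.random(43) < p).astype(int)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        assert roc_auc_score(y, p) == pytest.approx(
            roc_auc_score(y, np.log(p / (1 - p))), abs=1e-12)

    def test_holdout_mode_scores_only_test_patients(self, rng):
        data, y = _cohort(rng, shift=0.5)
        cfg = ModelConfig(n_iterations=5, seed=3, eval_population="holdout_only")
        res = resample_evaluate(data, y, ["f0"], cfg)
        n_scored = (~np.isnan(res.predictions)).sum(axis=1)
        assert (n_scored == 43 - int(np.floor(2 / 3 * 43))).all()


class TestKSweep:
    def _ranking(self, features, importances):
        return RankingResult(retained_features=features,
                             importances=dict(zip(features, importances)))

    def test_sweep_stops_at_positive_set_size(self, rng):
        data, y = _cohort(rng, shift=1.0, n_features=5)
        ranking = self._ranking(list(data.columns), [0.3, 0.1, -0.1, -0.2, 0.0])
        cfg = ModelConfig(n_iterations=20, seed=4)
        sweep = k_sweep(data, y, ranking, cfg)
        assert set(sweep.results) == {1, 2}

    def test_no_positive_importance_is_unmodelable(self, rng):
        data, y = _cohort(rng)
        ranking = self._ranking(list(data.columns), [-0.1, -0.2, 0.0])
        with pytest.raises(ParameterError, match="unmodelable"):
            k_sweep(data, y, ranking, ModelConfig(n_iterations=5))

    def test_auc_nondecreasing_until_saturation_on_separable_data(self, rng):
        # f0 separates partially, f0+f1 fully; noise-free nested models
        n = 30
        y = np.repeat([0, 1], n // 2)
        f0 = y * 2.0 + np.where(np.arange(n) % 3 == 0, 1.5, 0.0)
        f1 = y * 1.0 - 0.5 * f0
        data = pd.DataFrame({"f0": f0, "f1": f1},
                            index=[f"P{i}" for i in range(n)])
        ys = pd.Series(y, index=data.index)
        ranking = self._ranking(["f0", "f1"], [0.5, 0.2])
        sweep = k_sweep(data, ys, ranking, ModelConfig(n_iterations=40, seed=6))
        assert sweep.results[2].mean_auc >= sweep.results[1].mean_auc - 1e-9

    def test_tie_breaks_to_smaller_k(self, rng):
        data, y = _cohort(rng, shift=50.0, n_features=2)
        ranking = self._ranking(["f0", "f1"], [0.4, 0.1])
        sweep = k_sweep(data, y, ranking, ModelConfig(n_iterations=20, seed=7))
        # both K achieve AUC 1.0 -> parsimony picks K=1
        assert sweep.optimal_k == 1


class TestThresholdMetrics:
    def test_perfect_predictor(self, rng):
        data, y = _cohort(rng, shift=50.0, n_features=1)
        res = resample_evaluate(data, y, ["f0"], ModelConfig(n_iterations=10, seed=1))
        m = threshold_metrics(res).summary()
        assert m["sensitivity"]["mean"] == pytest.approx(1.0)
        assert m["specificity"]["mean"] == pytest.approx(1.0)

    def test_constant_prevalence_probability_accuracy(self):
        # p = prevalence (15/43) < 0.5 for every patient -> all-negative calls
        y = np.array([1] * 15 + [0] * 28)
        from deltarad.modeling import ModelEvalResult
        preds = np.full((1, 43), 15 / 43)
        res = ModelEvalResult(window_label="", k=0, features=[],
                              aucs=np.array([0.5]), mean_auc=0.5, ci_low=0.5,
                              ci_high=0.5, predictions=preds, y_true=y,
                              coef_mean={})
        m = threshold_metrics(res)
        assert m.specificity[0] == 1.0
        assert m.sensitivity[0] == 0.0
        assert m.accuracy[0] == pytest.approx(28 / 43)


class TestDichotomize:
    def test_printed_cohort_split(self):
        sev = pd.Series(["none"] * 16 + ["mild"] * 12 + ["moderate"] * 10
                        + ["severe"] * 5)
        labels = dichotomize(sev)
        assert int((labels == 0).sum()) == 28
        assert int(labels.sum()) == 15
        assert round(100 * (labels == 0).mean(), 1) == 65.1

    def test_unknown_category_rejected(self):
        with pytest.raises(ParameterError, match="severity"):
            dichotomize(pd.Series(["none", "awful"]))
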