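"""Incremental-K logistic models evaluated by repeated two-thirds resampling.

For each temporal window and each K (top-K ranked features with positive
importance, K = 1..min(7, number of positive features)), a plain
maximum-likelihood logistic regression (logit link, intercept, no penalty) is
fit on a random unstratified two-thirds subset of the cohort and used to
predict every patient; the AUC of those predictions against the true labels
is recorded.  After ``n_iterations`` draws the mean AUC and the empirical
2.5th/97.5th percentile interval are reported.  Training subsets that happen
to contain a single class are redrawn (and counted) so the iteration count is
exact.  Because every patient — including the training subset — is scored,
the estimate carries train-set optimism; a holdout-only evaluation mode is
available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .preprocess import ParameterError
from .selection import RankingResult

SEVERITY_MAP = {"none": 0, "mild": 0, "moderate": 1, "severe": 1}


def dichotomize(severities: pd.Series) -> pd.Series:
    """Collapse 4-level dysphagia severity into tolerable (0: none/mild) vs
    significant (1: moderate/severe)."""
    s = severities.astype(str).str.strip().str.lower()
    unknown = sorted(set(s) - set(SEVERITY_MAP))
    if unknown:
        raise ParameterError(f"severity: unknown categories {unknown}")
    return s.map(SEVERITY_MAP).rename("label")


@dataclass(frozen=True)
class ModelConfig:
    k_max: int = 7
    n_iterations: int = 1000
    train_fraction: float = 2 / 3
    eval_population: str = "all_patients"  # or "holdout_only"
    ci: tuple[float, float] = (2.5, 97.5)
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ParameterError("train_fraction: must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ParameterError("n_iterations: must be >= 1")
        if self.eval_population not in ("all_patients", "holdout_only"):
            raise ParameterError("eval_population: all_patients or holdout_only")


@dataclass
class FittedLogistic:
    model: LogisticRegression
    converged: bool
    features: list[str]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)[:, 1]


@dataclass
class ModelEvalResult:
    window_label: str
    k: int
    features: list[str]
    aucs: np.ndarray
    mean_auc: float
    ci_low: float
    ci_high: float
    predictions: np.ndarray          # (n_iterations, n_patients), NaN where unscored
    y_true: np.ndarray
    coef_mean: dict[str, float]
    n_redrawn: int = 0
    n_unconverged: int = 0


def fit_logistic(X: np.ndarray, y: np.ndarray, features: list[str] | None = None
                 ) -> FittedLogistic:
    """Maximum-likelihood logistic fit with intercept (no regularization).

    Perfectly separable data does not converge to finite coefficients; the fit
    is kept (probability ranks remain usable for AUC) and flagged.
    """
    if len(np.unique(y)) < 2:
        raise ParameterError("outcomes: both classes required for a logistic fit")
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=500, tol=1e-8)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return FittedLogistic(model=model, converged=converged,
                          features=features or [])


def resample_evaluate(data: pd.DataFrame, outcomes: pd.Series,
                      features: list[str], cfg: ModelConfig | None = None,
                      window_label: str = "") -> ModelEvalResult:
    """Repeated random two-thirds resampling of a fixed feature subset."""
    cfg = cfg or ModelConfig()
    cfg.validate()
    if not features:
        raise ParameterError("features: need at least one feature to model")
    sub = data[features].dropna(axis=0)
    y = outcomes.loc[sub.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise ParameterError("outcomes: both classes must be present")
    X = sub.to_numpy(dtype=np.float64)
    n = len(y)
    n_train = int(np.floor(cfg.train_fraction * n))
    if n_train < 2 or n_train >= n:
        raise ParameterError("train_fraction: degenerate training-set size")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    aucs = np.empty(cfg.n_iterations)
    preds = np.full((cfg.n_iterations, n), np.nan)
    coef_sum = np.zeros(X.shape[1])
    n_redrawn = 0
    n_unconverged = 0
    for it in range(cfg.n_iterations):
        while True:
            train = rng.choice(n, size=n_train, replace=False)
            if len(np.unique(y[train])) == 2:
                break
            n_redrawn += 1
        fit = fit_logistic(X[train], y[train], features)
        if not fit.converged:
            n_unconverged += 1
        if cfg.eval_population == "all_patients":
            eval_idx = np.arange(n)
        else:
            eval_idx = np.setdiff1d(np.arange(n), train)
        p = fit.predict_proba(X[eval_idx])
        preds[it, eval_idx] = p
        if len(np.unique(y[eval_idx])) < 2:
            aucs[it] = np.nan
        else:
            aucs[it] = roc_auc_score(y[eval_idx], p)
        coef_sum += fit.model.coef_[0]

    valid = aucs[~np.isnan(aucs)]
    lo, hi = np.percentile(valid, cfg.ci)
    return ModelEvalResult(
        window_label=window_label, k=len(features), features=list(features),
        aucs=aucs, mean_auc=float(valid.mean()), ci_low=float(lo), ci_high=float(hi),
        predictions=preds, y_true=y,
        coef_mean={f: float(c / cfg.n_iterations) for f, c in zip(features, coef_sum)},
        n_redrawn=n_redrawn, n_unconverged=n_unconverged)


@dataclass
class KSweepResult:
    window_label: str
    results: dict[int, ModelEvalResult]
    optimal_k: int

    @property
    def optimal(self) -> ModelEvalResult:
        return self.results[self.optimal_k]


def k_sweep(data: pd.DataFrame, outcomes: pd.Series, ranking: RankingResult,
            cfg: ModelConfig | None = None, window_label: str = "") -> KSweepResult:
    """Evaluate K = 1..min(k_max, |positive importance set|) nested models.

    The optimal K maximizes mean AUC; ties go to the smaller (more
    parsimonious) K.
    """
    cfg = cfg or ModelConfig()
    positive = ranking.positive_set
    if not positive:
        raise ParameterError("ranking: no feature has positive importance; window unmodelable")
    results: dict[int, ModelEvalResult] = {}
    for k in range(1, min(cfg.k_max, len(positive)) + 1):
        results[k] = resample_evaluate(data, outcomes, positive[:k], cfg,
                                       window_label=window_label)
    optimal_k = max(results, key=lambda k: (results[k].mean_auc, -k))
    return KSweepResult(window_label=window_label, results=results,
                        optimal_k=optimal_k)


@dataclass
class ThresholdMetrics:
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray

    def summary(self, ci=(2.5, 97.5)) -> dict[str, dict[str, float]]:
        out = {}
        for name, arr in (("sensitivity", self.sensitivity),
                          ("specificity", self.specificity),
                          ("accuracy", self.accuracy)):
            v = arr[~np.isnan(arr)]
            lo, hi = np.percentile(v, ci) if v.size else (np.nan, np.nan)
            out[name] = {"mean": float(v.mean()) if v.size else float("nan"),
                         "ci_low": float(lo), "ci_high": float(hi)}
        return out


def threshold_metrics(result: ModelEvalResult, threshold: float = 0.5
                      ) -> ThresholdMetrics:
    """Per-iteration confusion-matrix metrics at a probability threshold."""
    y = result.y_true
    n_iter = result.predictions.shape[0]
    sens = np.full(n_iter, np.nan)
    spec = np.full(n_iter, np.nan)
    acc = np.full(n_iter, np.nan)
    for it in range(n_iter):
        p = result.predictions[it]
        scored = ~np.isnan(p)
        pred = p[scored] >= threshold
        truth = y[scored] == 1
        if truth.any():
            sens[it] = np.mean(pred[truth])
        if (~truth).any():
            spec[it] = np.mean(~pred[~truth])
        if scored.any():
            acc[it] = np.mean(pred == truth)
    return ThresholdMetrics(sensitivity=sens, specificity=spec, accuracy=acc)
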