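"""Redundancy filtering and Random-Forest predictor ranking.

Filtering: a Spearman rank correlation matrix is computed across patients;
while any pair of surviving features has |rho| strictly exceeding the
threshold, the member of the worst-offending pair with the higher mean
absolute correlation to the other survivors is dropped.  Ties are broken by
registry (column) order, so the pass is fully deterministic.

Ranking: a bagged ensemble of Gini-split decision trees (a Random Forest with
per-node sqrt-feature subsampling) is fit on the filtered deltas, and each
feature's importance is the raw mean increase in out-of-bag misclassification
error after randomly permuting that feature among a tree's out-of-bag
patients.  Importances are not divided by their between-tree spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .preprocess import ParameterError


@dataclass(frozen=True)
class SelectionConfig:
    rho_threshold: float = 0.8
    n_trees: int = 500
    rf_seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.rho_threshold <= 1.0:
            raise ParameterError("rho_threshold: must lie in (0, 1]")
        if self.n_trees < 1:
            raise ParameterError("n_trees: must be >= 1")


@dataclass
class RankingResult:
    retained_features: list[str]
    removed_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    correlation: pd.DataFrame | None = None
    importances: dict[str, float] = field(default_factory=dict)

    @property
    def positive_set(self) -> list[str]:
        return [f for f, imp in self.importances.items() if imp > 0]

    def ranked(self) -> list[str]:
        return list(self.importances)


def spearman_filter(data: pd.DataFrame, cfg: SelectionConfig | None = None
                    ) -> RankingResult:
    """Greedy removal of redundant features at |rho| > threshold.

    ``data`` is a wide patients-by-features delta table whose column order is
    the registry order (used for tie-breaks).  Rows with missing cells are
    ignored for the correlation computation.  Exactly |rho| == threshold is
    retained ("exceeding" is strict).
    """
    cfg = cfg or SelectionConfig()
    cfg.validate()
    complete = data.dropna(axis=0)
    if len(complete) < 2:
        raise ParameterError("delta table: need >= 2 patients with complete rows")

    constant = [c for c in complete.columns if complete[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant features treated as rho=0: {constant}",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield NaN rho
        corr = complete.corr(method="spearman")
    corr = corr.fillna(0.0)

    cols = list(data.columns)
    remaining = list(cols)
    removed: list[tuple[str, str, float]] = []
    while len(remaining) > 1:
        a = corr.loc[remaining, remaining].abs().to_numpy()
        np.fill_diagonal(a, 0.0)
        m = a.max()
        if m <= cfg.rho_threshold:
            break
        i, j = np.unravel_index(int(a.argmax()), a.shape)  # row-major: first max
        if i > j:
            i, j = j, i
        fi, fj = remaining[i], remaining[j]
        others_i = np.delete(a[i], i)
        others_j = np.delete(a[j], j)
        # drop the feature more correlated with everything else; registry
        # order keeps the earlier one on ties
        drop, keep = (fi, fj) if others_i.mean() > others_j.mean() else (fj, fi)
        rho = float(corr.loc[fi, fj])
        removed.append((keep, drop, rho))
        remaining.remove(drop)
    return RankingResult(retained_features=remaining, removed_pairs=removed,
                         correlation=corr)


def _oob_permutation_importance(est: BaggingClassifier, X: np.ndarray,
                                y: np.ndarray, rng: np.random.Generator
                                ) -> np.ndarray:
    n, p = X.shape
    deltas = np.zeros(p)
    used = 0
    for tree, in_bag in zip(est.estimators_, est.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), in_bag)
        if oob.size == 0:
            continue
        Xo = X[oob]
        yo = y[oob]
        base_err = np.mean(tree.predict(Xo) != yo)
        # one batched predict per tree: stack a permuted copy per feature
        stacked = np.repeat(Xo[None, :, :], p, axis=0)
        for j in range(p):
            stacked[j, :, j] = Xo[rng.permutation(oob.size), j]
        pred = tree.predict(stacked.reshape(p * oob.size, p))
        perm_err = (pred.reshape(p, oob.size) != yo[None, :]).mean(axis=1)
        deltas += perm_err - base_err
        used += 1
    if used == 0:
        raise ParameterError("n_trees: no tree had out-of-bag samples")
    return deltas / used


def rf_rank(data: pd.DataFrame, outcomes: pd.Series,
            cfg: SelectionConfig | None = None,
            prior: RankingResult | None = None) -> RankingResult:
    """Rank features by out-of-bag permutation importance.

    ``data`` holds the (already filtered) delta features; ``outcomes`` is the
    binary label per patient.  Returns a result whose ``importances`` are in
    descending order (registry order on ties) and whose ``positive_set``
    contains the features with strictly positive importance.
    """
    cfg = cfg or SelectionConfig()
    cfg.validate()
    complete = data.dropna(axis=0)
    y = outcomes.loc[complete.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise ParameterError("outcomes: both classes must be present")
    X = complete.to_numpy(dtype=np.float64)

    ss = np.random.SeedSequence(cfg.rf_seed)
    skl_seed, perm_seed = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
    est = BaggingClassifier(
        estimator=DecisionTreeClassifier(criterion="gini", max_features="sqrt",
                                         random_state=0),
        n_estimators=cfg.n_trees, bootstrap=True, random_state=skl_seed)
    est.fit(X, y)
    imp = _oob_permutation_importance(est, X, y, np.random.default_rng(perm_seed))

    cols = list(data.columns)
    order = sorted(range(len(cols)), key=lambda k: (-imp[k], k))
    importances = {cols[k]: float(imp[k]) for k in order}
    return RankingResult(
        retained_features=cols,
        removed_pairs=prior.removed_pairs if prior else [],
        correlation=prior.correlation if prior else None,
        importances=importances)
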