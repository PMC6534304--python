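"""Feature-selection routes: RFE wrapper, tree-embedded importances, and
Mann-Whitney U ranking.

Three complementary routes rank the 51 acoustic features:

* ``rfe_rank`` — recursive feature elimination wrapped around a linear SVM:
  repeatedly fit, drop the feature with the smallest |coefficient|, and
  rank features by reverse elimination order (last survivor = rank 1).
* ``embedded_rank`` — mean impurity-decrease importance of a random-forest
  ensemble (deterministic under a fixed seed).
* ``mannwhitney_rank`` — per-feature two-sided Mann-Whitney U test between
  the classes; the reported statistic is min(U1, U2) (the SPSS convention)
  and features with p < alpha are selected, ranked by ascending U.

``RouteSelector`` wraps any route as a scikit-learn transformer so the
routes compose with Pipelines and leakage-controlled cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

ROUTES = ("rfe", "embedded", "utest")
EMBEDDED_SEED = 13


@dataclass
class SelectionResult:
    """A full ranking of the feature columns plus the chosen subset."""

    ranking: list[str]                    # best first
    scores: dict[str, float]              # route-specific score per feature
    selected: list[str]
    p_values: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, name in enumerate(self.ranking, start=1):
            rows.append({"rank": rank, "feature": name,
                         "score": self.scores.get(name, np.nan),
                         "p_value": self.p_values.get(name, np.nan),
                         "selected": name in self.selected})
        return pd.DataFrame(rows)


def _split_xy(table: pd.DataFrame, feature_names: list[str] | None):
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c not in ("label", "group_id")]
    X = table[feature_names].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    return X, y, feature_names


def mannwhitney_rank(table: pd.DataFrame, alpha: float = 0.05,
                     feature_names: list[str] | None = None) -> SelectionResult:
    """Rank features by two-sided Mann-Whitney U between the two classes.

    U is reported as min(U1, U2); small U means strong separation. Ties in
    U are broken by ascending p, then column order. ``selected`` contains
    the features significant at ``alpha``.
    """
    X, y, names = _split_xy(table, feature_names)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("Mann-Whitney ranking needs exactly two classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    n1, n2 = len(a), len(b)
    us, ps = [], []
    for j in range(X.shape[1]):
        res = mannwhitneyu(a[:, j], b[:, j], alternative="two-sided")
        u = min(float(res.statistic), n1 * n2 - float(res.statistic))
        us.append(u)
        ps.append(float(res.pvalue))
    order = sorted(range(len(names)), key=lambda j: (us[j], ps[j], j))
    ranking = [names[j] for j in order]
    scores = dict(zip(names, us))
    p_values = dict(zip(names, ps))
    selected = [n for n in ranking if p_values[n] < alpha]
    return SelectionResult(ranking, scores, selected, p_values)


def _default_rfe_evaluator() -> LinearSVC:
    return LinearSVC(C=1.0, max_iter=5000)


def rfe_rank(table: pd.DataFrame, evaluator=None, step: int = 1,
             n_select: int | None = None,
             feature_names: list[str] | None = None) -> SelectionResult:
    """Recursive feature elimination with a linear evaluator.

    The caller supplies training-fold data only (already standardized when
    a scale-sensitive evaluator is used). At each pass the ``step``
    features with the smallest |coefficient| (or importance) are dropped;
    ties drop the later column. Ranking is reverse elimination order.
    """
    X, y, names = _split_xy(table, feature_names)
    if evaluator is None:
        evaluator = _default_rfe_evaluator()
    remaining = list(range(len(names)))
    elimination_order: list[int] = []
    while remaining:
        est = clone(evaluator)
        est.fit(X[:, remaining], y)
        w = _importance_surface(est)
        if w is None:
            raise ValueError(
                "RFE evaluator exposes no coefficient or importance surface")
        k = min(step, len(remaining)) if len(remaining) > 1 else 1
        # smallest weight dropped first; ties drop the later column
        order = sorted(range(len(remaining)),
                       key=lambda i: (w[i], -remaining[i]))
        drop = [remaining[i] for i in order[:k]]
        for j in drop:
            elimination_order.append(j)
            remaining.remove(j)
    ranking_idx = list(reversed(elimination_order))
    ranking = [names[j] for j in ranking_idx]
    scores = {names[j]: float(len(elimination_order) - pos)
              for pos, j in enumerate(elimination_order)}
    n_sel = n_select if n_select is not None else len(names)
    return SelectionResult(ranking, scores, ranking[:n_sel])


def _importance_surface(est) -> np.ndarray | None:
    if hasattr(est, "coef_"):
        return np.abs(np.asarray(est.coef_)).sum(axis=0)
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_)
    return None


def embedded_rank(table: pd.DataFrame, ensemble=None,
                  seed: int = EMBEDDED_SEED,
                  n_select: int | None = None,
                  feature_names: list[str] | None = None) -> SelectionResult:
    """Rank features by mean impurity-decrease importance of a tree ensemble."""
    X, y, names = _split_xy(table, feature_names)
    if ensemble is None:
        ensemble = RandomForestClassifier(n_estimators=200, random_state=seed)
    est = clone(ensemble)
    if hasattr(est, "random_state"):
        est.random_state = seed
    est.fit(X, y)
    imp = est.feature_importances_
    order = sorted(range(len(names)), key=lambda j: (-imp[j], j))
    ranking = [names[j] for j in order]
    scores = {names[j]: float(imp[j]) for j in range(len(names))}
    n_sel = n_select if n_select is not None else len(names)
    return SelectionResult(ranking, scores, ranking[:n_sel])


def rank_features(table: pd.DataFrame, route: str,
                  feature_names: list[str] | None = None,
                  seed: int = EMBEDDED_SEED) -> SelectionResult:
    """Dispatch to one of the three selection routes."""
    if route == "utest":
        return mannwhitney_rank(table, feature_names=feature_names)
    if route == "rfe":
        return rfe_rank(table, feature_names=feature_names)
    if route == "embedded":
        return embedded_rank(table, seed=seed, feature_names=feature_names)
    raise ValueError(f"unknown selection route {route!r}; expected one of {ROUTES}")


class RouteSelector(BaseEstimator, TransformerMixin):
    """scikit-learn transformer selecting the top-k features of one route.

    Fit ranks the features of the training data with the configured route
    and keeps the first ``n_features`` of the ranking; transform slices
    those columns. Designed to sit inside a Pipeline after a scaler so the
    ranking is always computed on training folds only.
    """

    def __init__(self, route: str = "rfe", n_features: int = 10,
                 seed: int = EMBEDDED_SEED):
        self.route = route
        self.n_features = n_features
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        names = [str(j) for j in range(X.shape[1])]
        df = pd.DataFrame(X, columns=names)
        df["label"] = y
        result = rank_features(df, self.route, feature_names=names,
                               seed=self.seed)
        k = min(self.n_features, X.shape[1])
        self.ranking_ = [int(n) for n in result.ranking]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.ranking_[:k]] = True
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]
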