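"""Classifier evaluation under leakage-controlled cross-validation.

Two scenarios mirror a per-recording and a per-segment analysis:

* ``nested_kfold`` — one row per patient; stratified 5-fold outer loop, an
  inner stratified loop on each outer-training portion tunes the number of
  selected features and the classifier hyper-parameters, the best inner
  configuration is refit on the full outer-training rows and scored on the
  held-out outer fold.
* ``logout_eval`` — one row per one-minute segment with a patient
  ``group_id``; leave-one-group-out outer loop (all segments of one
  patient held out together), grouped inner loop for tuning.

Standardization (the "standard scalar" z-score (x - mu) / sigma) and
feature ranking are always fitted on training rows only — fitting them on
the full table before splitting is the classic leakage error this design
guards against.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import (GroupKFold, LeaveOneGroupOut,
                                     StratifiedKFold)
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .features import POSITIVE_LABEL
from .selection import rank_features

CLASSIFIERS = ("svm", "random_forest", "adaboost", "mlp", "sgd")

#: hyper-parameter grids per classifier family
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "svm": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "random_forest": [{"n_estimators": 60, "max_depth": d} for d in (None, 5)],
    "adaboost": [{"n_estimators": n} for n in (40, 80)],
    "mlp": [{"hidden_layer_sizes": (h,)} for h in (16, 64)],
    "sgd": [{"alpha": a} for a in (1e-4, 1e-3)],
}

#: fixed mid-grid parameters used when hyper-parameter tuning is disabled
DEFAULT_PARAMS: dict[str, dict] = {
    "svm": {"C": 1.0},
    "random_forest": {"n_estimators": 60, "max_depth": None},
    "adaboost": {"n_estimators": 40},
    "mlp": {"hidden_layer_sizes": (16,)},
    "sgd": {"alpha": 1e-4},
}

#: candidate numbers of selected features tried by the inner loop
DEFAULT_FEATURE_COUNTS = (10, 22, 51)


def make_classifier(name: str, params: dict, seed: int):
    if name == "svm":
        return LinearSVC(max_iter=5000, **params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if name == "mlp":
        return MLPClassifier(max_iter=300, random_state=seed, tol=1e-3,
                             **params)
    if name == "sgd":
        return SGDClassifier(loss="hinge", random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training rows only."""

    mean_: np.ndarray
    scale_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("standardization needs at least 2 training rows")
        sc = StandardScaler().fit(X)
        if np.any(np.asarray(sc.var_) == 0):
            warnings.warn("zero-variance column(s); passed through centred",
                          stacklevel=2)
        return cls(np.asarray(sc.mean_), np.asarray(sc.scale_))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_


def standardize(train: np.ndarray, apply: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, Standardizer]:
    """Fit a Standardizer on ``train``; transform both argument matrices."""
    st = Standardizer.fit(train)
    return st.transform(train), st.transform(apply), st


@dataclass
class ClassifierReport:
    classifier: str
    fold_accuracies: list[float]
    n_selected_features: int | None
    selected_features: list[list[str]] = field(default_factory=list)
    best_params: list[dict] = field(default_factory=list)
    y_true: list[str] = field(default_factory=list)
    y_pred: list[str] = field(default_factory=list)
    group_accuracies: list[float] | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))


@dataclass
class EvalReport:
    """Per-classifier, per-feature-regime evaluation results."""

    scenario: str
    route: str | None
    reports: dict[str, dict[str, ClassifierReport]]  # regime -> clf -> report
    fold_assignments: list[list[int]] = field(default_factory=list)

    def mean_accuracy(self, regime: str) -> float:
        return float(np.mean(
            [r.mean_accuracy for r in self.reports[regime].values()]))

    def to_dict(self) -> dict:
        out = {"scenario": self.scenario, "route": self.route, "results": {}}
        for regime, clfs in self.reports.items():
            out["results"][regime] = {}
            for name, rep in clfs.items():
                sens, spec = confusion_metrics(rep)
                out["results"][regime][name] = {
                    "accuracy_mean": rep.mean_accuracy,
                    "accuracy_std": rep.std_accuracy,
                    "n_selected": rep.n_selected_features,
                    "sensitivity": sens,
                    "specificity": spec,
                }
            out["results"][regime]["mean_over_classifiers"] = \
                self.mean_accuracy(regime)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion_metrics(rep: ClassifierReport,
                      positive: str = POSITIVE_LABEL) -> tuple[float, float]:
    """(sensitivity, specificity) pooled over outer test folds.

    Sensitivity is the recall of the positive (ND) class, specificity the
    recall of the negative (FMD) class.
    """
    y_true = np.asarray(rep.y_true)
    y_pred = np.asarray(rep.y_pred)
    pos = y_true == positive
    neg = ~pos
    sens = float(np.mean(y_pred[pos] == positive)) if pos.any() else 0.0
    spec = float(np.mean(y_pred[neg] != positive)) if neg.any() else 0.0
    return sens, spec


def _table_to_xy(table: pd.DataFrame, feature_names: list[str] | None):
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c not in ("label", "group_id")]
    X = table[feature_names].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    return X, y, feature_names


def _inner_tune(X_tr, y_tr, ranking_idx, classifier, grids, feature_counts,
                inner_cv, groups_tr, seed, tune_params=True):
    """Choose (n_features, params) maximizing inner-CV accuracy."""
    param_grid = grids if tune_params else [DEFAULT_PARAMS[classifier]]
    counts = [k for k in feature_counts if k <= X_tr.shape[1]]
    if not counts:
        counts = [X_tr.shape[1]]
    best = (-1.0, counts[0], param_grid[0])
    splits = list(inner_cv.split(X_tr, y_tr, groups_tr))
    for k in counts:
        cols = ranking_idx[:k] if ranking_idx is not None else slice(None)
        for params in param_grid:
            accs = []
            for itr, iva in splits:
                st = Standardizer.fit(X_tr[itr])
                Xi = st.transform(X_tr[itr])[:, cols]
                Xv = st.transform(X_tr[iva])[:, cols]
                clf = make_classifier(classifier, params, seed)
                clf.fit(Xi, y_tr[itr])
                accs.append(np.mean(clf.predict(Xv) == y_tr[iva]))
            score = float(np.mean(accs))
            if score > best[0]:
                best = (score, k, params)
    return best[1], best[2]


def _evaluate(table, outer_splits, route, grids, feature_counts, inner_cv_fn,
              seed, feature_names=None, classifiers=CLASSIFIERS,
              tune_params=True, leak_selection_full_table=False,
              include_all_regime=True):
    """Shared outer-loop engine for both scenarios.

    ``leak_selection_full_table`` deliberately ranks features on the whole
    table before splitting; it exists only so tests can demonstrate the
    optimistic bias that the default (leakage-free) path avoids.
    """
    X, y, names = _table_to_xy(table, feature_names)
    groups = table["group_id"].to_numpy() if "group_id" in table else None
    if grids is None:
        grids = DEFAULT_GRIDS

    leaky_ranking = None
    if leak_selection_full_table and route is not None:
        res = rank_features(table, route, feature_names=names, seed=seed)
        leaky_ranking = [names.index(n) for n in res.ranking]

    regimes = (["all"] if include_all_regime or not route else []) + \
        ([route] if route else [])
    reports: dict[str, dict[str, ClassifierReport]] = {r: {} for r in regimes}
    fold_assignments = [list(te) for _, te in outer_splits]

    # rank once per outer-training set (training rows only)
    rankings: list[list[int] | None] = []
    for tr, _te in outer_splits:
        if route is None:
            rankings.append(None)
        elif leaky_ranking is not None:
            rankings.append(leaky_ranking)
        else:
            st = Standardizer.fit(X[tr])
            df_tr = pd.DataFrame(st.transform(X[tr]), columns=names)
            df_tr["label"] = y[tr]
            res = rank_features(df_tr, route, feature_names=names, seed=seed)
            rankings.append([names.index(n) for n in res.ranking])

    for clf_name in classifiers:
        for regime in regimes:
            use_route = regime != "all"
            fold_accs, sel_feats, best_params = [], [], []
            y_true_all, y_pred_all, group_accs = [], [], []
            for (tr, te), ranking_idx in zip(outer_splits, rankings):
                g_tr = groups[tr] if groups is not None else None
                inner_cv = inner_cv_fn()
                if use_route:
                    k, params = _inner_tune(
                        X[tr], y[tr], ranking_idx, clf_name, grids[clf_name],
                        feature_counts, inner_cv, g_tr, seed, tune_params)
                    cols = ranking_idx[:k]
                else:
                    _, params = _inner_tune(
                        X[tr], y[tr], None, clf_name, grids[clf_name],
                        (X.shape[1],), inner_cv, g_tr, seed, tune_params)
                    k, cols = X.shape[1], slice(None)
                st = Standardizer.fit(X[tr])
                Xtr = st.transform(X[tr])[:, cols]
                Xte = st.transform(X[te])[:, cols]
                clf = make_classifier(clf_name, params, seed)
                clf.fit(Xtr, y[tr])
                pred = clf.predict(Xte)
                fold_accs.append(float(np.mean(pred == y[te])))
                y_true_all.extend(y[te])
                y_pred_all.extend(pred)
                sel_feats.append([names[j] for j in (
                    cols if isinstance(cols, list) else range(X.shape[1]))][:k])
                best_params.append(params)
                if groups is not None:
                    for g in np.unique(groups[te]):
                        m = groups[te] == g
                        group_accs.append(float(np.mean(pred[m] == y[te][m])))
            reports[regime][clf_name] = ClassifierReport(
                classifier=clf_name, fold_accuracies=fold_accs,
                n_selected_features=int(np.median([len(s) for s in sel_feats]))
                if use_route else X.shape[1],
                selected_features=sel_feats, best_params=best_params,
                y_true=y_true_all, y_pred=y_pred_all,
                group_accuracies=group_accs or None)
    scenario = "segments" if groups is not None and \
        len(np.unique(groups)) < len(table) else "recordings"
    return EvalReport(scenario, route, reports, fold_assignments)


def nested_kfold(table: pd.DataFrame, k: int = 5, route: str | None = "rfe",
                 grids: dict | None = None,
                 feature_counts=DEFAULT_FEATURE_COUNTS,
                 seed: int = 0, inner_k: int = 5,
                 classifiers=CLASSIFIERS, tune_params: bool = True,
                 _leak_selection: bool = False) -> EvalReport:
    """Scenario 1: nested stratified k-fold on a one-row-per-patient table."""
    X, y, _ = _table_to_xy(table, None)
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(outer.split(X, y))
    inner_fn = lambda: _StratifiedInner(inner_k, seed + 1)  # noqa: E731
    return _evaluate(table, splits, route, grids, feature_counts, inner_fn,
                     seed, classifiers=classifiers, tune_params=tune_params,
                     leak_selection_full_table=_leak_selection)


class _StratifiedInner:
    """Stratified inner CV; ignores the groups argument."""

    def __init__(self, n_splits: int, seed: int):
        self.n_splits = n_splits
        self.seed = seed

    def split(self, X, y, groups=None):
        _, counts = np.unique(y, return_counts=True)
        n = max(2, min(self.n_splits, int(counts.min())))
        return StratifiedKFold(n, shuffle=True,
                               random_state=self.seed).split(X, y)


class _GroupedInner:
    """Grouped inner CV that ignores the stratification argument."""

    def __init__(self, n_splits: int):
        self.n_splits = n_splits

    def split(self, X, y, groups):
        if groups is None:
            return StratifiedKFold(self.n_splits, shuffle=True,
                                   random_state=0).split(X, y)
        n = min(self.n_splits, len(np.unique(groups)))
        return GroupKFold(n_splits=n).split(X, y, groups)


def logout_eval(table: pd.DataFrame, route: str | None = "rfe",
                grids: dict | None = None,
                feature_counts=DEFAULT_FEATURE_COUNTS,
                seed: int = 0, inner_k: int = 3,
                classifiers=CLASSIFIERS,
                tune_params: bool = False,
                include_all_regime: bool = True) -> EvalReport:
    """Scenario 2: leave-one-group-out over per-segment rows.

    Every outer split holds out all segments of one patient; the inner
    loop is grouped so no patient leaks between inner training and
    validation. By default only the feature count is tuned in the inner
    loop (hyper-parameters at mid-grid), keeping the 30-group loop fast.
    """
    if "group_id" not in table:
        raise ValueError("leave-one-group-out requires a group_id column")
    groups = table["group_id"].to_numpy()
    if len(np.unique(groups)) < 3:
        raise ValueError("need at least 3 groups")
    X, y, _ = _table_to_xy(table, None)
    logo = LeaveOneGroupOut()
    splits = list(logo.split(X, y, groups))
    for tr, te in splits:
        if set(groups[tr]) & set(groups[te]):
            raise AssertionError("group appears on both sides of a split")
    inner_fn = lambda: _GroupedInner(inner_k)  # noqa: E731
    return _evaluate(table, splits, route, grids, feature_counts, inner_fn,
                     seed, classifiers=classifiers, tune_params=tune_params,
                     include_all_regime=include_all_regime)
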