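"""Binary canopy-health classification on per-slice VI features.

Three classical supervised learners are supported with fixed, documented
hyperparameters — random forest (100 trees, Gini impurity, unbounded
depth), K-nearest neighbors (k=5, uniform weights, ball-tree with leaf
size 30, Euclidean metric) and L2-penalized logistic regression (lbfgs) —
plus an optional seeded random-search over documented spaces with
stratified k-fold (k=5) cross-validation.

Evaluation centers on the costliest field error: a truly unhealthy slice
predicted healthy (false negative, positive class = unhealthy = 1). The
:class:`EvalReport` carries the confusion counts, accuracy, per-class
precision/recall/F1 with macro and support-weighted averages, and the
false-negative rate over the whole test set.

The module is exposed statsmodels-style: build a :class:`HealthClassifier`
from a feature table, call :meth:`~HealthClassifier.fit`, and read the
:class:`HealthResults` (reports, cross-validation, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    RandomizedSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .vegindex import SELECTED_FEATURES

__all__ = [
    "SplitSpec",
    "ModelSpec",
    "EvalReport",
    "stratified_split",
    "build_estimator",
    "fit",
    "evaluate",
    "crossval",
    "HealthClassifier",
    "HealthResults",
    "ALGORITHMS",
]

ALGORITHMS = ("random_forest", "knn", "logistic_regression")

#: Random-search spaces (used only when ModelSpec.search = "random_search").
SEARCH_SPACES = {
    "random_forest": {
        "clf__n_estimators": [50, 100, 200, 400],
        "clf__max_depth": [None, 4, 8, 16],
        "clf__min_samples_leaf": [1, 2, 5],
    },
    "knn": {
        "clf__n_neighbors": [3, 5, 7, 11, 15],
        "clf__weights": ["uniform", "distance"],
        "clf__leaf_size": [10, 30, 50],
    },
    "logistic_regression": {
        "clf__C": [0.01, 0.1, 1.0, 10.0, 100.0],
    },
}


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: stratified 80-20 by default."""

    test_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """Which learner to fit and how.

    ``search='none'`` uses the fixed hyperparameters above;
    ``search='random_search'`` tunes within :data:`SEARCH_SPACES` by
    accuracy over ``cv_folds`` stratified folds, then refits on the full
    training set. ``standardize`` z-scores features inside the estimator
    pipeline (off by default; KNN is the scale-sensitive one).
    """

    algorithm: str = "random_forest"
    cv_folds: int = 5
    search: str = "none"
    search_budget: int = 20
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.search not in ("none", "random_search"):
            raise ValueError(f"unknown search mode {self.search!r}")


@dataclass
class EvalReport:
    """Confusion counts and derived metrics; positive class = unhealthy (1)."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def n_test(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_test

    @property
    def fn_count(self) -> int:
        return self.fn

    @property
    def fn_rate(self) -> float:
        """False negatives over the whole test set (not just positives)."""
        return self.fn / self.n_test

    def precision(self, cls: int) -> float:
        pred = (self.tp + self.fp) if cls == 1 else (self.tn + self.fn)
        hit = self.tp if cls == 1 else self.tn
        return hit / pred if pred else 0.0

    def recall(self, cls: int) -> float:
        true = (self.tp + self.fn) if cls == 1 else (self.tn + self.fp)
        hit = self.tp if cls == 1 else self.tn
        return hit / true if true else 0.0

    def f1(self, cls: int) -> float:
        p, r = self.precision(cls), self.recall(cls)
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def support(self, cls: int) -> int:
        return (self.tp + self.fn) if cls == 1 else (self.tn + self.fp)

    def macro(self, metric: str) -> float:
        f = getattr(self, metric)
        return (f(0) + f(1)) / 2.0

    def weighted(self, metric: str) -> float:
        f = getattr(self, metric)
        n = self.n_test
        return (self.support(0) * f(0) + self.support(1) * f(1)) / n

    def to_dict(self) -> dict:
        return {
            "confusion": {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp},
            "n_test": self.n_test,
            "accuracy": self.accuracy,
            "per_class": {
                str(c): {
                    "precision": self.precision(c),
                    "recall": self.recall(c),
                    "f1": self.f1(c),
                    "support": self.support(c),
                }
                for c in (0, 1)
            },
            "macro": {m: self.macro(m) for m in ("precision", "recall", "f1")},
            "weighted": {m: self.weighted(m) for m in ("precision", "recall", "f1")},
            "fn_count": self.fn_count,
            "fn_rate": self.fn_rate,
        }


def _check_features(df: pd.DataFrame, feature_names: Sequence[str]) -> np.ndarray:
    cols = [f.lower() for f in feature_names]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    X = df[cols].to_numpy(dtype=float)
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        ids = (
            df.loc[bad, "slice_id"].tolist()
            if "slice_id" in df.columns
            else df.index[bad].tolist()
        )
        raise ValueError(f"non-finite feature values for slice(s): {ids[:10]}")
    return X


def stratified_split(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition, stratified by label."""
    labels = table["label"].astype(int)
    if labels.nunique() < 2:
        raise ValueError("both classes must be present to split")
    if len(table) < 10:
        raise ValueError("need at least 10 records to split")
    train, test = train_test_split(
        table,
        test_size=spec.test_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
    )
    return train, test


def build_estimator(spec: ModelSpec, seed: int = 0):
    """The scikit-learn estimator (optionally inside a scaling pipeline)."""
    if spec.algorithm == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=100, criterion="gini", max_depth=None, random_state=seed
        )
    elif spec.algorithm == "knn":
        clf = KNeighborsClassifier(
            n_neighbors=5, weights="uniform", algorithm="ball_tree", leaf_size=30, metric="euclidean"
        )
    else:
        # L2 penalty (the sklearn default) with a quasi-Newton (lbfgs) solver
        clf = LogisticRegression(solver="lbfgs", tol=1e-4, max_iter=1000)
    steps = [("scale", StandardScaler())] if spec.standardize else []
    return Pipeline(steps + [("clf", clf)])


def fit(
    spec: ModelSpec,
    train: pd.DataFrame,
    feature_names: Sequence[str] = SELECTED_FEATURES,
    seed: int = 0,
):
    """Fit one learner on a labeled feature table; returns the predictor."""
    X = _check_features(train, feature_names)
    y = train["label"].to_numpy(dtype=int)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary {0, 1}")
    est = build_estimator(spec, seed=seed)
    if spec.search == "random_search":
        cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
        est = RandomizedSearchCV(
            est,
            SEARCH_SPACES[spec.algorithm],
            n_iter=spec.search_budget,
            scoring="accuracy",
            cv=cv,
            random_state=seed,
            refit=True,
        )
    est.fit(X, y)
    est.feature_names_ = tuple(feature_names)
    return est


def evaluate(model, test: pd.DataFrame, feature_names: Sequence[str] | None = None) -> EvalReport:
    """Confusion-matrix evaluation of a fitted predictor on a test table."""
    feature_names = feature_names or getattr(model, "feature_names_", SELECTED_FEATURES)
    X = _check_features(test, feature_names)
    y = test["label"].to_numpy(dtype=int)
    if len(y) == 0:
        raise ValueError("test set is empty")
    pred = np.asarray(model.predict(X), dtype=int)
    tn = int(((y == 0) & (pred == 0)).sum())
    fp = int(((y == 0) & (pred == 1)).sum())
    fn = int(((y == 1) & (pred == 0)).sum())
    tp = int(((y == 1) & (pred == 1)).sum())
    return EvalReport(tn=tn, fp=fp, fn=fn, tp=tp)


def crossval(
    spec: ModelSpec,
    table: pd.DataFrame,
    feature_names: Sequence[str] = SELECTED_FEATURES,
    seed: int = 0,
) -> dict:
    """Stratified k-fold CV: per-fold EvalReports plus mean +/- sd accuracy."""
    y = table["label"].to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if (counts < spec.cv_folds).any():
        raise ValueError(
            f"each class needs >= {spec.cv_folds} members, got {counts.tolist()}"
        )
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    reports: list[EvalReport] = []
    for train_idx, test_idx in cv.split(np.zeros(len(y)), y):
        model = fit(spec, table.iloc[train_idx], feature_names, seed=seed)
        reports.append(evaluate(model, table.iloc[test_idx], feature_names))
    acc = np.array([r.accuracy for r in reports])
    return {
        "fold_reports": reports,
        "mean_accuracy": float(acc.mean()),
        "sd_accuracy": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
    }


# -- model/results facade -------------------------------------------------


class HealthClassifier:
    """Canopy-health classification model over a per-slice feature table.

    Parameters
    ----------
    data : DataFrame with lower-case VI feature columns and a binary
        ``label`` column (1 = unhealthy).
    feature_names : VI subset used as predictors.
    spec, split : learner and split specifications.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_names: Sequence[str] = SELECTED_FEATURES,
        spec: ModelSpec = ModelSpec(),
        split: SplitSpec = SplitSpec(),
    ):
        self.data = data.reset_index(drop=True)
        self.feature_names = tuple(feature_names)
        self.spec = spec
        self.split = split
        _check_features(self.data, self.feature_names)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "HealthClassifier":
        return cls(data, **kwargs)

    def fit(self, seed: int | None = None, run_cv: bool = True) -> "HealthResults":
        seed = self.split.seed if seed is None else seed
        split = SplitSpec(self.split.test_fraction, self.split.stratified, seed)
        train, test = stratified_split(self.data, split)
        model = fit(self.spec, train, self.feature_names, seed=seed)
        report = evaluate(model, test, self.feature_names)
        cv = crossval(self.spec, self.data, self.feature_names, seed=seed) if run_cv else None
        return HealthResults(self, model, train, test, report, cv, seed)


class HealthResults:
    """Fit artifacts: the predictor, hold-out report and CV diagnostics."""

    def __init__(self, model_obj, estimator, train, test, report, cv, seed):
        self.model = model_obj
        self.estimator = estimator
        self.train = train
        self.test = test
        self.report: EvalReport = report
        self.cv = cv
        self.seed = seed

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = _check_features(data, self.model.feature_names)
        return np.asarray(self.estimator.predict(X), dtype=int)

    def summary(self) -> str:
        r = self.report
        lines = [
            "Canopy health classification",
            "=" * 60,
            f"algorithm:     {self.model.spec.algorithm}",
            f"features:      {', '.join(self.model.feature_names)}",
            f"train/test:    {len(self.train)}/{len(self.test)} "
            f"(test fraction {self.model.split.test_fraction})",
            f"seed:          {self.seed}",
            "-" * 60,
            "class      precision  recall     f1      support",
            f"healthy(0)   {r.precision(0):7.3f} {r.recall(0):7.3f} {r.f1(0):7.3f} {r.support(0):8d}",
            f"unhealthy(1) {r.precision(1):7.3f} {r.recall(1):7.3f} {r.f1(1):7.3f} {r.support(1):8d}",
            f"macro avg    {r.macro('precision'):7.3f} {r.macro('recall'):7.3f} {r.macro('f1'):7.3f}",
            f"weighted avg {r.weighted('precision'):7.3f} {r.weighted('recall'):7.3f} {r.weighted('f1'):7.3f}",
            "-" * 60,
            f"accuracy:      {r.accuracy:.3f}",
            f"false negatives: {r.fn_count} of {r.n_test} test slices "
            f"({100 * r.fn_rate:.1f}%)",
        ]
        if self.cv is not None:
            lines.append(
                f"{self.model.spec.cv_folds}-fold CV accuracy: "
                f"{self.cv['mean_accuracy']:.3f} +/- {self.cv['sd_accuracy']:.3f}"
            )
        return "\n".join(lines)
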