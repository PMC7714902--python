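"""Cross-validated stress harness: classification accuracy and regression RMSE.

The benefit of an enhanced cohort is measured two ways, both with
10-fold cross-validation:

* **classification** — predict each patient's class label (the stratum
  defined by the full binary pattern) from all B + P features, scoring
  percent accuracy over the held-out folds; and
* **regression** — predict a binary endpoint, encoded 0/1 and regressed
  as numeric, from the remaining (B - 2) + P features (both endpoints
  are excluded from the predictors), scoring root-mean-square error.

Learner presets mirror the common interactive-tool defaults they are
named after: a fine decision tree (CART, Gini, at most 100 splits for
classification; minimum leaf size 4 for regression), 1-nearest-neighbour
and 10-NN with squared-inverse-distance weights, a linear SVM (C = 1,
one-vs-one), ordinary least squares, and a linear epsilon-insensitive
SVR (C = 1, epsilon = 0.1).  Numeric predictors are standardized with
train-fold statistics for the distance- and margin-based learners; trees
and OLS see raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .io import CohortTable
from .preprocess import StratifiedCohort, restratify

__all__ = [
    "EvalResult",
    "CLASSIFIERS",
    "REGRESSORS",
    "crossval_accuracy",
    "crossval_rmse",
    "stress_report",
]

CLASSIFIERS = ("fine_tree", "fine_knn", "weighted_knn", "linear_svm")
REGRESSORS = ("fine_tree", "linear", "linear_svm")


@dataclass
class EvalResult:
    """One cross-validated score (accuracy in % or RMSE)."""

    task: str
    learner: str
    metric: float
    per_fold: list[float]
    n: int
    seed: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task == "classification" and not (0.0 <= self.metric <= 100.0):
            raise ValueError("accuracy must lie in [0, 100]")
        if self.task == "regression" and self.metric < 0:
            raise ValueError("RMSE must be non-negative")


def _squared_inverse_weights(dist: np.ndarray) -> np.ndarray:
    """1/d^2 neighbour weights; exact matches get all the weight."""
    with np.errstate(divide="ignore"):
        w = 1.0 / (dist**2)
    inf_rows = np.isinf(w).any(axis=1)
    if inf_rows.any():
        w[inf_rows] = np.isinf(w[inf_rows]).astype(float)
    return w


def _with_scaler(estimator, numeric_idx: Sequence[int], standardize: bool):
    # All predictors (dummies included) are standardized with train-fold
    # statistics, matching the presets these learners are named after.
    if not standardize:
        return estimator
    return Pipeline([("scale", StandardScaler()), ("model", estimator)])


def _classifier(name: str, seed: int, numeric_idx: Sequence[int]):
    if name == "fine_tree":
        return DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=101, random_state=seed
        )
    if name == "fine_knn":
        return _with_scaler(KNeighborsClassifier(n_neighbors=1), numeric_idx, True)
    if name == "weighted_knn":
        return _with_scaler(
            KNeighborsClassifier(n_neighbors=10, weights=_squared_inverse_weights),
            numeric_idx,
            True,
        )
    if name == "linear_svm":
        return _with_scaler(SVC(kernel="linear", C=1.0), numeric_idx, True)
    raise ValueError(f"unknown classifier preset {name!r}; choose from {CLASSIFIERS}")


def _regressor(name: str, seed: int, numeric_idx: Sequence[int]):
    if name == "fine_tree":
        return DecisionTreeRegressor(min_samples_leaf=4, random_state=seed)
    if name == "linear":
        return LinearRegression()
    if name == "linear_svm":
        return _with_scaler(
            LinearSVR(C=1.0, epsilon=0.1, max_iter=20_000, random_state=seed),
            numeric_idx,
            True,
        )
    raise ValueError(f"unknown regressor preset {name!r}; choose from {REGRESSORS}")


def _classification_xy(strat: StratifiedCohort) -> tuple[np.ndarray, np.ndarray, list[int]]:
    Xb = strat.table.binary_matrix().to_numpy(dtype=float)
    Xn = strat.table.numeric_matrix()
    X = np.hstack([Xb, Xn])
    numeric_idx = list(range(Xb.shape[1], X.shape[1]))
    return X, strat.class_index.copy(), numeric_idx


def crossval_accuracy(
    data: StratifiedCohort | CohortTable,
    learner: str = "fine_knn",
    seed: int = 0,
    folds: int = 10,
) -> EvalResult:
    """10-fold cross-validated class-label accuracy (%).

    Folds are stratified by class where possible; classes smaller than
    the fold count may be entirely held out of some training folds, and
    their test rows then count as errors — the price of very small
    strata.  Every row is predicted exactly once.
    """
    strat = data if isinstance(data, StratifiedCohort) else restratify(data)
    if strat.n_classes < 2:
        raise ValueError("classification needs at least two classes")
    X, y, numeric_idx = _classification_xy(strat)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = np.zeros(len(y), dtype=bool)
    per_fold: list[float] = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*least populated class.*")
        for train, test in cv.split(X, y):
            model = _classifier(learner, seed, numeric_idx)
            model.fit(X[train], y[train])
            pred = model.predict(X[test])
            correct[test] = pred == y[test]
            per_fold.append(100.0 * float(np.mean(pred == y[test])))
    return EvalResult(
        task="classification",
        learner=learner,
        metric=100.0 * float(correct.mean()),
        per_fold=per_fold,
        n=len(y),
        seed=seed,
    )


def crossval_rmse(
    table: CohortTable,
    endpoint: str,
    learner: str = "fine_tree",
    seed: int = 0,
    folds: int = 10,
) -> EvalResult:
    """10-fold cross-validated RMSE for a 0/1 endpoint regressed as numeric.

    Predictors are all binary features except the two endpoints, plus
    all numeric features; the target endpoint is never among them.
    """
    schema = table.schema
    if endpoint not in schema.endpoint_features:
        raise ValueError(f"{endpoint!r} is not a declared endpoint")
    predictors = [b for b in schema.binary_features if b not in schema.endpoint_features]
    Xb = table.df[predictors].to_numpy(dtype=float)
    Xn = table.numeric_matrix()
    X = np.hstack([Xb, Xn])
    numeric_idx = list(range(Xb.shape[1], X.shape[1]))
    y = table.df[endpoint].to_numpy(dtype=float)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_err = np.zeros(len(y))
    per_fold: list[float] = []
    for train, test in cv.split(X):
        model = _regressor(learner, seed, numeric_idx)
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        sq_err[test] = (pred - y[test]) ** 2
        per_fold.append(float(np.sqrt(np.mean((pred - y[test]) ** 2))))
    return EvalResult(
        task="regression",
        learner=learner,
        metric=float(np.sqrt(sq_err.mean())),
        per_fold=per_fold,
        n=len(y),
        seed=seed,
        extra={"endpoint": endpoint},
    )


def stress_report(
    datasets: Mapping[str, CohortTable | StratifiedCohort],
    seed: int = 0,
    classifiers: Sequence[str] = CLASSIFIERS,
    regressors: Sequence[str] = REGRESSORS,
    folds: int = 10,
) -> dict[str, pd.DataFrame]:
    """Full accuracy/RMSE grid over several datasets (learners x datasets).

    ``datasets`` maps a display name (e.g. ``original``, ``20x shuffle``)
    to a table; all must share one schema.  Returns one DataFrame of
    percent accuracies plus one RMSE DataFrame per endpoint, each with
    learners as rows and datasets as columns — the natural layout for a
    side-by-side comparison of the original and enhanced cohorts.
    """
    if not datasets:
        raise ValueError("no datasets given")
    tables = {
        name: (d.table if isinstance(d, StratifiedCohort) else d)
        for name, d in datasets.items()
    }
    schema = next(iter(tables.values())).schema
    if any(t.schema != schema for t in tables.values()):
        raise ValueError("datasets must share a schema")
    grids: dict[str, pd.DataFrame] = {}
    acc = pd.DataFrame(index=list(classifiers), columns=list(tables), dtype=float)
    for name, data in datasets.items():
        for learner in classifiers:
            acc.loc[learner, name] = crossval_accuracy(
                data, learner, seed=seed, folds=folds
            ).metric
    grids["accuracy"] = acc
    for endpoint in schema.endpoint_features:
        grid = pd.DataFrame(index=list(regressors), columns=list(tables), dtype=float)
        for name, table in tables.items():
            for learner in regressors:
                grid.loc[learner, name] = crossval_rmse(
                    table, endpoint, learner, seed=seed, folds=folds
                ).metric
        grids[f"rmse_{endpoint}"] = grid
    return grids
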