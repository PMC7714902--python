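"""Cardinality-enhancement generators and the k-fold enlargement loop.

Two generators create synthetic patients inside existing strata:

* the intraclass-intrafeature **shuffle**, which independently permutes
  each numeric feature's values among the patients of one class — every
  synthetic patient is a recombination of observed, class-consistent
  values, so per-class value multisets (and hence per-class means) are
  conserved exactly; and
* the **repeated-measures** comparator, a Gaussian linear model with
  the class as the sole categorical predictor: per-class mean vectors
  with a covariance pooled across classes, sampled as a class-conditional
  multivariate normal.

Both run inside :func:`enhance`, which accumulates whole-cohort passes,
deletes exact replicas of any already-present patient after every pass,
and stops when the target multiplier is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .io import SYNTHETIC, CohortTable
from .preprocess import StratifiedCohort

__all__ = [
    "RepeatedMeasuresModel",
    "EnhancementReport",
    "intraclass_shuffle_once",
    "fit_repeated_measures",
    "sample_repeated_measures",
    "deduplicate",
    "enhance",
    "max_unique_bound",
]

Method = Literal["shuffle", "repeated_measures"]

#: Relative ridge added to a pooled covariance that fails Cholesky.
RIDGE_EPS = 1e-8
#: Tolerance below which a negative eigenvalue is a numerical error.
PSD_TOL = 1e-10


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class RepeatedMeasuresModel:
    """Class-conditional Gaussian model of the numeric features.

    ``pooled_cov`` is the residual covariance about the per-class means
    with denominator ``n - G`` (the multivariate one-way model's
    unbiased estimate, shared by all classes).
    """

    class_means: np.ndarray  # (G, P)
    pooled_cov: np.ndarray  # (P, P)
    class_keys: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        c = self.pooled_cov
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("pooled covariance is not symmetric")
        min_eig = float(np.linalg.eigvalsh(c).min())
        scale = max(1.0, float(np.trace(c)))
        if min_eig < -PSD_TOL * scale:
            raise ValueError(f"pooled covariance is not PSD (min eigenvalue {min_eig:g})")


@dataclass
class EnhancementReport:
    """Provenance of one enhancement run."""

    method: str
    multiplier: int
    seed: int | None
    cardinality_before: int
    cardinality_after: int
    duplicates_deleted: int
    saturated: bool
    rounds: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cardinality_after > self.multiplier * self.cardinality_before:
            raise ValueError("enhanced cardinality exceeds the k-fold target")
        if self.cardinality_after < self.cardinality_before:
            raise ValueError("enhancement lost rows")


def _synthetic_like(strat: StratifiedCohort, numerics: np.ndarray) -> CohortTable:
    """Build a synthetic table with the original binary block and new numerics."""
    schema = strat.table.schema
    df = strat.table.df.copy()
    if schema.id_column:
        df[schema.id_column] = ""
    df[list(schema.numeric_features)] = numerics
    return CohortTable(schema, df, [SYNTHETIC] * len(df))


def intraclass_shuffle_once(
    strat: StratifiedCohort, seed: int | np.random.Generator
) -> CohortTable:
    """One whole-cohort pass of the intraclass-intrafeature shuffle.

    For each class and each numeric feature independently, the feature's
    values within the class block are replaced by a uniformly random
    permutation of themselves.  Binary features (endpoints included) are
    copied unchanged, so every synthetic row keeps its class key.  The
    generator is consumed in class-index then feature-index order, which
    makes results reproducible for a given seed.
    """
    if np.any(strat.class_sizes < 2):
        raise ValueError("shuffle requires every class size >= 2 (drop monoexamples first)")
    rng = _rng(seed)
    numerics = strat.table.numeric_matrix().copy()
    for sl in strat.class_slices():
        block = numerics[sl]
        m = block.shape[0]
        for j in range(block.shape[1]):
            block[:, j] = block[rng.permutation(m), j]
        numerics[sl] = block
    return _synthetic_like(strat, numerics)


def fit_repeated_measures(strat: StratifiedCohort) -> RepeatedMeasuresModel:
    """Fit the class-conditional Gaussian (repeated-measures) model.

    Class means are exact sample means; the pooled covariance is the
    residual cross-product divided by ``n - G``.  A singular pooled
    covariance is legal here and handled at sampling time.
    """
    n, G = strat.n_rows, strat.n_classes
    if n <= G:
        raise ValueError(f"no residual degrees of freedom: n={n} <= G={G}")
    X = strat.table.numeric_matrix()
    P = X.shape[1]
    means = np.empty((G, P))
    resid = np.empty_like(X)
    for g, sl in enumerate(strat.class_slices()):
        means[g] = X[sl].mean(axis=0)
        resid[sl] = X[sl] - means[g]
    pooled = resid.T @ resid / (n - G)
    pooled = (pooled + pooled.T) / 2.0
    return RepeatedMeasuresModel(means, pooled, list(strat.class_keys))


def _cholesky_with_ridge(cov: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, ridge-regularized if the matrix is singular."""
    P = cov.shape[0]
    trace = float(np.trace(cov))
    if trace <= 0.0:
        return np.zeros_like(cov)  # degenerate: all residuals are zero
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        ridge = RIDGE_EPS * trace / P
        return np.linalg.cholesky(cov + ridge * np.eye(P))


def sample_repeated_measures(
    model: RepeatedMeasuresModel,
    strat: StratifiedCohort,
    seed: int | np.random.Generator,
) -> CohortTable:
    """Draw one synthetic patient per original patient from the model.

    Each row's numerics come from N(mean of its class, pooled covariance);
    binary features are the class key.  Generation is class-conditional:
    two rows of one class are exchangeable draws.
    """
    if model.class_keys != list(strat.class_keys):
        raise ValueError("model was fitted on a different stratification")
    rng = _rng(seed)
    L = _cholesky_with_ridge(model.pooled_cov)
    P = model.pooled_cov.shape[0]
    numerics = np.empty((strat.n_rows, P))
    for g, sl in enumerate(strat.class_slices()):
        m = sl.stop - sl.start
        z = rng.standard_normal((m, P))
        numerics[sl] = model.class_means[g] + z @ L.T
    return _synthetic_like(strat, numerics)


def deduplicate(base: CohortTable, candidates: CohortTable) -> tuple[CohortTable, int]:
    """Delete candidate rows replicating a base row or an earlier candidate.

    Row identity is exact equality on all B + P feature values.  Base
    rows (the originals, plus anything already accepted) are never
    touched — only candidates are filtered.
    """
    if base.schema != candidates.schema:
        raise ValueError("base and candidates must share a schema")
    seen = set(base.row_keys())
    keep: list[int] = []
    for i, key in enumerate(candidates.row_keys()):
        if key not in seen:
            seen.add(key)
            keep.append(i)
    kept = candidates.take(keep)
    return kept, len(candidates) - len(kept)


def enhance(
    strat: StratifiedCohort,
    method: Method,
    k: int,
    seed: int,
    max_rounds: int | None = None,
) -> tuple[CohortTable, EnhancementReport]:
    """Enlarge a stratified cohort to (at most) ``k`` times its cardinality.

    Repeats whole-cohort generator passes, deleting exact replicas of
    anything already accumulated after each pass, until the output holds
    ``k * n0`` unique patients (originals always included; excess rows
    from the final pass are dropped in generation order).  If
    ``max_rounds`` passes (default ``10 * k``) cannot fill the target —
    the unique pool is exhausted — the run is flagged ``saturated``.
    """
    if k < 1:
        raise ValueError(f"multiplier k must be >= 1, got {k}")
    if method not in ("shuffle", "repeated_measures"):
        raise ValueError(f"unknown method {method!r}")
    if max_rounds is None:
        max_rounds = 10 * k
    rng = np.random.default_rng(seed)
    n0 = strat.n_rows
    target = k * n0
    accumulated = strat.table.copy()
    model = fit_repeated_measures(strat) if method == "repeated_measures" else None
    duplicates = 0
    rounds = 0
    while len(accumulated) < target and rounds < max_rounds:
        rounds += 1
        if method == "shuffle":
            candidates = intraclass_shuffle_once(strat, rng)
        else:
            candidates = sample_repeated_measures(model, strat, rng)
        fresh, deleted = deduplicate(accumulated, candidates)
        duplicates += deleted
        room = target - len(accumulated)
        if len(fresh) > room:
            fresh = fresh.take(range(room))
        if len(fresh):
            accumulated = CohortTable.concat([accumulated, fresh])
    saturated = len(accumulated) < target
    report = EnhancementReport(
        method=method,
        multiplier=k,
        seed=seed if isinstance(seed, int) else None,
        cardinality_before=n0,
        cardinality_after=len(accumulated),
        duplicates_deleted=duplicates,
        saturated=saturated,
        rounds=rounds,
    )
    return accumulated, report


def max_unique_bound(strat: StratifiedCohort) -> int:
    """Upper bound on the unique cardinality the shuffle can reach.

    The shuffle recombines observed values per feature within a class,
    so class g can realize at most ``prod_j d_gj`` distinct rows, where
    ``d_gj`` counts the distinct values of numeric feature j inside the
    class.  The bound is the sum over classes; it is always at least the
    current cardinality because the originals are realizable.
    """
    X = strat.table.numeric_matrix()
    total = 0
    for sl in strat.class_slices():
        prod = 1
        for j in range(X.shape[1]):
            prod *= len(np.unique(X[sl, j]))
        total += prod
    return total
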