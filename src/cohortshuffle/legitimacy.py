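"""Hotelling T-squared legitimacy gate for enhanced cohorts.

An enhancement is *statistically legitimate* when the enhanced dataset
is, multivariately, the same population as the original: a one-sample
Hotelling T2 test compares the enhanced table's numeric mean vector
against the original cohort's expected multivariate mean vector (EMMV)
and the enhancement passes iff the p-value is NOT significant
(p > alpha, alpha = 0.05 by default).

The statistic for a sample of size n with mean ``x̄`` and unbiased
covariance ``S`` against null mean ``mu0`` is

    T2 = n (x̄ - mu0)' S^{-1} (x̄ - mu0),
    F  = (n - P) / (P (n - 1)) * T2  ~  F(P, n - P)  under H0,

with P numeric features.  The covariance is taken from the tested
(enhanced) sample; mu0 is fixed at the original cohort's mean and never
re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .augment import EnhancementReport, enhance
from .io import CohortTable
from .preprocess import StratifiedCohort, restratify

__all__ = [
    "HotellingResult",
    "emmv",
    "hotelling_t2",
    "hotelling_from_stats",
    "legitimacy_gate",
    "max_legitimate_multiplier",
    "combined_enhance",
]

#: Condition number above which the sample covariance is treated as singular.
MAX_CONDITION = 1e12


@dataclass(frozen=True)
class HotellingResult:
    """Outcome of a one-sample Hotelling T2 test."""

    t2: float
    F: float
    df1: int
    df2: int
    p: float
    n: int
    mu0: np.ndarray

    def __post_init__(self) -> None:
        if self.t2 < 0 or not (0.0 <= self.p <= 1.0) or self.df2 < 1:
            raise ValueError("invalid Hotelling result")

    def to_dict(self) -> dict:
        return {
            "t2": self.t2,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "n": self.n,
            "mu0": [float(v) for v in np.asarray(self.mu0)],
        }


def emmv(strat: StratifiedCohort | CohortTable) -> np.ndarray:
    """Expected multivariate mean vector: the original cohort's numeric means."""
    table = strat.table if isinstance(strat, StratifiedCohort) else strat
    if len(table) == 0:
        raise ValueError("cannot take the mean of an empty cohort")
    X = table.numeric_matrix()
    if np.isnan(X).any():
        raise ValueError("EMMV requires complete numeric data")
    return X.mean(axis=0)


def hotelling_from_stats(
    mean: np.ndarray, cov: np.ndarray, n: int, mu0: np.ndarray
) -> HotellingResult:
    """Hotelling T2 from summary statistics (mean, unbiased covariance, n)."""
    mean = np.asarray(mean, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    P = mean.shape[0]
    if n <= P:
        raise ValueError(f"Hotelling test needs n > P (got n={n}, P={P})")
    cov = np.asarray(cov, dtype=float)
    if np.linalg.cond(cov) > MAX_CONDITION:
        raise np.linalg.LinAlgError(
            "sample covariance is numerically singular; inspect the numeric "
            "features for constant or collinear columns"
        )
    diff = mean - mu0
    t2 = float(n * diff @ np.linalg.solve(cov, diff))
    t2 = max(t2, 0.0)  # guard tiny negative round-off
    df1, df2 = P, n - P
    F = (df2 / (P * (n - 1))) * t2
    p = float(stats.f.sf(F, df1, df2))
    return HotellingResult(t2=t2, F=F, df1=df1, df2=df2, p=p, n=n, mu0=mu0)


def hotelling_t2(sample: np.ndarray, mu0: np.ndarray) -> HotellingResult:
    """One-sample Hotelling T2 test of ``sample``'s mean against ``mu0``.

    ``sample`` is an (n, P) array of numeric rows.  For P = 1 the
    statistic is exactly the squared one-sample t statistic and the
    p-value equals the two-sided t-test's.
    """
    X = np.asarray(sample, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
    return hotelling_from_stats(mean, cov, n, mu0)


def legitimacy_gate(
    enhanced: CohortTable, mu0: np.ndarray, alpha: float = 0.05
) -> tuple[HotellingResult, bool]:
    """Test an enhanced table against the original EMMV.

    Returns the test result and ``legitimate = (p > alpha)``.
    """
    if len(enhanced) == 0:
        raise ValueError("cannot gate an empty table")
    result = hotelling_t2(enhanced.numeric_matrix(), mu0)
    return result, bool(result.p > alpha)


def max_legitimate_multiplier(
    strat: StratifiedCohort,
    method: str,
    alpha: float = 0.05,
    k_max: int = 30,
    seed: int = 0,
) -> tuple[int, list[HotellingResult]]:
    """Largest multiplier k <= k_max whose enhancement passes the gate.

    Scans k = 1..k_max, building a fresh enhancement for each k under
    the per-k seed ``seed + k`` (reproducible, independent across k),
    and gates each against the fixed original EMMV.  k = 1 is the
    original dataset itself and always passes with p = 1.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    mu0 = emmv(strat)
    best = 0
    trace: list[HotellingResult] = []
    for k in range(1, k_max + 1):
        enhanced, _ = enhance(strat, method, k, seed=seed + k)
        result, legit = legitimacy_gate(enhanced, mu0, alpha)
        trace.append(result)
        if legit:
            best = k
    if best < 1:
        raise AssertionError("k=1 must always be legitimate (p=1 at the original)")
    return best, trace


def combined_enhance(
    strat: StratifiedCohort,
    k_shuffle: int,
    k_rm: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[CohortTable, list[EnhancementReport], HotellingResult]:
    """Shuffle-enhance, then repeated-measures-enhance the result.

    The shuffled population is restratified (same class keys), a fresh
    repeated-measures model is fitted on it, and the second enlargement
    is gated against the ORIGINAL cohort's EMMV — the null never drifts
    with the enhancements.
    """
    mu0 = emmv(strat)
    shuffled, rep1 = enhance(strat, "shuffle", k_shuffle, seed=seed)
    strat2 = restratify(shuffled)
    combined, rep2 = enhance(strat2, "repeated_measures", k_rm, seed=seed + 1)
    result, legit = legitimacy_gate(combined, mu0, alpha)
    rep2.extra["legitimate"] = legit
    return combined, [rep1, rep2], result
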