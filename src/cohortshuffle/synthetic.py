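"""Synthetic cohort generators.

Two generators live here:

* :func:`generate_cohort` builds a cohort from an explicit
  :class:`SyntheticSpec` — distinct binary class patterns, per-class
  multivariate-normal numerics with a shared covariance, configurable
  cell-wise missingness.  It is the workhorse for property tests.

* :func:`synthetic_hf_cohort` builds a deterministic **synthetic
  surrogate** of a published heart-failure trial cohort whose raw data
  are not redistributable here.  It reproduces that cohort's published
  *structure* exactly — 711 patients; 116 with a missing endpoint; 67
  more with another missing value; 143 complete patients alone in their
  stratum; 385 patients left in 61 classes of 2–30 — while the clinical
  values themselves are simulated.  Three binary flags are genuine
  threshold indicators of their numeric counterparts (age > 75 years,
  heart rate >= 90 bpm, LVEF > 50 %), endpoint flags are a function of
  the clinical condition (the remaining 11 flags), and measurements are
  recorded at clinical precision (integer years, bpm, mmHg, percent;
  0.1 kg).  No attempt is made to match the real trials' marginal
  distributions; the surrogate emulates structure, not clinical content.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortSchema, CohortTable
from .preprocess import filter_missing_endpoints, filter_missing_features

__all__ = [
    "SyntheticSpec",
    "generate_cohort",
    "expected_removals",
    "hf_like_spec",
    "hf_schema",
    "synthetic_hf_cohort",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generic cohort generator."""

    n_binary: int = 13
    n_numeric: int = 6
    n_classes: int = 61
    class_sizes: tuple[int, ...] = ()
    class_mean_range: tuple[float, float] = (-3.0, 3.0)
    covariance_scale: float = 1.0
    endpoint_count: int = 2
    missing_rate_endpoint: float = 0.0
    missing_rate_feature: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes > 2**self.n_binary:
            raise ValueError(
                f"cannot place {self.n_classes} distinct patterns in "
                f"2^{self.n_binary} cells"
            )
        if self.endpoint_count > self.n_binary:
            raise ValueError("more endpoints than binary features")
        for p in (self.missing_rate_endpoint, self.missing_rate_feature):
            if not 0.0 <= p <= 1.0:
                raise ValueError("missing rates must be probabilities")
        if self.class_sizes and len(self.class_sizes) != self.n_classes:
            raise ValueError("class_sizes length must equal n_classes")
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class sizes must be positive")

    @property
    def schema(self) -> CohortSchema:
        endpoints = tuple(f"endpoint_{i+1}" for i in range(self.endpoint_count))
        others = tuple(f"bin_{i+1}" for i in range(self.n_binary - self.endpoint_count))
        return CohortSchema(
            binary_features=endpoints + others,
            numeric_features=tuple(f"num_{j+1}" for j in range(self.n_numeric)),
            endpoint_features=endpoints,
        )


def _distinct_patterns(
    rng: np.random.Generator, count: int, n_bits: int, prevalence: np.ndarray | None = None
) -> np.ndarray:
    """Draw ``count`` distinct bit patterns (rejection sampling)."""
    if prevalence is None:
        prevalence = np.full(n_bits, 0.5)
    seen: set[tuple[int, ...]] = set()
    out = np.empty((count, n_bits), dtype=int)
    attempts = 0
    while len(seen) < count:
        attempts += 1
        if attempts > 1000 * count:
            raise RuntimeError("pattern space too crowded for rejection sampling")
        pat = tuple((rng.random(n_bits) < prevalence).astype(int))
        if pat not in seen:
            out[len(seen)] = pat
            seen.add(pat)
    return out


def generate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Generate a cohort per the spec (deterministic for a given spec)."""
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema
    G, B, P = spec.n_classes, spec.n_binary, spec.n_numeric
    sizes = (
        np.asarray(spec.class_sizes, dtype=int)
        if spec.class_sizes
        else rng.integers(2, 31, size=G)
    )
    patterns = _distinct_patterns(rng, G, B)
    lo, hi = spec.class_mean_range
    class_means = rng.uniform(lo, hi, size=(G, P))
    A = rng.standard_normal((P, P)) / np.sqrt(P)
    cov = A @ A.T + 0.1 * np.eye(P)  # SPD, unit-ish scale
    cov *= spec.covariance_scale
    L = np.linalg.cholesky(cov)
    bin_rows, num_rows = [], []
    for g in range(G):
        m = int(sizes[g])
        bin_rows.append(np.tile(patterns[g], (m, 1)))
        num_rows.append(class_means[g] + rng.standard_normal((m, P)) @ L.T)
    binm = np.vstack(bin_rows).astype(float)
    numm = np.vstack(num_rows)
    # cell-wise missingness (endpoints vs everything else)
    n = binm.shape[0]
    endpoint_cols = schema.endpoint_features
    for j, col in enumerate(schema.binary_features):
        rate = (
            spec.missing_rate_endpoint if col in endpoint_cols else spec.missing_rate_feature
        )
        if rate > 0:
            binm[rng.random(n) < rate, j] = np.nan
    if spec.missing_rate_feature > 0:
        mask = rng.random((n, P)) < spec.missing_rate_feature
        numm[mask] = np.nan
    df = pd.DataFrame(
        np.hstack([binm, numm]), columns=list(schema.feature_columns)
    )
    return CohortTable(schema, df)


def expected_removals(
    spec: SyntheticSpec, trials: int, seed: int
) -> pd.DataFrame:
    """Monte-Carlo summary of filter removal counts under a spec.

    Regenerates the cohort ``trials`` times (seeds derived from ``seed``)
    and tabulates how many rows each sequential filter removes; used to
    compare against binomial expectations.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rows = []
    for t in range(trials):
        cohort = generate_cohort(replace(spec, seed=seed + t))
        t1, r_end = filter_missing_endpoints(cohort)
        _, r_feat = filter_missing_features(t1)
        rows.append({"missing_endpoint": r_end, "missing_feature": r_feat})
    df = pd.DataFrame(rows)
    return df.agg(["mean", "std", "min", "max"])


def hf_like_spec(seed: int = 0) -> SyntheticSpec:
    """A preset spec mirroring the shape this method was designed for:
    13 binary features (2 endpoints), 6 numerics, 61 classes of 2-30
    patients totalling ~385, complete data."""
    rng = np.random.default_rng(seed)
    sizes = _skewed_sizes(rng, n_classes=61, total=385, low=2, high=30)
    return SyntheticSpec(
        n_binary=13,
        n_numeric=6,
        n_classes=61,
        class_sizes=tuple(int(s) for s in sizes),
        class_mean_range=(-3.0, 3.0),
        covariance_scale=1.0,
        endpoint_count=2,
        seed=seed,
    )


def _skewed_sizes(
    rng: np.random.Generator, n_classes: int, total: int, low: int, high: int
) -> np.ndarray:
    """Class sizes with many small and few large strata, summing to ``total``."""
    raw = rng.geometric(0.22, size=n_classes) + (low - 1)
    sizes = np.clip(raw, low, high).astype(int)
    # repair the sum while respecting the bounds
    while sizes.sum() != total:
        diff = total - sizes.sum()
        if diff > 0:
            idx = rng.integers(n_classes)
            if sizes[idx] < high:
                sizes[idx] += 1
        else:
            idx = rng.integers(n_classes)
            if sizes[idx] > low:
                sizes[idx] -= 1
    return sizes


# ---------------------------------------------------------------------------
# Synthetic surrogate of the heart-failure trial cohort
# ---------------------------------------------------------------------------

_HF_BINARY = (
    "peripheral_edema",
    "composite_endpoint",
    "age_gt_75",
    "arb_intake",
    "beta_blocker_intake",
    "lvef_gt_50",
    "ntprobnp_gt_1000",
    "diabetes",
    "ckd_gfr_lt_50",
    "hr_ge_90",
    "anemia",
    "hospitalization_endpoint",
    "gt2_hospitalizations",
)
_HF_NUMERIC = (
    "age",
    "heart_rate",
    "body_weight",
    "systolic_bp",
    "diastolic_bp",
    "lvef",
)
_HF_ENDPOINTS = ("composite_endpoint", "hospitalization_endpoint")

#: Population mean and SD of each measurement (HF-plausible, chosen once).
_HF_MARGINALS = {
    "age": (72.0, 10.0),
    "heart_rate": (74.0, 13.0),
    "body_weight": (80.0, 16.0),
    "systolic_bp": (126.0, 18.0),
    "diastolic_bp": (74.0, 11.0),
    "lvef": (45.0, 13.0),
}
#: Recording precision of each measurement (decimal places).
_HF_DECIMALS = {
    "age": 0,
    "heart_rate": 0,
    "body_weight": 1,
    "systolic_bp": 0,
    "diastolic_bp": 0,
    "lvef": 0,
}
#: Binary flags that are threshold indicators of a measurement:
#: flag -> (measurement, threshold, margin).  A flag of 1 forces the
#: value above threshold + margin; 0 forces it below (rounding-safe).
_HF_THRESHOLDS = {
    "age_gt_75": ("age", 75.0, 0.51),
    "hr_ge_90": ("heart_rate", 89.5, 0.01),
    "lvef_gt_50": ("lvef", 50.0, 0.51),
}
#: Prevalence of the 11 condition flags (endpoints are derived, not drawn).
_HF_PREVALENCE = {
    "peripheral_edema": 0.35,
    "age_gt_75": 0.45,
    "arb_intake": 0.30,
    "beta_blocker_intake": 0.75,
    "lvef_gt_50": 0.45,
    "ntprobnp_gt_1000": 0.50,
    "diabetes": 0.35,
    "ckd_gfr_lt_50": 0.30,
    "hr_ge_90": 0.15,
    "anemia": 0.30,
    "gt2_hospitalizations": 0.15,
}
#: Published structural counts of the cohort the surrogate emulates.
HF_STRUCTURE = {
    "n_total": 711,
    "n_missing_endpoint": 116,
    "n_missing_feature": 67,
    "n_monoexample": 143,
    "n_final": 385,
    "n_classes": 61,
}


def hf_schema() -> CohortSchema:
    """Schema of the (synthetic) heart-failure cohort."""
    return CohortSchema(
        binary_features=_HF_BINARY,
        numeric_features=_HF_NUMERIC,
        endpoint_features=_HF_ENDPOINTS,
    )


def _hf_condition_patterns(rng: np.random.Generator, count: int) -> np.ndarray:
    """Distinct patterns over the 11 non-endpoint condition flags."""
    cond_flags = [b for b in _HF_BINARY if b not in _HF_ENDPOINTS]
    prev = np.array([_HF_PREVALENCE[b] for b in cond_flags])
    return _distinct_patterns(rng, count, len(cond_flags), prev)


def _hf_endpoints_for(cond: np.ndarray) -> np.ndarray:
    """Endpoint flags as deterministic clinical rules over condition flags.

    Rehospitalization is driven by congestion with preserved ejection
    fraction or by a history of frequent admissions; death by severe
    decompensation (high natriuretic peptide with resting tachycardia).
    The composite endpoint is hospitalization or death.  Because the
    rules are functions of the condition pattern, every stratum has a
    well-defined outcome pair.
    """
    cond_flags = [b for b in _HF_BINARY if b not in _HF_ENDPOINTS]
    col = {name: cond_flags.index(name) for name in cond_flags}
    edema = cond[:, col["peripheral_edema"]]
    lvef_hi = cond[:, col["lvef_gt_50"]]
    freq = cond[:, col["gt2_hospitalizations"]]
    bnp = cond[:, col["ntprobnp_gt_1000"]]
    tachy = cond[:, col["hr_ge_90"]]
    hosp = np.maximum(edema * lvef_hi, freq)
    death = bnp * tachy
    comp = np.maximum(hosp, death)
    return np.column_stack([comp, hosp])  # (composite, hospitalization)


def _hf_full_pattern(cond: np.ndarray, endpoints: np.ndarray) -> np.ndarray:
    """Assemble 13-bit rows in schema column order from condition bits
    (11, in non-endpoint schema order) and endpoint bits (2)."""
    count = cond.shape[0]
    out = np.empty((count, len(_HF_BINARY)), dtype=int)
    cond_iter_cols = [b for b in _HF_BINARY if b not in _HF_ENDPOINTS]
    for j, name in enumerate(_HF_BINARY):
        if name == "composite_endpoint":
            out[:, j] = endpoints[:, 0]
        elif name == "hospitalization_endpoint":
            out[:, j] = endpoints[:, 1]
        else:
            out[:, j] = cond[:, cond_iter_cols.index(name)]
    return out


def _hf_numeric_rows(
    rng: np.random.Generator, patterns: np.ndarray, sizes: np.ndarray
) -> np.ndarray:
    """Per-class numeric draws at clinical precision.

    Each class gets a mean offset ~ N(0, sd/sqrt(2)) per measurement;
    within-class values are N(class mean, sd/sqrt(2)), truncated to the
    side demanded by any linked threshold flag, then rounded to the
    recording precision.  Between- and within-class variance are split
    evenly, so strata overlap substantially — adjacent clinical
    conditions are not cleanly separable from the measurements alone.
    """
    flag_idx = {name: _HF_BINARY.index(name) for name in _HF_THRESHOLDS}
    n = int(sizes.sum())
    out = np.empty((n, len(_HF_NUMERIC)))
    start = 0
    for g in range(patterns.shape[0]):
        m = int(sizes[g])
        for j, feat in enumerate(_HF_NUMERIC):
            mu, sd = _HF_MARGINALS[feat]
            sd_b = sd_w = sd / np.sqrt(2.0)
            loc = mu + rng.normal(0.0, sd_b)
            lb, ub = -np.inf, np.inf
            for flag, (meas, thr, margin) in _HF_THRESHOLDS.items():
                if meas != feat:
                    continue
                if patterns[g, flag_idx[flag]] == 1:
                    lb = thr + margin
                else:
                    ub = thr - margin
            if np.isinf(lb) and np.isinf(ub):
                vals = rng.normal(loc, sd_w, size=m)
            else:
                a, b = (lb - loc) / sd_w, (ub - loc) / sd_w
                vals = stats.truncnorm.rvs(a, b, loc=loc, scale=sd_w, size=m, random_state=rng)
            out[start : start + m, j] = np.round(vals, _HF_DECIMALS[feat])
        start += m
    return out


def synthetic_hf_cohort(seed: int = 0) -> CohortTable:
    """Deterministic synthetic surrogate of the heart-failure trial cohort.

    The returned table has 711 rows whose preprocessing bookkeeping
    matches the published cohort exactly: the endpoint filter removes
    116 rows, the any-feature filter another 67, monoexample-class
    removal another 143, leaving 385 complete patients in 61 classes of
    2-30.  All clinical values are simulated (see the module docstring);
    only the structure is faithful.
    """
    rng = np.random.default_rng(seed)
    s = HF_STRUCTURE
    # distinct condition patterns: 61 retained classes + 143 singletons,
    # all distinct as full 13-bit patterns because the 11-bit condition
    # projections are distinct and endpoints are per-pattern constants.
    n_patterns = s["n_classes"] + s["n_monoexample"]
    cond = _hf_condition_patterns(rng, n_patterns)
    endpoints = _hf_endpoints_for(cond)
    full = _hf_full_pattern(cond, endpoints)
    class_patterns, singleton_patterns = full[: s["n_classes"]], full[s["n_classes"] :]
    sizes = _skewed_sizes(rng, s["n_classes"], s["n_final"], low=2, high=30)
    # -- complete block: 385 stratified + 143 singleton rows
    class_bin = np.repeat(class_patterns, sizes, axis=0)
    class_num = _hf_numeric_rows(rng, class_patterns, sizes)
    single_num = _hf_numeric_rows(rng, singleton_patterns, np.ones(s["n_monoexample"], int))
    # -- incomplete block: rows later removed by the two filters
    n_bad_end, n_bad_feat = s["n_missing_endpoint"], s["n_missing_feature"]
    bad_cond = (
        rng.random((n_bad_end + n_bad_feat, cond.shape[1]))
        < np.array([_HF_PREVALENCE[b] for b in _HF_BINARY if b not in _HF_ENDPOINTS])
    ).astype(int)
    bad_end = _hf_endpoints_for(bad_cond)
    bad_full = _hf_full_pattern(bad_cond, bad_end).astype(float)
    bad_num = _hf_numeric_rows(
        rng, _hf_full_pattern(bad_cond, bad_end), np.ones(n_bad_end + n_bad_feat, int)
    )
    ep_idx = [_HF_BINARY.index(e) for e in _HF_ENDPOINTS]
    other_bin_idx = [j for j in range(len(_HF_BINARY)) if j not in ep_idx]
    for i in range(n_bad_end):  # at least one endpoint missing
        drop = rng.random(2) < 0.7
        if not drop.any():
            drop[rng.integers(2)] = True
        for d, j in zip(drop, ep_idx):
            if d:
                bad_full[i, j] = np.nan
        extra = rng.random(len(other_bin_idx)) < 0.03
        bad_full[i, np.array(other_bin_idx)[extra]] = np.nan
        bad_num[i, rng.random(len(_HF_NUMERIC)) < 0.03] = np.nan
    for i in range(n_bad_end, n_bad_end + n_bad_feat):  # endpoints intact
        cells = np.concatenate(
            [rng.random(len(other_bin_idx)) < 0.06, rng.random(len(_HF_NUMERIC)) < 0.06]
        )
        if not cells.any():
            cells[rng.integers(len(cells))] = True
        bin_mask, num_mask = cells[: len(other_bin_idx)], cells[len(other_bin_idx) :]
        bad_full[i, np.array(other_bin_idx)[bin_mask]] = np.nan
        bad_num[i, num_mask] = np.nan
    # -- assemble and shuffle the row order
    binm = np.vstack(
        [class_bin.astype(float), singleton_patterns.astype(float), bad_full]
    )
    numm = np.vstack([class_num, single_num, bad_num])
    order = rng.permutation(binm.shape[0])
    schema = hf_schema()
    df = pd.DataFrame(
        np.hstack([binm[order], numm[order]]), columns=list(schema.feature_columns)
    )
    assert len(df) == s["n_total"]
    return CohortTable(schema, df)
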