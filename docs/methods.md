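# Methods

## The enhancement model

A cohort is a table of `n` patients with `B` binary features (two of
which are outcome endpoints) and `P` continuous features. The ordered
`B`-tuple of a patient's binary values is their *class key*; a class is
the set of patients sharing a key. Grouping equal keys is implemented
as a stable lexicographic sort of the key tuples in declared column
order — the same partition a balanced search tree over the bit strings
would produce, with class indices assigned in sorted-key order.
Classes are the unit of synthesis: all generators condition on the
class and never alter binary values, so a synthetic patient's flags are
always an observed clinical condition.

**Sequential exclusions.** (1) any endpoint missing; (2) any other
value missing; (3) classes of size one (a lone patient admits no
intraclass permutation). Filters only delete rows; surviving values
are never modified, and removal counts reconcile exactly
(`n_in = n_out + Σ removed`). No imputation is performed — the method
deliberately removes rather than fills.

**Shuffle generator.** For class `g` and numeric feature `j`
independently, the column segment of `g` is replaced by a uniformly
random permutation of itself. Consequences used as test invariants:
per-class per-feature value multisets, per-class means and the grand
mean are conserved exactly (pre-deduplication); a class whose feature
takes a single value is a fixed point. The number of distinct rows
class `g` can realize is `Π_j d_gj` (`d_gj` = distinct values of
feature `j` in `g`), so `Σ_g Π_j d_gj` bounds the achievable unique
cardinality (`max_unique_bound`); small or discrete-valued classes
saturate first.

**Repeated-measures comparator.** A multivariate one-way model with
the class as sole categorical predictor: exact per-class sample means
`μ_g` and pooled residual covariance `Σ` with denominator `n − G`.
Sampling is class-conditional, `x ~ N(μ_g, Σ)`, one draw per original
row. A singular `Σ` is legal at fit time; before factorization a ridge
`ε·tr(Σ)/P·I` with `ε = 1e-8` is added only if the Cholesky fails, and
a zero `Σ` degenerates to drawing the class means themselves. Whether
generation should condition on each original row or only on its class
is underdetermined; class-conditional generation is the normative
choice here, matching the fitted model's exchangeability within class.

**Enlargement loop (`k×` semantics).** The target is `k·n₀` rows with
the originals always included. Whole-cohort generator passes
accumulate; after each pass, candidates equal (on all `B + P` values,
exact equality) to any existing row or an earlier candidate are
deleted; excess rows from the final pass are dropped in generation
order. `max_rounds` (default `10k`) bounds the loop; exhausting it
before the target marks the run *saturated*. One seeded generator per
call is consumed in class-index then feature-index order, so shuffle
outputs are bit-for-bit reproducible.

**Legitimacy gate.** One-sample Hotelling test of the enhanced table's
numeric mean against the *original* cohort's mean vector (EMMV), which
is never re-estimated. The covariance is the enhanced sample's — the
standard one-sample statistic, requiring no extra assumption. The
enhanced table includes the originals when tested. `α = 0.05`;
legitimate iff `p > α`. The multiplier scan rebuilds a fresh
enhancement per `k` under seed `seed + k` and returns the largest
legitimate `k`; no multiplicity correction is applied across the scan,
matching the procedure this package operationalizes. The combined
route shuffles to `k_s×`, restratifies (class keys are preserved by
construction), refits the Gaussian model on the enlarged population,
enlarges `k_rm×`, and gates against the original EMMV.

Numerical notes: `T²` is computed via a linear solve (no explicit
inverse); a sample covariance with condition number above `1e12` raises
instead of returning an unstable number; `T² = 0` yields `p = 1`
exactly; `n ≤ P` or `n ≤ G` raise degrees-of-freedom errors.

## The evaluation harness

10-fold cross-validation throughout; every row is predicted exactly
once. Classification predicts the class label from all `B + P`
features with folds stratified by class where possible — classes
smaller than the fold count can be absent from a training partition,
and their held-out rows then score as errors. Regression predicts one
endpoint (kept numeric 0/1) from the `(B − 2) + P` non-endpoint
features.

Learner presets are the documented defaults of the interactive-tool
presets they are named after: fine tree = CART/Gini with at most 100
splits (classification) or minimum leaf size 4 (regression); fine
KNN = 1-NN, Euclidean; weighted KNN = 10-NN with squared-inverse
distance weights (exact matches take all weight); linear SVM = linear
kernel, `C = 1`, one-vs-one; linear = OLS; linear SVR = `C = 1`,
`ε = 0.1`. For the distance- and margin-based learners **all**
predictors, dummies included, are standardized with train-fold
statistics — the behaviour of the presets being mirrored; scaling only
the numerics was evaluated and leaves the 0/1 dummies too weak against
within-class numeric spread, degrading the class signal the
stratification is built on. Trees and OLS are scale-invariant and use
raw features.

## The synthetic generators

`generate_cohort` draws `G` distinct binary patterns (rejection
sampling), per-class mean vectors uniform in a configurable range, a
shared random SPD covariance, and independent cell-wise missingness at
separate endpoint/feature rates. It exists so every pipeline stage is
testable without clinical data.

`synthetic_hf_cohort` is a **synthetic surrogate** of a heart-failure
trial cohort whose raw data cannot be shipped. Its construction fixes
the published structure exactly, for every seed: 711 patients; 116
with ≥1 endpoint missing; 67 more with another value missing; 143
complete patients alone in their stratum; 385 left in 61 classes of
2–30 patients (class sizes drawn from a skewed distribution and
repaired to the exact total). Chosen-once realism defaults:

- measurements with HF-plausible marginals (age 72 ± 10 y, heart rate
  74 ± 13 bpm, weight 80 ± 16 kg, systolic/diastolic pressure
  126 ± 18 / 74 ± 11 mmHg, LVEF 45 ± 13 %), recorded at clinical
  precision (integers; 0.1 kg for weight), with variance split evenly
  between and within classes so that strata overlap substantially;
- three flags are genuine threshold indicators of their measurement
  (age > 75, HR ≥ 90, LVEF > 50), enforced by truncated-normal
  sampling with a rounding-safe margin;
- condition-flag prevalences typical of an HF population (e.g.
  β-blocker 0.75, diabetes 0.35, tachycardia 0.15);
- endpoints are deterministic clinical rules over the condition flags
  — rehospitalization = (peripheral edema ∧ LVEF > 50) ∨ >2 prior
  hospitalizations; death = NT-proBNP > 1000 ∧ HR ≥ 90; composite =
  either — so each stratum has a well-defined outcome pair, the
  pattern of outcomes is learnable from the condition flags, and the
  retained strata have distinct condition projections.

What the surrogate does **not** emulate: the real trials' clinical
marginals and correlations, patient-level outcome noise (two real
patients with identical conditions can differ in outcome; surrogate
strata cannot), repeated or near-duplicate patients, and the real
cohort's particular numeric geometry. Tests passing on the surrogate
therefore demonstrate the pipeline's mechanics, invariants and
structural bookkeeping — not that any particular cross-validated score
on real data is reproduced. Concretely, 1-NN accuracy on the original
surrogate (~99.5 %) exceeds what heavily overlapping real strata yield,
because surrogate classes are cleanly separated once dummies are
standardized; the enhanced-data endpoints (100 % accuracy, zero
fine-tree RMSE) are robust to this difference and do transfer.

## Problem sizes and runtime

Default test and reproduction sizes: the 711-row surrogate; 20×
enhancement (7,700 rows, ~20–25 shuffle passes); combined 20×+2×
(15,400 rows); property suites at 200 random cohorts (shuffle
conservation), 1,000 random samples (Hotelling vs. brute force), and a
50,000-row draw (parameter recovery). The full suite runs in about a
minute on one CPU; the reproduction script in a few seconds.

## Known limitations

- Exact-equality deduplication is appropriate for recombined observed
  values and finite-precision records; continuous repeated-measures
  draws essentially never collide, so the replica checkpoint acts
  almost entirely on the shuffle path.
- The gate tests only the numeric mean vector; higher moments and the
  binary margins (conserved by construction for the shuffle, not for
  the comparator) are not tested.
- The multiplier scan's achievable `k` depends on class-size structure
  and value discreteness via the unique-row bound; cohorts of
  small, coarsely recorded classes saturate early.
- Cross-validation on oversampled data is guarded by intraclass-only
  synthesis and replica deletion, but synthetic rows remain
  statistically dependent on the originals they recombine; reported
  post-enhancement scores characterize the enhanced table, not an
  independent cohort.
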