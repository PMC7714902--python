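"""Shuffle and repeated-measures generators, deduplication, enlargement."""

import numpy as np
import pytest

from cohortshuffle import (
    CohortTable,
    assign_classes,
    deduplicate,
    enhance,
    fit_repeated_measures,
    intraclass_shuffle_once,
    max_unique_bound,
    sample_repeated_measures,
)
from .conftest import make_table, random_small_cohort


def per_class_feature_multisets(strat, table):
    """Sorted value arrays per (class, numeric feature)."""
    X = table.numeric_matrix()
    return [
        np.sort(X[sl, j])
        for sl in strat.class_slices()
        for j in range(X.shape[1])
    ]


class TestShuffle:
    def test_conserves_per_class_value_multisets(self, hf_strat):
        shuffled = intraclass_shuffle_once(hf_strat, seed=3)
        before = per_class_feature_multisets(hf_strat, hf_strat.table)
        after = per_class_feature_multisets(hf_strat, shuffled)
        for a, b in zip(before, after):
            np.testing.assert_array_equal(a, b)

    def test_binary_block_untouched_and_rows_synthetic(self, hf_strat):
        shuffled = intraclass_shuffle_once(hf_strat, seed=3)
        assert shuffled.binary_matrix().equals(hf_strat.table.binary_matrix())
        assert set(shuffled.origin) == {"synthetic"}

    def test_class_means_and_grand_mean_invariant(self, hf_strat):
        shuffled = intraclass_shuffle_once(hf_strat, seed=5)
        for sl in hf_strat.class_slices():
            np.testing.assert_allclose(
                shuffled.numeric_matrix()[sl].mean(axis=0),
                hf_strat.table.numeric_matrix()[sl].mean(axis=0),
                rtol=0, atol=1e-12,
            )

    def test_constant_class_is_fixed_point(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [{"ep": 0, "b1": 1, "b2": 0, "x": 2.0, "y": 7.0}] * 4,
        )
        strat = assign_classes(table)
        shuffled = intraclass_shuffle_once(strat, seed=11)
        np.testing.assert_array_equal(
            shuffled.numeric_matrix(), strat.table.numeric_matrix()
        )

    def test_singleton_class_rejected(self, tiny_schema):
        table = make_table(
            tiny_schema, [{"ep": 0, "b1": 1, "b2": 0, "x": 2.0, "y": 7.0}]
        )
        with pytest.raises(ValueError):
            intraclass_shuffle_once(assign_classes(table), seed=0)

    def test_two_patient_swaps_are_uniform(self, tiny_schema):
        """Each feature swaps independently with probability 1/2, so the
        four (swap x, swap y) outcomes each occur ~25% of the time."""
        table = make_table(
            tiny_schema,
            [
                {"ep": 0, "b1": 0, "b2": 0, "x": 1.0, "y": 10.0},
                {"ep": 0, "b1": 0, "b2": 0, "x": 2.0, "y": 20.0},
            ],
        )
        strat = assign_classes(table)
        counts = {(False, False): 0, (False, True): 0, (True, False): 0, (True, True): 0}
        for seed in range(10_000):
            out = intraclass_shuffle_once(strat, seed=seed).numeric_matrix()
            counts[(out[0, 0] == 2.0, out[0, 1] == 20.0)] += 1
        for outcome, c in counts.items():
            assert abs(c / 10_000 - 0.25) < 0.02, (outcome, c)

    def test_reproducible_bit_for_bit(self, hf_strat):
        a = intraclass_shuffle_once(hf_strat, seed=42).numeric_matrix()
        b = intraclass_shuffle_once(hf_strat, seed=42).numeric_matrix()
        np.testing.assert_array_equal(a, b)


class TestRepeatedMeasures:
    def test_hand_computed_single_class_fit(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [
                {"ep": 0, "b1": 0, "b2": 0, "x": 0.0, "y": 0.0},
                {"ep": 0, "b1": 0, "b2": 0, "x": 2.0, "y": 2.0},
            ],
        )
        model = fit_repeated_measures(assign_classes(table))
        np.testing.assert_array_equal(model.class_means, [[1.0, 1.0]])
        np.testing.assert_array_equal(model.pooled_cov, [[2.0, 2.0], [2.0, 2.0]])

    def test_identical_rows_give_zero_covariance(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [{"ep": 0, "b1": 0, "b2": 0, "x": 1.0, "y": 2.0}] * 2
            + [{"ep": 1, "b1": 1, "b2": 0, "x": 5.0, "y": 6.0}] * 2,
        )
        model = fit_repeated_measures(assign_classes(table))
        np.testing.assert_array_equal(model.pooled_cov, np.zeros((2, 2)))

    def test_insufficient_dof_rejected(self, two_class_table):
        strat = assign_classes(two_class_table.take([0, 1]))
        # n == G is still too few once we also test n == G exactly
        half = assign_classes(
            CohortTable(two_class_table.schema, two_class_table.df.iloc[:2])
        )
        assert half.n_classes == 1 and half.n_rows == 2  # fine: n > G
        single_rows = two_class_table.take([0, 2])
        with pytest.raises(ValueError, match="degrees of freedom|n="):
            fit_repeated_measures(assign_classes(single_rows))

    def test_zero_covariance_sampling_returns_class_means(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [{"ep": 0, "b1": 0, "b2": 0, "x": 1.0, "y": 2.0}] * 3,
        )
        strat = assign_classes(table)
        model = fit_repeated_measures(strat)
        out = sample_repeated_measures(model, strat, seed=0)
        np.testing.assert_array_equal(out.numeric_matrix(), strat.table.numeric_matrix())
        assert out.binary_matrix().equals(strat.table.binary_matrix())

    def test_parameter_recovery_at_large_n(self, tiny_schema):
        """Sampling 50,000 rows from a 1-class model recovers the class
        mean and pooled covariance within 3 standard errors."""
        rng = np.random.default_rng(8)
        base = make_table(
            tiny_schema,
            [
                {"ep": 0, "b1": 0, "b2": 0, "x": float(x), "y": float(y)}
                for x, y in rng.normal([5.0, -2.0], [2.0, 1.0], size=(40, 2))
            ],
        )
        strat = assign_classes(base)
        model = fit_repeated_measures(strat)
        big = CohortTable(
            base.schema,
            CohortTable.concat([base] * 1250).df,  # 50,000 rows, same class
        )
        big_strat = assign_classes(big)
        draws = sample_repeated_measures(model, big_strat, seed=9).numeric_matrix()
        n = draws.shape[0]
        se_mean = np.sqrt(np.diag(model.pooled_cov) / n)
        np.testing.assert_allclose(
            draws.mean(axis=0), model.class_means[0], atol=3 * se_mean.max()
        )
        emp_cov = np.cov(draws, rowvar=False)
        # SE of a covariance entry is O(cov_scale / sqrt(n))
        scale = np.abs(model.pooled_cov).max()
        assert np.abs(emp_cov - model.pooled_cov).max() < 3 * 2 * scale / np.sqrt(n)

    def test_model_must_match_stratification(self, hf_strat, two_class_table):
        model = fit_repeated_measures(hf_strat)
        with pytest.raises(ValueError):
            sample_repeated_measures(model, assign_classes(two_class_table), seed=0)


class TestDeduplicate:
    def test_candidates_identical_to_base_all_deleted(self, two_class_table):
        kept, deleted = deduplicate(two_class_table, two_class_table)
        assert len(kept) == 0 and deleted == len(two_class_table)

    def test_all_distinct_candidates_unchanged(self, two_class_table, tiny_schema):
        fresh = make_table(
            tiny_schema,
            [{"ep": 0, "b1": 0, "b2": 1, "x": 9.0, "y": 9.0}],
        )
        kept, deleted = deduplicate(two_class_table, fresh)
        assert deleted == 0 and kept == fresh

    def test_internal_candidate_replicas_deleted(self, tiny_schema):
        base = make_table(tiny_schema, [{"ep": 0, "b1": 0, "b2": 1, "x": 1.0, "y": 1.0}])
        twice = make_table(
            tiny_schema,
            [{"ep": 0, "b1": 0, "b2": 1, "x": 2.0, "y": 2.0}] * 2,
        )
        kept, deleted = deduplicate(base, twice)
        assert len(kept) == 1 and deleted == 1

    def test_idempotent(self, hf_strat):
        shuffled = intraclass_shuffle_once(hf_strat, seed=1)
        once, d1 = deduplicate(hf_strat.table, shuffled)
        again, d2 = deduplicate(hf_strat.table, once)
        assert d2 == 0 and again == once


class TestEnhance:
    def test_k1_is_identity(self, hf_strat):
        out, report = enhance(hf_strat, "shuffle", k=1, seed=0)
        assert out == hf_strat.table
        assert report.duplicates_deleted == 0 and not report.saturated

    def test_invalid_k_rejected(self, hf_strat):
        with pytest.raises(ValueError):
            enhance(hf_strat, "shuffle", k=0, seed=0)

    @pytest.mark.parametrize("method", ["shuffle", "repeated_measures"])
    def test_output_has_no_duplicate_rows(self, hf_strat, method):
        out, _ = enhance(hf_strat, method, k=3, seed=2)
        keys = out.row_keys()
        assert len(keys) == len(set(keys))

    def test_originals_always_included(self, hf_strat):
        out, _ = enhance(hf_strat, "shuffle", k=2, seed=2)
        out_keys = set(out.row_keys())
        assert set(hf_strat.table.row_keys()) <= out_keys

    def test_saturation_on_constant_classes(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [{"ep": 0, "b1": 0, "b2": 0, "x": 1.0, "y": 2.0}] * 3
            + [{"ep": 1, "b1": 1, "b2": 0, "x": 3.0, "y": 4.0}] * 2,
        )
        strat = assign_classes(table)
        out, report = enhance(strat, "shuffle", k=2, seed=0)
        assert report.saturated
        assert out == strat.table  # shuffle can only replicate here

    def test_shuffle_enhancement_reproducible(self, hf_strat):
        a, _ = enhance(hf_strat, "shuffle", k=2, seed=7)
        b, _ = enhance(hf_strat, "shuffle", k=2, seed=7)
        np.testing.assert_array_equal(a.numeric_matrix(), b.numeric_matrix())


class TestUniqueBound:
    def test_two_by_two_distinct_contributes_four(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [
                {"ep": 0, "b1": 0, "b2": 0, "x": 1.0, "y": 10.0},
                {"ep": 0, "b1": 0, "b2": 0, "x": 2.0, "y": 20.0},
            ],
        )
        assert max_unique_bound(assign_classes(table)) == 4

    def test_constant_class_contributes_one(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [{"ep": 0, "b1": 0, "b2": 0, "x": 1.0, "y": 10.0}] * 5,
        )
        assert max_unique_bound(assign_classes(table)) == 1

    def test_bound_at_least_current_cardinality(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            strat = assign_classes(random_small_cohort(rng))
            assert max_unique_bound(strat) >= strat.n_rows
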