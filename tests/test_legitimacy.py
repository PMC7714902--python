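"""Hotelling T2 statistic, the legitimacy gate, and the multiplier scan."""

import numpy as np
import pytest
from scipy import stats

from cohortshuffle import (
    assign_classes,
    combined_enhance,
    emmv,
    enhance,
    hotelling_from_stats,
    hotelling_t2,
    intraclass_shuffle_once,
    legitimacy_gate,
    max_legitimate_multiplier,
)
from .conftest import make_table


def brute_force_t2(X, mu0):
    """Independent oracle: explicit inverse of the sample covariance."""
    X = np.asarray(X, float)
    n = X.shape[0]
    d = X.mean(axis=0) - mu0
    S = np.cov(X, rowvar=False, ddof=1)
    return float(n * d @ np.linalg.inv(np.atleast_2d(S)) @ d)


class TestStatistic:
    def test_mean_equal_to_null_gives_zero_and_p_one(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [-1.0, 0.0], [5.0, 2.0]])
        res = hotelling_t2(X, X.mean(axis=0))
        assert res.t2 == pytest.approx(0.0, abs=1e-20)
        assert res.p == 1.0

    def test_univariate_equals_squared_t(self):
        """{1..5} against mu0=2: t = (3-2)/sqrt(2.5/5), so t2 = F = 2."""
        res = hotelling_t2(np.arange(1.0, 6.0), np.array([2.0]))
        assert res.t2 == pytest.approx(2.0, rel=1e-12)
        assert res.F == pytest.approx(2.0, rel=1e-12)
        assert (res.df1, res.df2) == (1, 4)

    def test_univariate_p_matches_t_test(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=n)
            mu0 = rng.uniform(-2, 2)
            res = hotelling_t2(x, np.array([mu0]))
            t, p = stats.ttest_1samp(x, mu0)
            assert res.t2 == pytest.approx(t**2, rel=1e-12)
            assert res.p == pytest.approx(p, abs=1e-12)

    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            X = rng.normal(size=(n, 3)) @ rng.normal(size=(3, 3)) + rng.normal(size=3)
            mu0 = rng.normal(size=3)
            res = hotelling_t2(X, mu0)
            assert res.t2 == pytest.approx(brute_force_t2(X, mu0), rel=1e-10)

    def test_f_transform_identity(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 4))
        res = hotelling_t2(X, np.zeros(4))
        n, P = 25, 4
        assert res.F == pytest.approx((n - P) / (P * (n - 1)) * res.t2, rel=1e-13)

    def test_scaling_linear_in_n(self):
        """At fixed mean and covariance, T2 is proportional to n."""
        rng = np.random.default_rng(7)
        mean = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + np.eye(3)
        mu0 = mean + 0.3
        base = hotelling_from_stats(mean, cov, 50, mu0)
        for c in (2, 5, 20):
            scaled = hotelling_from_stats(mean, cov, 50 * c, mu0)
            assert scaled.t2 == pytest.approx(c * base.t2, rel=1e-12)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            hotelling_t2(np.zeros((3, 3)) + np.eye(3), np.zeros(3))

    def test_singular_covariance_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError):
            hotelling_t2(X, np.zeros(2))


class TestEMMV:
    def test_hand_example(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [
                {"ep": 0, "b1": 0, "b2": 0, "x": 0.0, "y": 0.0},
                {"ep": 0, "b1": 0, "b2": 0, "x": 2.0, "y": 2.0},
            ],
        )
        np.testing.assert_array_equal(emmv(table), [1.0, 1.0])

    def test_single_row(self, tiny_schema):
        table = make_table(tiny_schema, [{"ep": 0, "b1": 0, "b2": 0, "x": 7.0, "y": -1.0}])
        np.testing.assert_array_equal(emmv(table), [7.0, -1.0])

    def test_invariant_under_shuffle_pass(self, hf_strat):
        shuffled = intraclass_shuffle_once(hf_strat, seed=13)
        np.testing.assert_allclose(emmv(shuffled), emmv(hf_strat), rtol=0, atol=1e-12)


class TestGate:
    def test_original_passes_with_p_one(self, hf_strat):
        res, legit = legitimacy_gate(hf_strat.table, emmv(hf_strat))
        assert legit and res.p == pytest.approx(1.0)

    def test_large_shift_fails(self, tiny_schema):
        rng = np.random.default_rng(3)
        rows = [
            {"ep": 0, "b1": 0, "b2": 0, "x": float(x), "y": float(y)}
            for x, y in rng.normal(0.0, 1.0, size=(1000, 2))
        ]
        table = make_table(tiny_schema, rows)
        mu0 = emmv(table) + 10.0  # ten pooled SDs away
        res, legit = legitimacy_gate(table, mu0)
        assert not legit and res.p < 1e-10


class TestScan:
    def test_kmax_one_returns_one(self, hf_strat):
        best, trace = max_legitimate_multiplier(hf_strat, "shuffle", k_max=1, seed=0)
        assert best == 1
        assert len(trace) == 1 and trace[0].p == pytest.approx(1.0)

    def test_k1_trace_entry_always_legitimate(self, hf_strat):
        best, trace = max_legitimate_multiplier(hf_strat, "shuffle", k_max=3, seed=1)
        assert 1 <= best <= 3
        assert trace[0].p > 0.05

    def test_constant_cohort_saturates_legitimately(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [{"ep": 0, "b1": 0, "b2": 0, "x": 1.0, "y": 2.0}] * 2
            + [{"ep": 1, "b1": 1, "b2": 0, "x": 3.0, "y": 1.0}] * 2
            + [{"ep": 1, "b1": 0, "b2": 1, "x": 2.0, "y": 5.0}] * 2,
        )
        strat = assign_classes(table)
        out, report = enhance(strat, "shuffle", k=2, seed=0)
        assert report.saturated and len(out) == strat.n_rows
        res, legit = legitimacy_gate(out, emmv(strat))
        assert legit and res.p == pytest.approx(1.0)


class TestCombined:
    def test_identity_multipliers_return_original(self, hf_strat):
        out, reports, res = combined_enhance(hf_strat, 1, 1, seed=0)
        assert len(out) == hf_strat.n_rows
        assert res.p == pytest.approx(1.0)

    def test_cardinality_bounded_by_product(self, hf_strat):
        out, reports, res = combined_enhance(hf_strat, 2, 2, seed=0)
        assert hf_strat.n_rows <= len(out) <= 4 * hf_strat.n_rows
        assert len(reports) == 2
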