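"""Exact, permutation and IRLS analyses against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from finchcall import (
    fit_poisson_glm_irls,
    habituation_trend,
    holm_adjust,
    pairwise_condition_tests,
    permutation_condition_test,
    poisson_rate_ratio_test,
)
from finchcall.stats import condition_design


def brute_force_conditional_p(x1, T1, x2, T2):
    """Independent enumeration of the conditional binomial two-sided p."""
    n = x1 + x2
    if n == 0:
        return 1.0
    p1 = T1 / (T1 + T2)
    probs = [sps.binom.pmf(k, n, p1) for k in range(n + 1)]
    obs = probs[x1]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-9)))


class TestExactRateTest:
    def test_symmetric_counts_give_p_one(self):
        res = poisson_rate_ratio_test(2, 1.0, 2, 1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.rate_ratio == pytest.approx(1.0)

    def test_five_versus_zero_equal_exposure(self):
        # Binomial(5, 1/2): P(0) + P(5) = 2/32
        res = poisson_rate_ratio_test(5, 1.0, 0, 1.0)
        assert res.p_value == pytest.approx(0.0625)
        assert np.isinf(res.rate_ratio)

    def test_double_zero_is_degenerate(self):
        res = poisson_rate_ratio_test(0, 1.0, 0, 2.0)
        assert res.p_value == 1.0
        assert np.isnan(res.rate_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_rate_ratio_test(-1, 1.0, 2, 1.0)

    def test_matches_enumeration_for_small_counts(self):
        for n in range(13):
            for x1 in range(n + 1):
                for T1, T2 in [(1.0, 1.0), (2.0, 3.0)]:
                    res = poisson_rate_ratio_test(x1, T1, n - x1, T2)
                    assert res.p_value == pytest.approx(
                        brute_force_conditional_p(x1, T1, n - x1, T2), abs=1e-12
                    )


def _count_table(counts_by_bird, exposure=10.0):
    """counts_by_bird: {subject: {condition: count}} -> tidy within-song table."""
    rows = []
    for subject, conds in counts_by_bird.items():
        for condition, count in conds.items():
            rows.append(
                {
                    "subject": subject,
                    "session": 1,
                    "condition": condition,
                    "window": "within_song",
                    "exposure_s": exposure,
                    "count": count,
                }
            )
    return pd.DataFrame(rows)


class TestPermutationTest:
    def test_constant_statistic_gives_p_one(self):
        table = _count_table({"b1": {"A": 4, "B": 4}, "b2": {"A": 7, "B": 7}})
        assert permutation_condition_test(table, ("A", "B")) == 1.0

    def test_matches_exhaustive_enumeration_two_birds(self):
        # oracle: enumerate all 4 within-bird swaps by hand
        data = {"b1": {"A": 10, "B": 0}, "b2": {"A": 8, "B": 1}}
        table = _count_table(data, exposure=10.0)
        diffs = np.array([(10 - 0) / 10.0, (8 - 1) / 10.0])
        t_obs = diffs.mean()
        stats = [
            np.mean([s1 * diffs[0], s2 * diffs[1]])
            for s1, s2 in itertools.product([1, -1], repeat=2)
        ]
        expected = np.mean([abs(t) >= abs(t_obs) - 1e-12 for t in stats])
        assert permutation_condition_test(table, ("A", "B")) == pytest.approx(expected)

    def test_random_sampling_path_is_seed_deterministic(self):
        rng_counts = np.random.default_rng(3)
        data = {
            f"b{i}": {"A": int(rng_counts.poisson(6)), "B": int(rng_counts.poisson(3))}
            for i in range(16)  # 2^16 assignments > n_perm: random path
        }
        table = _count_table(data)
        p1 = permutation_condition_test(table, ("A", "B"), n_perm=500, rng=7)
        p2 = permutation_condition_test(table, ("A", "B"), n_perm=500, rng=7)
        assert p1 == p2

    def test_missing_condition_for_a_bird_rejected(self):
        table = _count_table({"b1": {"A": 1, "B": 2}, "b2": {"A": 3}})
        with pytest.raises(ValueError, match="lacks condition"):
            permutation_condition_test(table, ("A", "B"))


class TestPoissonIrls:
    def test_intercept_only_closed_form(self):
        fit = fit_poisson_glm_irls(
            np.array([3.0, 5.0]), np.ones((2, 1)), np.zeros(2), names=["intercept"]
        )
        assert np.exp(fit.coef("intercept")) == pytest.approx(4.0, abs=1e-8)

    def test_saturated_one_factor_closed_form(self):
        y = np.array([6.0, 2.0, 9.0])
        X = np.eye(3)
        exposure = np.array([2.0, 1.0, 3.0])
        fit = fit_poisson_glm_irls(y, X, np.log(exposure), names=list("abc"))
        np.testing.assert_allclose(np.exp(fit.coefficients), y / exposure, atol=1e-8)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_response_hits_boundary_flag(self):
        fit = fit_poisson_glm_irls(np.zeros(4), np.ones((4, 1)), np.zeros(4))
        assert fit.boundary
        assert fit.coefficients[0] <= -30.0

    def test_rank_deficiency_names_collinear_columns(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="collinear"):
            fit_poisson_glm_irls(np.arange(4.0), X, names=["one", "dup"])

    def test_agrees_with_direct_likelihood_maximization(self):
        # independent oracle: Newton/quasi-Newton on the Poisson log-likelihood
        rng = np.random.default_rng(12)
        for _ in range(50):
            n, p = 20, 3
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            beta_true = rng.normal(0, 0.5, size=p)
            offset = np.log(rng.uniform(0.5, 2.0, size=n))
            y = rng.poisson(np.exp(offset + X @ beta_true)).astype(float)
            if y.sum() == 0:
                continue
            fit = fit_poisson_glm_irls(y, X, offset)

            def nll(b):
                eta = offset + X @ b
                return np.sum(np.exp(eta)) - np.sum(y * eta)

            res = optimize.minimize(nll, np.zeros(p), method="BFGS", tol=1e-12)
            np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-6)

    def test_agrees_with_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        offset = np.log(rng.uniform(1.0, 3.0, size=n))
        y = rng.poisson(np.exp(offset + X @ np.array([0.3, -0.6]))).astype(float)
        fit = fit_poisson_glm_irls(y, X, offset)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-4)

    def test_likelihood_ratio_for_condition_term(self):
        table = _count_table(
            {"b1": {"A": 12, "B": 2}, "b2": {"A": 9, "B": 1}, "b3": {"A": 11, "B": 3}}
        )
        y, X, offset, names, cond_cols = condition_design(table)
        fit = fit_poisson_glm_irls(
            y, X, offset, names=names, term="condition", term_columns=cond_cols
        )
        assert fit.lr_stat > 0
        assert fit.lr_df == 1
        assert fit.lr_p < 0.001


class TestHabituationTrend:
    def _session_table(self, counts_per_session, n_birds=3, exposure=10.0):
        rows = []
        for b in range(n_birds):
            for s, count in enumerate(counts_per_session, start=1):
                rows.append(
                    {
                        "subject": f"b{b}",
                        "session": s,
                        "condition": "FIXED",
                        "window": "within_song",
                        "exposure_s": exposure,
                        "count": count,
                    }
                )
        return pd.DataFrame(rows)

    def test_exact_halving_recovers_log_half_slope(self):
        table = self._session_table([16, 8, 4, 2])
        fit = habituation_trend(table)
        assert fit.coef("session") == pytest.approx(np.log(0.5), abs=1e-6)

    def test_constant_counts_give_zero_slope(self):
        table = self._session_table([5, 5, 5])
        fit = habituation_trend(table)
        assert fit.coef("session") == pytest.approx(0.0, abs=1e-6)
        assert fit.lr_stat == pytest.approx(0.0, abs=1e-6)

    def test_single_session_rejected(self):
        table = self._session_table([5])
        with pytest.raises(ValueError, match="two sessions"):
            habituation_trend(table)


class TestMultipleComparisons:
    def test_holm_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.04, 0.03, 0.20, 0.6])
        _, expected, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), expected, atol=1e-12)

    def test_pairwise_contrasts_report_raw_and_adjusted(self):
        table = _count_table(
            {
                "b1": {"FIXED": 12, "REVERSAL": 1, "SHUFFLED": 10},
                "b2": {"FIXED": 9, "REVERSAL": 0, "SHUFFLED": 11},
            }
        )
        out = pairwise_condition_tests(table)
        assert len(out) == 3
        assert (out["p_holm"] >= out["p_raw"] - 1e-12).all()
        assert {"condition_1", "condition_2", "p_raw", "p_holm"} <= set(out.columns)
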