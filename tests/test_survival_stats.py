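import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpbm.survival_stats import (
    fit_univariate_cox,
    fit_univariate_cox_many,
    hazard_ratio,
    km_estimate,
    logrank_test,
    mann_whitney,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def efron_loglik(x, time, event, beta):
    """Straight-from-the-definition Efron partial log-likelihood (loop form)."""
    ll = 0.0
    for ut in np.unique(time[event == 1]):
        D = (time == ut) & (event == 1)
        R = time >= ut
        d = int(D.sum())
        s0r = np.exp(beta * x[R]).sum()
        s0d = np.exp(beta * x[D]).sum()
        ll += beta * x[D].sum()
        for l in range(d):
            ll -= np.log(s0r - (l / d) * s0d)
    return ll


def grid_search_beta(x, time, event, lo=-5.0, hi=5.0, step=1e-4):
    """Argmax of the Efron partial likelihood over a dense beta grid.

    Same per-event-time tabulation as :func:`efron_loglik`, evaluated for the
    whole grid at once (numpy broadcasting over betas only).
    """
    betas = np.arange(lo, hi + step / 2, step)
    ll = np.zeros_like(betas)
    ex = np.exp(np.outer(betas, x))  # (B, n)
    for ut in np.unique(time[event == 1]):
        D = (time == ut) & (event == 1)
        R = time >= ut
        d = int(D.sum())
        s0r = ex[:, R].sum(axis=1)
        s0d = ex[:, D].sum(axis=1)
        ll += betas * x[D].sum()
        for l in range(d):
            ll -= np.log(s0r - (l / d) * s0d)
    return betas[np.argmax(ll)]


def km_product_oracle(time, event):
    """Direct product-of-terms Kaplan–Meier, one factor per event time."""
    out = {}
    s = 1.0
    for ut in sorted(set(time[event == 1])):
        d = ((time == ut) & (event == 1)).sum()
        n = (time >= ut).sum()
        s *= 1 - d / n
        out[ut] = s
    return out


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

class TestCox:
    def test_antisymmetry(self, toy_survival):
        x = np.array([0.3, -1.2, 0.7, 2.0, -0.5, 1.1, 0.0, -0.9, 0.4, 1.6])
        f1 = fit_univariate_cox(x, toy_survival.time, toy_survival.event)
        f2 = fit_univariate_cox(-x, toy_survival.time, toy_survival.event)
        assert f1.beta == pytest.approx(-f2.beta, abs=1e-8)
        assert f1.p_value == pytest.approx(f2.p_value, abs=1e-10)

    def test_zero_variance_flagged(self, toy_survival):
        f = fit_univariate_cox(
            np.ones(10), toy_survival.time, toy_survival.event
        )
        assert f.beta == 0.0 and f.p_value == 1.0 and f.flag == "zero_variance"

    def test_zero_events_error(self):
        with pytest.raises(ValueError, match="no events"):
            fit_univariate_cox(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5))

    def test_eight_subject_binary_matches_grid_search(self):
        # fixed small dataset with tied event times
        time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = fit_univariate_cox(x, time, event)
        oracle = grid_search_beta(x, time, event)
        assert fit.converged
        assert fit.beta == pytest.approx(oracle, abs=2e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_small_matches_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            n = int(rng.integers(7, 13))
            x = rng.standard_normal(n)
            time = np.round(rng.exponential(5, n), 1)
            event = rng.integers(0, 2, n)
            if event.sum() < 1:
                continue
            fit = fit_univariate_cox(x, time, event)
            if fit.converged and abs(fit.beta) < 4.5:
                break
        assert fit.beta == pytest.approx(grid_search_beta(x, time, event), abs=2e-4)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        n = 150
        x = rng.standard_normal(n)
        t = rng.exponential(1 / (0.1 * np.exp(0.5 * x)))
        c = rng.exponential(12, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        fit = fit_univariate_cox(x, time, event)
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e"
        )
        assert fit.beta == pytest.approx(cph.params_.iloc[0], abs=1e-5)
        assert fit.se == pytest.approx(cph.standard_errors_.iloc[0], rel=1e-4)

    def test_scale_equivariance(self, toy_survival):
        x = np.array([0.3, -1.2, 0.7, 2.0, -0.5, 1.1, 0.2, -0.9, 0.4, 1.6])
        f1 = fit_univariate_cox(x, toy_survival.time, toy_survival.event)
        f2 = fit_univariate_cox(2 * x, toy_survival.time, toy_survival.event)
        assert f2.beta == pytest.approx(f1.beta / 2, abs=1e-7)

    def test_vectorized_agrees_with_scalar(self, rng):
        n, G = 80, 25
        X = rng.standard_normal((n, G))
        t = rng.exponential(5, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        res = fit_univariate_cox_many(X, t, e)
        for j in [0, 7, 24]:
            f = fit_univariate_cox(X[:, j], t, e)
            assert res["beta"][j] == pytest.approx(f.beta, abs=1e-7)
            assert res["p_value"][j] == pytest.approx(f.p_value, rel=1e-6)

    def test_monotone_likelihood_flagged(self):
        # covariate perfectly ordered with event times: beta diverges
        time = np.arange(1.0, 9.0)
        event = np.ones(8)
        x = np.arange(8.0)
        f = fit_univariate_cox(x, time, event)
        assert not f.converged and f.flag == "monotone"

    def test_two_group_direction(self, rng):
        # exp(beta) must point the same way as the empirical hazard ratio
        n = 200
        g = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        t = rng.exponential(np.where(g == 1, 2.0, 6.0))
        f = fit_univariate_cox(g, t, np.ones(n))
        assert f.beta > 0  # group 1 has ~3x the hazard


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

class TestLogRank:
    def test_identical_groups_null(self):
        time = np.r_[np.array([1.0, 2, 3, 4, 5]), np.array([1.0, 2, 3, 4, 5])]
        event = np.r_[np.array([1, 0, 1, 1, 0]), np.array([1, 0, 1, 1, 0])]
        g = np.r_[np.zeros(5), np.ones(5)]
        res = logrank_test(g, time, event)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_symmetric(self, toy_survival):
        g = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        a = logrank_test(g, toy_survival.time, toy_survival.event)
        b = logrank_test(1 - g, toy_survival.time, toy_survival.event)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_ten_subject_hand_tabulation(self, toy_survival):
        g = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        time, event = toy_survival.time, toy_survival.event
        # independent per-event-time tabulation
        O1 = E1 = V = 0.0
        for ut in sorted(set(time[event == 1])):
            at = time >= ut
            n = at.sum()
            n1 = (at & (g == 1)).sum()
            d = ((time == ut) & (event == 1)).sum()
            d1 = ((time == ut) & (event == 1) & (g == 1)).sum()
            O1 += d1
            E1 += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_stat = (O1 - E1) ** 2 / V
        res = logrank_test(g, time, event)
        assert res.statistic == pytest.approx(expected_stat, rel=1e-12)

    def test_no_events_degenerate(self):
        res = logrank_test(
            np.array([0, 0, 1, 1]), np.array([1.0, 2, 3, 4]), np.zeros(4)
        )
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_one_group_empty_raises(self):
        with pytest.raises(ValueError):
            logrank_test(np.zeros(4), np.arange(1.0, 5.0), np.ones(4))


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

class TestKM:
    def test_all_censored_flat(self):
        km = km_estimate(np.array([1.0, 2, 3]), np.zeros(3))
        assert km.event_times.size == 0
        assert km.survival_at(99.0) == 1.0

    def test_distinct_events_closed_form(self):
        n = 6
        km = km_estimate(np.arange(1.0, n + 1), np.ones(n))
        np.testing.assert_allclose(km.survival, (n - 1 - np.arange(n)) / n)

    def test_mixed_cohort_product_oracle(self, toy_survival):
        km = km_estimate(toy_survival.time, toy_survival.event)
        oracle = km_product_oracle(toy_survival.time, toy_survival.event)
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(oracle[t], rel=1e-12)

    def test_no_censoring_is_empirical_survival(self, rng):
        t = rng.exponential(3, 40)
        km = km_estimate(t, np.ones(40))
        for q in [np.quantile(t, 0.3), np.quantile(t, 0.8)]:
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_curve_monotone_from_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        t = np.round(rng.exponential(5, n), 1)
        e = rng.integers(0, 2, n)
        km = km_estimate(t, e)
        assert np.all(km.survival <= 1.0 + 1e-12)
        assert np.all(np.diff(km.survival) <= 1e-12)


# ---------------------------------------------------------------------------
# hazard ratio
# ---------------------------------------------------------------------------

class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        time = np.r_[np.arange(1.0, 11.0), np.arange(1.0, 11.0)]
        event = np.r_[np.ones(10), np.ones(10)]
        g = np.r_[np.zeros(10), np.ones(10)]
        res = hazard_ratio(g, time, event)
        assert res.hr == pytest.approx(1.0, abs=1e-6)
        assert res.ci_low < 1.0 < res.ci_high

    def test_complement_reciprocal(self, toy_survival):
        g = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        a = hazard_ratio(g, toy_survival.time, toy_survival.event)
        b = hazard_ratio(1 - g, toy_survival.time, toy_survival.event)
        assert a.hr == pytest.approx(1 / b.hr, rel=1e-8)

    def test_equals_exp_grid_beta(self, toy_survival):
        g = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1]).astype(float)
        oracle = grid_search_beta(g, toy_survival.time, toy_survival.event)
        res = hazard_ratio(g, toy_survival.time, toy_survival.event)
        assert res.hr == pytest.approx(np.exp(oracle), rel=5e-4)

    def test_all_events_one_group_flagged(self):
        # all events in group 1 while group 0 stays at risk: beta diverges
        g = np.r_[np.ones(5), np.zeros(5)]
        t = np.arange(1.0, 11.0)
        e = np.r_[np.ones(5), np.zeros(5)]
        res = hazard_ratio(g, t, e)
        assert res.flag == "monotone"
        assert res.hr in (0.0, np.inf)


# ---------------------------------------------------------------------------
# Mann–Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_samples_p_one(self):
        a = [3.0, 3.0, 3.0]
        _, p = mann_whitney(a, a)
        assert p == pytest.approx(1.0)

    def test_three_vs_three_exact(self):
        # all C(6,3)=20 labelings; the observed split is the most extreme
        # one in each direction -> two-sided p = 2/20
        _, p = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(2 / 20)

    def test_swap_symmetry(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(10)
        _, p1 = mann_whitney(a, b)
        _, p2 = mann_whitney(b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_exhaustive_enumeration_oracle_with_ties(self):
        # ties across the two samples: the permutation-exact p must match
        # brute-force enumeration over all C(7,4) labelings of the pooled data
        a = np.array([0.1, 0.9, 1.4, 2.0])
        b = np.array([0.5, 0.9, 2.0])
        pooled = np.concatenate([a, b])
        n_a = a.size
        u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        count_ge = count_le = total = 0
        for comb in itertools.combinations(range(pooled.size), n_a):
            aa = pooled[list(comb)]
            bb = np.delete(pooled, list(comb))
            u = sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)
            total += 1
            count_ge += u >= u_obs
            count_le += u <= u_obs
        expected = min(1.0, 2 * min(count_ge / total, count_le / total))
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_scipy_exact_without_ties(self, rng, alternative):
        # scipy's exact method assumes untied data, so compare on continuous draws
        from scipy.stats import mannwhitneyu

        a = rng.standard_normal(9)
        b = rng.standard_normal(11) + 0.3
        u, p = mann_whitney(a, b, alternative=alternative)
        ref = mannwhitneyu(a, b, alternative=alternative, method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_close_to_normal_approx_n12(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.standard_normal(12)
        b = rng.standard_normal(12) + 0.8
        _, p_exact = mann_whitney(a, b)
        p_approx = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_approx) < 0.01


class TestLikelihoodRatioOption:
    def test_lr_p_close_to_wald_on_moderate_effect(self, toy_survival):
        x = np.array([0.3, -1.2, 0.7, 2.0, -0.5, 1.1, 0.2, -0.9, 0.4, 1.6])
        wald = fit_univariate_cox(x, toy_survival.time, toy_survival.event)
        lr = fit_univariate_cox(
            x, toy_survival.time, toy_survival.event, p_method="lr"
        )
        assert lr.beta == wald.beta
        assert 0 < lr.p_value <= 1
        # both tests agree on significance at moderate effects
        assert (lr.p_value < 0.05) == (wald.p_value < 0.05)

    def test_lr_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        from scipy.stats import chi2

        n = 120
        x = rng.standard_normal(n)
        t = rng.exponential(1 / (0.1 * np.exp(0.6 * x)))
        c = rng.exponential(12, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        lr = fit_univariate_cox(x, time, event, p_method="lr")
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e"
        )
        ref = cph.log_likelihood_ratio_test()
        assert lr.p_value == pytest.approx(chi2.sf(ref.test_statistic, 1), rel=1e-4)
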