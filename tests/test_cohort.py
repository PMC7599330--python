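"""Survival stack and contingency tests against hand and library oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from dx2quant.cohort import (
    ConvergenceError,
    cox_ph,
    fisher_exact_rxc,
    km_estimate,
    logrank_test,
    mann_whitney_u,
    quantile_cutoff,
)


class TestQuantileCutoff:
    def test_type7_first_quartile(self):
        split = quantile_cutoff([1, 2, 3, 4, 5], q=0.25)
        assert split.cutoff == pytest.approx(2.0)
        assert list(split.labels) == ["low", "high", "high", "high", "high"]

    def test_median_of_two(self):
        assert quantile_cutoff([0, 10], q=0.5).cutoff == pytest.approx(5.0)

    def test_all_equal_single_group_warns(self):
        with pytest.warns(UserWarning, match="single group"):
            split = quantile_cutoff([3, 3, 3], q=0.25)
        assert set(split.labels) == {"high"}

    def test_empty_and_bad_q(self):
        with pytest.raises(ValueError):
            quantile_cutoff([], 0.25)
        with pytest.raises(ValueError):
            quantile_cutoff([1.0], 1.5)


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        curve = km_estimate([1, 2, 3], [True, True, True])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.median == 2.0

    def test_all_censored_median_not_reached(self):
        curve = km_estimate([5, 6, 7], [False, False, False])
        assert curve.times.size == 0
        assert curve.median is None
        assert curve.survival_at(100.0) == 1.0

    def test_single_event(self):
        curve = km_estimate([5.0], [True])
        assert curve.survival_at(5.0) == 0.0
        assert curve.median == 5.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(1, 30, size=25).astype(float)
        curve = km_estimate(times, np.ones_like(times, dtype=bool))
        for t in np.unique(times):
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_censoring_handled_like_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=40)
        events = rng.random(40) < 0.7
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [True, True])


class TestLogrank:
    def test_identical_groups_null(self):
        g = ([1, 2, 3, 4], [True, True, False, True])
        chi2, p = logrank_test([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_o_e_v(self):
        """A events at 1,2; B events at 10,11; O/E/V tabulated by hand.

        Event times 1,2,10,11. For group A:
          t=1: nA=2,nB=2,d=1 -> E=1/2, V=(1*3/3)*(2*2/16)=1/4
          t=2: nA=1,nB=2,d=1 -> E=1/3, V=2/9
          t=10: nA=0 -> E=0, V=0 ; t=11: E=0, V=0
        O_A=2, E_A=5/6, V=1/4+2/9=17/36 -> chi2=(2-5/6)^2/(17/36)
        """
        chi2, p = logrank_test([([1, 2], [True, True]), ([10, 11], [True, True])])
        expected = (2 - 5 / 6) ** 2 / (17 / 36)
        assert chi2 == pytest.approx(expected)
        assert p == pytest.approx(float(stats.chi2.sf(expected, 1)))

    def test_label_swap_symmetry(self):
        a = ([1, 3, 5, 9], [True, False, True, True])
        b = ([2, 4, 6, 8], [True, True, False, True])
        assert logrank_test([a, b])[0] == pytest.approx(logrank_test([b, a])[0])

    def test_three_groups_df(self, rng):
        groups = [
            (rng.exponential(scale, 15), np.ones(15, dtype=bool))
            for scale in (5, 10, 20)
        ]
        chi2, p = logrank_test(groups)
        assert p == pytest.approx(float(stats.chi2.sf(chi2, df=2)))

    def test_lifelines_cross_check(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t1, t2 = rng.exponential(8, 30), rng.exponential(14, 25)
        e1 = rng.random(30) < 0.8
        e2 = rng.random(25) < 0.8
        chi2, p = logrank_test([(t1, e1), (t2, e2)])
        res = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
        assert p == pytest.approx(res.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1], [True]), ([], [])])


def naive_breslow_neglogpl(beta, times, events, x):
    """Written-out Breslow partial log-likelihood for a single covariate."""
    ll = 0.0
    for et in sorted({t for t, e in zip(times, events) if e}):
        dead = [i for i, (t, e) in enumerate(zip(times, events)) if t == et and e]
        risk = [i for i, t in enumerate(times) if t >= et]
        denom = sum(math.exp(beta * x[i]) for i in risk)
        for i in dead:
            ll += beta * x[i]
        ll -= len(dead) * math.log(denom)
    return ll


class TestCox:
    times = [3.0, 5.0, 7.0, 11.0, 2.0, 6.0, 9.0, 14.0, 4.0, 8.0]
    events = [True, True, False, True, True, True, True, False, True, True]
    x = [1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0]

    def test_coefficient_matches_grid_search_oracle(self):
        fit = cox_ph(self.times, self.events, self.x)
        grid = np.linspace(-3, 3, 6001)
        lls = [naive_breslow_neglogpl(b, self.times, self.events, self.x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert fit.coef[0] == pytest.approx(beta_grid, abs=1e-3)
        # refined: golden-section around the grid optimum on the naive formula
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda b: -naive_breslow_neglogpl(b, self.times, self.events, self.x),
            bracket=(beta_grid - 0.01, beta_grid + 0.01),
        )
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-4)

    def test_symmetric_groups_give_zero_coefficient(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [True] * 6
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        # mirrored event patterns: covariate carries no information
        fit = cox_ph(times, events, x)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr[0] == pytest.approx(1.0)

    def test_score_test_equals_logrank_for_binary_covariate(self):
        fit = cox_ph(self.times, self.events, self.x)
        chi2, _ = logrank_test(
            [
                ([t for t, g in zip(self.times, self.x) if g == 1],
                 [e for e, g in zip(self.events, self.x) if g == 1]),
                ([t for t, g in zip(self.times, self.x) if g == 0],
                 [e for e, g in zip(self.events, self.x) if g == 0]),
            ]
        )
        assert fit.score_chi2 == pytest.approx(chi2, abs=1e-6)

    def test_wald_ci_brackets_hr(self):
        fit = cox_ph(self.times, self.events, self.x)
        lo, hi = fit.ci95[0]
        assert lo <= fit.hr[0] <= hi

    def test_lifelines_cross_check_no_ties(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 60
        x = rng.random(n)
        t = rng.exponential(np.exp(-0.8 * x))
        e = rng.random(n) < 0.85
        fit = cox_ph(t, e, x)  # no ties: Breslow == Efron
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.coef[0] == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert fit.se[0] == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-5)

    def test_efron_ties_option(self):
        times = [2, 2, 3, 4, 4, 5, 6, 7]
        events = [True] * 8
        x = [1, 0, 1, 1, 0, 0, 1, 0]
        b = cox_ph(times, events, x, ties="breslow").coef[0]
        e = cox_ph(times, events, x, ties="efron").coef[0]
        assert b != pytest.approx(e, abs=1e-6)  # tie corrections differ

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_ph([1, 2, 3], [False, False, False], [0.0, 1.0, 2.0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_ph([1, 2, 3], [True, True, True], [2.0, 2.0, 2.0])

    def test_complete_separation_diverges(self):
        # all treated events strictly precede every control event: monotone PL
        times = [1, 2, 3, 4, 10, 11, 12, 13]
        events = [True] * 8
        x = [1, 1, 1, 1, 0, 0, 0, 0]
        with pytest.raises(ConvergenceError):
            cox_ph(times, events, x)


def fisher_2x2_oracle(table):
    """Independent 2x2 two-sided Fisher by direct enumeration over one cell."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logp(x):
        return (
            gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1) + gammaln(n - c1 + 1)
            - gammaln(n + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
            - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = logp(a)
    return sum(math.exp(logp(x)) for x in range(lo, hi + 1) if logp(x) <= obs + 1e-7)


class TestFisherRxC:
    def test_two_by_two_identity_table(self):
        assert fisher_exact_rxc([[1, 0], [0, 1]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 1], [1, 3]],
            [[8, 2], [1, 5]],
            [[10, 0], [0, 10]],
            [[2, 7], [8, 2]],
        ],
    )
    def test_two_by_two_matches_scipy_and_oracle(self, table):
        p = fisher_exact_rxc(table)
        assert p == pytest.approx(stats.fisher_exact(table)[1], rel=1e-9)
        assert p == pytest.approx(fisher_2x2_oracle(table), rel=1e-9)

    def test_three_by_three_total_probability_and_range(self):
        table = [[2, 3, 1], [4, 0, 2], [1, 2, 3]]
        with np.errstate(all="ignore"):
            p = fisher_exact_rxc(table)
        assert 0 < p <= 1

    def test_r_by_c_probability_mass_sums_to_one(self, recwarn):
        # the implementation warns if enumerated probabilities miss 1 by >1e-6
        fisher_exact_rxc([[2, 3, 1], [4, 0, 2], [1, 2, 3]])
        assert not [w for w in recwarn.list if "sum to" in str(w.message)]

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1.5, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_rxc([[-1, 2], [3, 4]])

    def test_degenerate_margins_return_one(self):
        assert fisher_exact_rxc([[0, 0], [1, 2]]) == 1.0


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / math.comb(6, 3))  # 0.1 by enumeration

    def test_identical_multisets_p_one(self):
        u, p = mann_whitney_u([1, 2, 2, 5], [1, 2, 2, 5])
        assert p == pytest.approx(1.0)

    def test_u_complement_identity(self, rng):
        x = rng.integers(0, 20, 7).astype(float)
        y = rng.integers(0, 20, 9).astype(float)
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_matches_full_enumeration_with_ties(self):
        x = [1.0, 2.0, 2.0]
        y = [2.0, 3.0, 4.0]
        _, p = mann_whitney_u(x, y)
        pooled = x + y
        ranks = stats.rankdata(pooled)
        n1 = len(x)
        mu = n1 * len(y) / 2
        obs = abs(ranks[:n1].sum() - n1 * (n1 + 1) / 2 - mu)
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
            total += 1
            count += abs(u - mu) >= obs - 1e-9
        assert p == pytest.approx(count / total)

    def test_large_samples_use_corrected_normal_approx(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 35)
        _, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
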