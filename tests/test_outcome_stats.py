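import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize_scalar

import giscore as g
from giscore.outcome_stats import FIVE_YEARS_DAYS


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        km = g.km_fit([1, 2, 3, 4], [True] * 4)
        assert km.rate_at(2.5)[0] == pytest.approx(0.5)
        # empirical survival at every observed time
        times = np.array([1, 2, 3, 4.0])
        for t in times:
            assert km.rate_at(t)[0] == pytest.approx((times > t).mean())

    def test_all_censored_survival_is_one(self):
        km = g.km_fit([5, 10, 15], [False] * 3)
        assert km.rate_at(20)[0] == 1.0

    def test_hand_computed_product_limit_table(self):
        # 6 subjects, censoring at t=2 and t=5:
        # S(1)=5/6, S(3)=5/6*3/4=0.625, S(4)=0.625*2/3, S(6)=0
        km = g.km_fit([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        assert km.rate_at(1)[0] == pytest.approx(5 / 6)
        assert km.rate_at(3)[0] == pytest.approx(0.625)
        assert km.rate_at(4)[0] == pytest.approx(5 / 12)
        assert km.rate_at(6)[0] == pytest.approx(0.0)

    def test_ci_brackets_estimate(self, bundle):
        clin = bundle.clinical
        km = g.km_fit(clin["os_days"], clin["os_event"])
        assert np.all(km.survival[1:] <= km.survival[:-1] + 1e-12)
        ok = np.isfinite(km.ci_low) & np.isfinite(km.ci_high)
        assert np.all(km.ci_low[ok] <= km.survival[ok] + 1e-9)
        assert np.all(km.survival[ok] <= km.ci_high[ok] + 1e-9)
        rate, lo, hi = km.five_year_rate()
        assert 0 <= lo <= rate <= hi <= 1

    def test_no_subjects_is_error(self):
        with pytest.raises(ValueError):
            g.km_fit([], [])


class TestLogRank:
    def test_identical_groups(self):
        t = [3, 5, 8, 10]
        e = [1, 1, 0, 1]
        res = g.logrank_test([(t, e), (t, e)])
        assert res.chi2 == pytest.approx(0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            g.logrank_test([([1, 2], [1, 1]), ([], [])])

    @pytest.mark.parametrize("seed", [5, 17])
    def test_permutation_matches_enumeration_oracle(self, seed):
        """Exact permutation p equals a brute-force enumeration of every
        group relabelling scored with lifelines' statistic."""
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(seed)
        t = rng.exponential(10, 8).round(1)
        e = rng.random(8) < 0.8
        if not e.any():
            e[0] = True
        got = g.logrank_test([(t[:4], e[:4]), (t[4:], e[4:])],
                             method="permutation")
        obs = ll(t[:4], t[4:], e[:4], e[4:]).test_statistic
        hits = 0
        for idx in combinations(range(8), 4):
            m = np.zeros(8, bool)
            m[list(idx)] = True
            if ll(t[m], t[~m], e[m], e[~m]).test_statistic >= obs - 1e-12:
                hits += 1
        assert got.p == pytest.approx(hits / comb(8, 4))

    def test_power_under_strong_hazard_separation(self):
        """HR = 0.3 with 200 per arm should be detected at p < .001."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t1 = rng.exponential(10, 200)
            t2 = rng.exponential(10 / 0.3, 200)
            c = rng.exponential(30, 400)
            times = np.concatenate([np.minimum(t1, c[:200]),
                                    np.minimum(t2, c[200:])])
            ev = np.concatenate([t1 <= c[:200], t2 <= c[200:]])
            res = g.logrank_test([(times[:200], ev[:200]),
                                  (times[200:], ev[200:])])
            hits += res.p < 0.001
        assert hits >= 19


def _breslow_negloglik(beta, t, e, x):
    ll = 0.0
    for ti in t[e]:
        risk = t >= ti
        ll += beta * x[(t == ti) & e].sum() - np.log(np.exp(beta * x[risk]).sum())
    return -ll


class TestCox:
    def test_single_covariate_matches_partial_likelihood_oracle(self):
        """Coefficient equals direct maximization of the written-out partial
        likelihood (golden-section / bounded scalar search)."""
        t = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        e = np.array([1, 1, 0, 1, 1, 1], bool)
        x = np.array([1.0, 0, 1, 0, 1, 0])
        oracle = minimize_scalar(_breslow_negloglik, args=(t, e, x),
                                 bounds=(-10, 10), method="bounded",
                                 options={"xatol": 1e-10}).x
        res = g.cox_fit(pd.DataFrame({"x": x}), t, e, ties="breslow")
        assert res.summary.loc["x", "coef"] == pytest.approx(oracle, abs=1e-6)
        # no tied event times: Efron and Breslow coincide
        res_e = g.cox_fit(pd.DataFrame({"x": x}), t, e, ties="efron")
        assert res_e.summary.loc["x", "coef"] == pytest.approx(oracle, abs=1e-6)

    def test_duplicating_subjects_preserves_breslow_estimate(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 40)
        e = rng.random(40) < 0.8
        x = rng.random(40)
        a = g.cox_fit(pd.DataFrame({"x": x}), t, e, ties="breslow")
        b = g.cox_fit(pd.DataFrame({"x": np.r_[x, x]}), np.r_[t, t],
                      np.r_[e, e], ties="breslow")
        assert b.summary.loc["x", "coef"] == pytest.approx(
            a.summary.loc["x", "coef"], abs=1e-5)

    def test_null_covariate_ci_calibration(self):
        """A covariate independent of survival: 95% Wald CI covers HR=1 at
        roughly the nominal rate."""
        covered = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t = rng.exponential(10, 200)
            e = rng.random(200) < 0.7
            x = rng.integers(0, 2, 200).astype(float)
            s = g.cox_fit(pd.DataFrame({"x": x}), t, e).summary
            covered += s.loc["x", "ci95_low"] <= 1.0 <= s.loc["x", "ci95_high"]
        assert covered >= 0.85 * n_seeds

    def test_consistency_against_exponential_mle(self):
        """With exponential survival and a binary covariate, the Cox
        coefficient approaches the log rate ratio of exponential MLEs."""
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        lam = 0.1 * np.exp(0.7 * x)
        t = rng.exponential(1 / lam)
        e = np.ones(n, bool)
        mle = np.log((e[x == 1].sum() / t[x == 1].sum())
                     / (e[x == 0].sum() / t[x == 0].sum()))
        res = g.cox_fit(pd.DataFrame({"x": x}), t, e)
        assert res.summary.loc["x", "coef"] == pytest.approx(mle, abs=0.05)

    def test_cross_check_against_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "t": rng.exponential(10, 150).round(0) + 1,  # induces ties
            "e": rng.random(150) < 0.7,
            "x1": rng.normal(size=150),
            "x2": rng.integers(0, 2, 150).astype(float),
        })
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        res = g.cox_fit(df[["x1", "x2"]], df["t"], df["e"], ties="efron")
        for c in ("x1", "x2"):
            assert res.summary.loc[c, "coef"] == pytest.approx(
                cph.params_[c], abs=1e-4)

    def test_constant_covariate_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            g.cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}),
                      [1, 2, 3], [1, 1, 0])

    def test_few_events_warns(self):
        rng = np.random.default_rng(1)
        design = pd.DataFrame(rng.normal(size=(30, 3)),
                              columns=["x", "y", "z"])
        t = rng.exponential(10, 30)
        e = np.zeros(30, bool)
        e[[4, 11]] = True  # fewer events than covariates
        with pytest.warns(UserWarning, match="events"):
            g.cox_fit(design, t, e)


class TestWilcoxon:
    def test_identical_multisets(self):
        assert g.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        # 20 assignments of 3 ranks; the two extreme ones are as deviant
        assert g.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_branch_matches_enumeration_with_ties(self, seed):
        """Exact p equals a brute-force enumeration over all group
        assignments of the pooled (midrank) values."""
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=rng.integers(2, 6)).astype(float)
        b = rng.integers(0, 5, size=rng.integers(2, 6)).astype(float)
        got = g.wilcoxon_rank_sum(a, b)
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        n, na = pooled.size, a.size
        expect = na * (n + 1) / 2
        dev = abs(ranks[:na].sum() - expect)
        hits = sum(abs(ranks[list(idx)].sum() - expect) >= dev - 1e-9
                   for idx in combinations(range(n), na))
        assert got == pytest.approx(hits / comb(n, na))

    def test_exact_branch_matches_scipy_without_ties(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=5), rng.normal(size=6)
        assert g.wilcoxon_rank_sum(a, b) == pytest.approx(
            sps.mannwhitneyu(a, b, method="exact").pvalue)

    def test_asymptotic_branch_matches_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 20, 30).astype(float)
        b = rng.integers(5, 25, 35).astype(float)
        expected = sps.mannwhitneyu(a, b, method="asymptotic",
                                    use_continuity=True).pvalue
        assert g.wilcoxon_rank_sum(a, b) == pytest.approx(expected, rel=1e-9)

    def test_power_under_shift(self):
        """Shift of 2 SD with 50 per arm is essentially always detected."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 50)
            b = rng.normal(2, 1, 50)
            hits += g.wilcoxon_rank_sum(a, b) < 0.01
        assert hits == 20

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            g.wilcoxon_rank_sum([], [1.0])


def _fisher_enumeration_oracle(table):
    """Independent hypergeometric enumeration for a 2x2 table."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    n1, m1, N = a + b, a + c, a + b + c + d
    rv = sps.hypergeom(N, m1, n1)
    p_obs = rv.pmf(a)
    ks = range(max(0, m1 - (c + d)), min(m1, n1) + 1)
    return float(sum(rv.pmf(k) for k in ks if rv.pmf(k) <= p_obs * (1 + 1e-7)))


class TestFisher:
    def test_symmetric_table(self):
        assert g.fisher_exact_2x2([[5, 5], [5, 5]]).p == pytest.approx(1.0)

    def test_zero_margin(self):
        assert g.fisher_exact_2x2([[0, 0], [3, 4]]).p == 1.0

    def test_reconstructed_platinum_table(self):
        """High-score vs low-score platinum-resistance table: p agrees with
        the enumeration oracle and rounds to 0.05."""
        res = g.fisher_exact_2x2([[25, 73], [38, 59]])
        assert res.p == pytest.approx(0.0472620528337835, abs=1e-12)
        assert res.p == pytest.approx(_fisher_enumeration_oracle([[25, 73], [38, 59]]))
        assert res.odds_ratio == pytest.approx(25 * 59 / (73 * 38))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_random_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() <= 40 and all(t.sum(axis=0) > 0) and all(t.sum(axis=1) > 0):
                break
        assert g.fisher_exact_2x2(t).p == pytest.approx(
            _fisher_enumeration_oracle(t), abs=1e-10)


class TestBinTrend:
    def test_step_outcome_construction(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 120, 600)
        scores[0], scores[-1] = 0.0, 120.0  # pin the range
        outcome = scores >= 60
        trend = g.bin_response_trend(scores, outcome)
        assert np.all(trend.rate[:6] == 0)
        assert np.all(trend.rate[6:] == 1)
        assert trend.slope > 0
        assert trend.n.sum() == 600

    def test_empty_bin_excluded_from_regression(self):
        scores = np.r_[np.linspace(0, 10, 40), np.linspace(110, 120, 40)]
        outcome = scores >= 60
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trend = g.bin_response_trend(scores, outcome)
        assert np.isnan(trend.rate[trend.n == 0]).all()
        assert np.isfinite(trend.slope)

    def test_identical_scores_error(self):
        with pytest.raises(ValueError):
            g.bin_response_trend([5.0] * 30, [True] * 30)
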