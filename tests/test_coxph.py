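"""Cox engine, Kaplan-Meier, log-rank and Schoenfeld diagnostics.

Oracles: lifelines (independent implementation) for full fits, a 1-D
golden-section maximizer of the explicitly coded partial likelihood for the
tiny-sample case, and hand tabulation for the log-rank worked example.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import recursig as rs
from recursig import coxph


def _censored_data(seed, n=150, beta=(0.7, -0.4), cens=30.0, ties=False):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(beta)))
    T = rng.exponential(1.0 / (0.05 * np.exp(X @ np.asarray(beta))))
    C = rng.exponential(cens, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    if ties:
        time = np.round(time, 0) + 0.5
    return X, time, event


class TestFitCox:
    @pytest.mark.parametrize("ties,strata", [(False, False), (True, False),
                                             (True, True)])
    def test_matches_lifelines(self, ties, strata):
        from lifelines import CoxPHFitter
        X, time, event = _censored_data(1, ties=ties)
        s = np.random.default_rng(2).choice(["a", "b"], len(time)) if strata else None
        fit = rs.fit_cox(X, time, event, strata=s)
        df = pd.DataFrame(X, columns=["x0", "x1"]).assign(t=time, e=event)
        kw = {}
        if strata:
            df["s"] = s
            kw["strata"] = ["s"]
        cf = CoxPHFitter().fit(df, "t", "e", **kw)
        np.testing.assert_allclose(fit.coef, cf.params_.values, atol=2e-5)
        np.testing.assert_allclose(fit.se, cf.standard_errors_.values, atol=2e-5)
        np.testing.assert_allclose(fit.loglik, cf.log_likelihood_, atol=1e-6)

    def test_null_case_coefficient_within_3se(self):
        rng = np.random.default_rng(4)
        n = 400
        g = (rng.random(n) < 0.5).astype(float)
        T = rng.exponential(20.0, n)  # identical law in both groups
        fit = rs.fit_cox(g[:, None], T, np.ones(n, int))
        assert abs(fit.coef[0]) < 3 * fit.se[0]

    def test_true_hr2_recovered(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        T = rng.exponential(1.0 / (0.02 * np.exp(np.log(2.0) * x)))
        fit = rs.fit_cox(x[:, None], T, np.ones(n, int))
        assert abs(fit.coef[0] - np.log(2.0)) < 0.1

    def test_tiny_sample_matches_1d_brute_force(self):
        """Newton solution equals golden-section maximization of the coded
        partial likelihood on n=5 uncensored, tie-free data."""
        x = np.array([[0.5], [-1.2], [0.3], [2.0], [-0.7]])
        time = np.array([3.0, 7.0, 1.0, 9.0, 5.0])
        event = np.ones(5, int)
        fit = rs.fit_cox(x, time, event)

        def negll(b):
            return -rs.cox_loglik(x, time, event, [b])[0]

        res = optimize.minimize_scalar(negll, bounds=(-10, 10),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        assert abs(fit.coef[0] - res.x) < 1e-6

    def test_score_vanishes_at_optimum(self):
        X, time, event = _censored_data(5)
        fit = rs.fit_cox(X, time, event)
        _, grad, _ = rs.cox_loglik(X, time, event, fit.coef)
        assert np.abs(grad).max() < 1e-6

    def test_no_events_error(self):
        X, time, _ = _censored_data(6, n=20)
        with pytest.raises(ValueError, match="events"):
            rs.fit_cox(X, time, np.zeros(20, int))

    def test_constant_covariate_error(self):
        X, time, event = _censored_data(7, n=20)
        X[:, 1] = 1.0
        with pytest.raises(ValueError, match="constant"):
            rs.fit_cox(X, time, event)

    def test_separation_triggers_ridge_fallback(self):
        # covariate perfectly ordering event times -> monotone likelihood
        n = 30
        x = np.linspace(-1, 1, n)
        time = np.argsort(np.argsort(-x)) + 1.0  # high x fails first
        fit = rs.fit_cox(x[:, None], time, np.ones(n, int))
        assert fit.separable
        assert np.isfinite(fit.coef[0])


class TestBatchCox:
    def test_batch_agrees_with_single_fits(self):
        rng = np.random.default_rng(10)
        n, G = 80, 12
        genes = rng.standard_normal((G, n))
        age = rng.normal(65, 8, n)
        T = rng.exponential(1.0 / (0.03 * np.exp(0.5 * genes[0])))
        C = rng.exponential(40.0, n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
        strata = rng.choice(["a", "b"], n)
        res = coxph.batch_cox(genes, time, event, shared=age[:, None],
                              strata=strata)
        for g in range(0, G, 3):
            single = rs.fit_cox(np.column_stack([genes[g], age]), time, event,
                                strata=strata)
            np.testing.assert_allclose(res["coef"][g], single.coef[0], atol=1e-6)
            np.testing.assert_allclose(res["p"][g], single.p[0], atol=1e-6)


class TestSchoenfeld:
    def test_residuals_sum_to_zero(self):
        X, time, event = _censored_data(11, ties=True)
        fit = rs.fit_cox(X, time, event)
        _, res = rs.schoenfeld_residuals(fit, X, time, event)
        np.testing.assert_allclose(res.sum(axis=0), 0.0, atol=1e-8)

    def test_matches_lifelines_km_transform(self):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test
        X, time, event = _censored_data(12)
        fit = rs.fit_cox(X, time, event)
        p_mine = rs.schoenfeld_ph_test(fit, X, time, event, transform="km")
        df = pd.DataFrame(X, columns=["x0", "x1"]).assign(t=time, e=event)
        cf = CoxPHFitter().fit(df, "t", "e")
        r = proportional_hazard_test(cf, df, time_transform="km")
        np.testing.assert_allclose(np.sort(p_mine),
                                   np.sort(r.summary["p"].values), atol=1e-4)

    def test_type_i_error_calibrated(self):
        """PH-true replicates: rejection rate at alpha=0.05 in [0.03, 0.07]."""
        rng = np.random.default_rng(13)
        n_rej, N = 0, 1000
        for _ in range(N):
            n = 100
            x = rng.standard_normal((n, 1))
            T = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x[:, 0])))
            C = rng.exponential(1.0 / 0.03, n)
            time, event = np.minimum(T, C), (T <= C).astype(int)
            fit = rs.fit_cox(x, time, event)
            n_rej += rs.schoenfeld_ph_test(fit, x, time, event,
                                           transform="rank")[0] < 0.05
        assert 0.03 <= n_rej / N <= 0.07

    def test_power_against_sign_flip(self):
        """Effect reversing sign at the median time is detected."""
        rng = np.random.default_rng(14)
        detected, N = 0, 60
        for _ in range(N):
            n = 500
            x = rng.standard_normal(n)
            t_flip = np.log(2) / 0.05
            lam1 = 0.05 * np.exp(x)
            lam2 = 0.05 * np.exp(-x)
            u = rng.exponential(1.0, n)
            T = np.where(u < lam1 * t_flip, u / lam1,
                         t_flip + (u - lam1 * t_flip) / lam2)
            fit = rs.fit_cox(x[:, None], T, np.ones(n, int))
            detected += rs.schoenfeld_ph_test(fit, x[:, None], T,
                                              np.ones(n, int))[0] < 0.01
        assert detected / N >= 0.90

    def test_too_few_events_error(self):
        x = np.array([[0.1], [0.4], [-0.2], [0.9]])
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 0])
        fit = rs.fit_cox(x, time, event)
        with pytest.raises(ValueError, match="3 events"):
            rs.schoenfeld_ph_test(fit, x, time, event)


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survivor(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(10.0, 40)
        km = rs.km_estimate(t, np.ones(40, int))
        for u, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(t > u))

    def test_all_censored_survival_one(self):
        km = rs.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at(100.0) == 1.0

    def test_hand_product_limit(self):
        km = rs.km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2.0 / 3.0)
        assert km.survival_at(2.5) == pytest.approx(2.0 / 3.0)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(16)
        t = rng.exponential(5.0, 30)
        e = (rng.random(30) < 0.6).astype(int)
        km1 = rs.km_estimate(t, e)
        perm = rng.permutation(30)
        km2 = rs.km_estimate(t[perm], e[perm])
        np.testing.assert_array_equal(km1.times, km2.times)
        np.testing.assert_allclose(km1.survival, km2.survival, atol=1e-14)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(17)
        t = rng.exponential(5.0, 60)
        e = (rng.random(60) < 0.7).astype(int)
        km = rs.km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(km.times).values
        np.testing.assert_allclose(km.survival, ref, atol=1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        chi2, p = rs.logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(18)
        t = rng.exponential(5.0, 50)
        e = (rng.random(50) < 0.7).astype(int)
        g = (rng.random(50) < 0.4).astype(int)
        chi2a, _ = rs.logrank_test(t, e, g)
        chi2b, _ = rs.logrank_test(t, e, 1 - g)
        assert chi2a == pytest.approx(chi2b, rel=1e-12)

    def test_hand_tabulated_six_samples(self):
        # group 0: times 1(event), 3(event), 5(censored)
        # group 1: times 2(event), 4(censored), 6(event)
        t = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        e = np.array([1, 1, 0, 1, 0, 1])
        g = np.array([0, 0, 0, 1, 1, 1])
        # hand tabulation over event times 1, 2, 3, 6 (group-1 at risk / total):
        # t=1: 3/6, t=2: 3/5, t=3: 2/4, t=6: 1/1
        o_minus_e = (0 - 3 / 6) + (1 - 3 / 5) + (0 - 2 / 4) + (1 - 1)
        var = sum(nr * (1 - nr) for nr in (3 / 6, 3 / 5, 2 / 4, 1.0))
        chi2, _ = rs.logrank_test(t, e, g)
        assert chi2 == pytest.approx(o_minus_e ** 2 / var, abs=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(19)
        t = rng.exponential(5.0, 80)
        e = (rng.random(80) < 0.7).astype(int)
        g = (rng.random(80) < 0.5).astype(int)
        chi2, p = rs.logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)

    def test_equals_cox_score_test_breslow_no_ties(self):
        """On tie-free data the log-rank chi2 equals the Cox score test of
        the group indicator under Breslow tie handling."""
        rng = np.random.default_rng(20)
        t = rng.exponential(5.0, 70)  # continuous: no ties a.s.
        e = (rng.random(70) < 0.8).astype(int)
        g = (rng.random(70) < 0.5).astype(float)
        chi2, _ = rs.logrank_test(t, e, g)
        _, score, info = rs.cox_loglik(g[:, None], t, e, [0.0], ties="breslow")
        score_chi2 = score[0] ** 2 / info[0, 0]
        assert chi2 == pytest.approx(score_chi2, rel=1e-6)

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="2 non-empty groups"):
            rs.logrank_test([1.0, 2.0], [1, 1], [0, 0])
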