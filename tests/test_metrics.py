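"""Concordance / Somers' Dxy and time-dependent ROC under censoring."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import recursig as rs


def brute_force_concordance(scores, time, event):
    """Independent O(n^2) pair enumeration oracle (explicit double loop)."""
    conc = ties = usable = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                usable += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    ties += 1
    c = (conc + 0.5 * ties) / usable
    return c, usable


class TestSomersDxy:
    def test_perfect_risk_ordering(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, 30)
        res = rs.somers_dxy(-t, t, np.ones(30, int))
        assert res.c_index == 1.0 and res.dxy == -1.0

    def test_all_scores_tied(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10.0, 20)
        res = rs.somers_dxy(np.zeros(20), t, np.ones(20, int))
        assert res.c_index == 0.5 and res.dxy == 0.0

    def test_matches_brute_force_oracle_exactly(self, censored_outcome):
        time, event = censored_outcome
        rng = np.random.default_rng(2)
        scores = np.round(rng.standard_normal(len(time)), 1)  # induce ties
        res = rs.somers_dxy(scores, time, event)
        c_ref, usable_ref = brute_force_concordance(scores, time, event)
        assert res.c_index == c_ref
        assert res.n_pairs == usable_ref

    @given(st.integers(0, 10 ** 6))
    def test_identity_and_oracle_random_censored(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        time = rng.exponential(10.0, n)
        event = (rng.random(n) < 0.7).astype(int)
        if event.sum() == 0:
            event[0] = 1
        scores = np.round(rng.standard_normal(n), 1)
        res = rs.somers_dxy(scores, time, event)
        c_ref, _ = brute_force_concordance(scores, time, event)
        assert res.c_index == c_ref
        assert res.dxy == -2.0 * (res.c_index - 0.5)          # risk direction
        # time-direction form of the same identity (equal up to rounding)
        assert res.dxy == pytest.approx(2.0 * ((1.0 - res.c_index) - 0.5),
                                        abs=1e-12)

    def test_matches_scikit_survival(self, censored_outcome):
        from sksurv.metrics import concordance_index_censored
        time, event = censored_outcome
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(len(time))  # continuous: no ties
        res = rs.somers_dxy(scores, time, event)
        ref = concordance_index_censored(event.astype(bool), time, scores)[0]
        assert res.c_index == pytest.approx(ref, abs=1e-12)

    def test_no_usable_pairs_error(self):
        with pytest.raises(ValueError, match="usable"):
            rs.somers_dxy([1.0, 2.0], [5.0, 6.0], [0, 0])


class TestTimeROC:
    def test_perfect_marker_auc_one(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(50.0, 100)
        for q in (0.25, 0.5, 0.75):
            roc = rs.time_dependent_roc(-t, t, np.ones(100, int),
                                        np.quantile(t, q))
            assert roc.auc == 1.0

    def test_no_censoring_equals_mann_whitney(self):
        rng = np.random.default_rng(5)
        n = 120
        t = rng.exponential(50.0, n)
        x = 0.5 * -t + rng.standard_normal(n) * 10
        horizon = np.median(t)
        roc = rs.time_dependent_roc(x, t, np.ones(n, int), horizon)
        cases, controls = x[t <= horizon], x[t > horizon]
        mw = np.mean([(ci > cj) + 0.5 * (ci == cj)
                      for ci in cases for cj in controls])
        assert roc.auc == pytest.approx(mw, abs=0.01)

    def test_null_marker_mean_half(self):
        rng = np.random.default_rng(6)
        aucs = []
        for _ in range(60):
            n = 150
            T = rng.exponential(40.0, n)
            C = rng.exponential(90.0, n)
            t_obs = np.minimum(T, C)
            e = (T <= C).astype(int)
            x = rng.standard_normal(n)
            aucs.append(rs.time_dependent_roc(x, t_obs, e,
                                              np.median(t_obs)).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.04

    def test_negated_marker_flips_auc(self):
        rng = np.random.default_rng(7)
        n = 150
        T = rng.exponential(40.0, n)
        C = rng.exponential(90.0, n)
        t_obs, e = np.minimum(T, C), (T <= C).astype(int)
        x = -T + rng.standard_normal(n) * 20
        t0 = np.median(t_obs)
        a1 = rs.time_dependent_roc(x, t_obs, e, t0).auc
        a2 = rs.time_dependent_roc(-x, t_obs, e, t0).auc
        assert a1 + a2 == pytest.approx(1.0, abs=0.01)

    def test_sensitivity_specificity_bounds(self):
        rng = np.random.default_rng(8)
        n = 100
        T = rng.exponential(40.0, n)
        C = rng.exponential(60.0, n)
        t_obs, e = np.minimum(T, C), (T <= C).astype(int)
        roc = rs.time_dependent_roc(rng.standard_normal(n), t_obs, e,
                                    np.median(t_obs))
        assert ((roc.sensitivity >= 0) & (roc.sensitivity <= 1)).all()
        assert ((roc.specificity >= 0) & (roc.specificity <= 1)).all()
        assert 0.0 <= roc.auc <= 1.0

    def test_no_cases_error(self):
        t = np.array([10.0, 20.0, 30.0])
        with pytest.raises(ValueError, match="cases"):
            rs.time_dependent_roc([1.0, 2.0, 3.0], t, [1, 1, 1], 5.0)

    def test_no_controls_error(self):
        t = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="controls"):
            rs.time_dependent_roc([1.0, 2.0, 3.0], t, [1, 1, 1], 5.0)


class TestAUCCurve:
    def test_constant_marker_half_everywhere(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(40.0, 80)
        grid = np.quantile(t, [0.3, 0.5, 0.7])
        aucs = rs.auc_curve(np.ones(80), t, np.ones(80, int), grid)
        np.testing.assert_allclose(aucs, 0.5, atol=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        n = 100
        T = rng.exponential(40.0, n)
        C = rng.exponential(80.0, n)
        t_obs, e = np.minimum(T, C), (T <= C).astype(int)
        x = rng.standard_normal(n)
        grid = np.quantile(t_obs, [0.4, 0.6])
        a1 = rs.auc_curve(x, t_obs, e, grid)
        a2 = rs.auc_curve(np.exp(2.0 * x), t_obs, e, grid)
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_length_one_grid_reduces_to_single_roc(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(40.0, 60)
        x = rng.standard_normal(60)
        t0 = np.median(t)
        a = rs.auc_curve(x, t, np.ones(60, int), [t0])
        roc = rs.time_dependent_roc(x, t, np.ones(60, int), t0)
        assert a[0] == roc.auc

    def test_invalid_grid_points_yield_nan(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(40.0, 50)
        x = rng.standard_normal(50)
        grid = [np.median(t), t.max() + 1.0]   # second point has no controls
        a = rs.auc_curve(x, t, np.ones(50, int), grid)
        assert np.isfinite(a[0]) and np.isnan(a[1])
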