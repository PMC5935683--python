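"""Survival and categorical statistics against hand-computed and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oligosnf as og
from oligosnf.stats import (ConvergenceError, bh_adjust, chisq_test, cox_ph,
                            cox_score_test, fisher_exact, km_estimate,
                            logrank_test)


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        c = km_estimate([1, 2, 3], [1, 1, 1])
        assert c.survival_at(1) == pytest.approx(2 / 3)
        assert c.survival_at(2) == pytest.approx(1 / 3)
        assert c.survival_at(3) == pytest.approx(0.0)
        assert c.survival_at(0.5) == 1.0

    def test_all_censored_flat_curve(self):
        c = km_estimate([5, 6, 7], [0, 0, 0])
        assert c.survival_at(100) == 1.0
        assert c.median is None

    def test_six_subject_hand_computation(self):
        # times 1,2+,3,4,5+,6 -> S: 5/6, 5/6*3/4, *2/3, *0
        c = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        assert c.survival_at(1) == pytest.approx(5 / 6)
        assert c.survival_at(3) == pytest.approx(5 / 6 * 3 / 4)
        assert c.survival_at(4) == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert c.survival_at(6) == pytest.approx(0.0)
        assert c.median == 4.0

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 50).round(1)
        e = rng.integers(0, 2, 50)
        mine = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in (1.0, 5.0, 12.0):
            assert mine.survival_at(q) == pytest.approx(
                float(kmf.predict(q)), abs=1e-9
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    @given(st.lists(st.tuples(st.floats(0, 100), st.integers(0, 1)),
                    min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_survival_nonincreasing_in_unit_interval(self, data):
        t = [d[0] for d in data]
        e = [d[1] for d in data]
        c = km_estimate(t, e)
        assert np.all(np.diff(c.survival) <= 1e-12)
        assert np.all((c.survival >= 0) & (c.survival <= 1 + 1e-12))


def brute_force_logrank(times, events, groups):
    """Independent oracle: accumulate per-event-time group tables explicitly."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(sorted(np.unique(groups))))
    k = len(labels)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for ti in sorted(set(times[events == 1])):
        risk = times >= ti
        n = risk.sum()
        d = int(((times == ti) & (events == 1)).sum())
        for gi, g in enumerate(labels):
            ng = int((risk & (groups == g)).sum())
            dg = int(((times == ti) & (events == 1) & (groups == g)).sum())
            O[gi] += dg
            E[gi] += d * ng / n
            for hj, h in enumerate(labels):
                nh = int((risk & (groups == h)).sum())
                delta = 1.0 if g == h else 0.0
                if n > 1:
                    V[gi, hj] += (d * (n - d) / (n - 1)) * (ng / n) * (delta - nh / n)
    z = (O - E)[:-1]
    return float(z @ np.linalg.pinv(V[:-1, :-1]) @ z)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_far_shifted_group_strongly_significant(self, rng):
        t1 = rng.exponential(5, 20)
        t2 = t1 + 100.0
        res = logrank_test(np.r_[t1, t2], np.ones(40, int), np.r_[np.zeros(20), np.ones(20)])
        assert res.p_value < 0.001

    def test_three_group_matches_brute_force_oracle(self, rng):
        t = rng.exponential(8, 30).round(0)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        g = rng.integers(0, 3, 30)
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(brute_force_logrank(t, e, g), abs=1e-9)
        assert res.df == 2

    def test_matches_lifelines_multivariate(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(8, 40).round(1)
        e = rng.integers(0, 2, 40)
        e[:3] = 1
        g = rng.integers(0, 3, 40)
        res = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_subject_order_invariance(self, rng):
        t = rng.exponential(5, 25)
        e = rng.integers(0, 2, 25)
        e[0] = 1
        g = rng.integers(0, 2, 25)
        perm = rng.permutation(25)
        a = logrank_test(t, e, g)
        b = logrank_test(t[perm], e[perm], g[perm])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def test_logrank_type_one_error_calibrated():
    """Under the null (no group effect), the two-group log-rank rejects at
    the 5% level with frequency inside the 95% binomial band."""
    reps = 400
    rejections = 0
    for s in range(reps):
        r = np.random.default_rng(s)
        t = r.exponential(10, 100)
        c = r.uniform(0, 25, 100)
        e = (t <= c).astype(int)
        g = r.integers(0, 2, 100)
        rejections += logrank_test(np.minimum(t, c), e, g).p_value <= 0.05
    half_width = 1.96 * np.sqrt(0.05 * 0.95 / reps)
    assert 0.05 - half_width <= rejections / reps <= 0.05 + half_width


class TestCox:
    def test_null_covariate_hazard_ratio_near_one(self, rng):
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(10, n)
        cens = rng.uniform(0, 20, n)
        fit = cox_ph(x, np.minimum(t, cens), (t <= cens).astype(int))
        assert 0.85 <= float(np.exp(fit.coef[0])) <= 1.18

    def test_score_test_equals_two_group_logrank_untied(self, rng):
        n = 40
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10 / np.exp(0.7 * x))  # continuous: no ties
        e = np.ones(n, int)
        score = cox_score_test(x, t, e)
        lr = logrank_test(t, e, x.astype(int))
        assert score.statistic == pytest.approx(lr.statistic, rel=1e-9)

    def test_duplicated_dataset_same_coef_se_scaled(self, rng):
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(5 / np.exp(0.4 * x))
        e = np.ones(n, int)
        one = cox_ph(x, t, e, ties="breslow")
        two = cox_ph(np.r_[x, x], np.r_[t, t], np.r_[e, e], ties="breslow")
        assert two.coef[0] == pytest.approx(one.coef[0], abs=1e-6)
        assert two.se[0] == pytest.approx(one.se[0] / np.sqrt(2), rel=1e-3)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_lifelines(self, rng, ties):
        import pandas as pd
        from lifelines import CoxPHFitter

        n = 150
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1 / np.exp(0.5 * X[:, 0] - 0.3 * X[:, 1]))
        if ties == "efron":
            t = t.round(1) + 0.1  # force ties
        c = rng.uniform(0, 2.0, n)
        time = np.minimum(t, c)
        ev = (t <= c).astype(int)
        fit = cox_ph(X, time, ev, ties=ties)
        df = pd.DataFrame({"t": time, "e": ev, "x0": X[:, 0], "x1": X[:, 1]})
        ref = CoxPHFitter().fit(df, "t", "e")  # lifelines uses Efron
        tol = 1e-4 if ties == "efron" else 0.05
        np.testing.assert_allclose(fit.coef, ref.params_.values, atol=tol)
        if ties == "efron":
            np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=1e-4)

    def test_log_hr_recovery(self):
        """Data generated at log-HR 0.7 is recovered within 0.1 on average."""
        est = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.integers(0, 2, 1000).astype(float)
            t = r.exponential(1 / (0.05 * np.exp(0.7 * x)))
            c = r.uniform(0, 40, 1000)
            fit = cox_ph(x, np.minimum(t, c), (t <= c).astype(int))
            est.append(fit.coef[0])
        assert abs(np.mean(est) - 0.7) <= 0.1

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_ph(np.ones(10), np.arange(1, 11), np.ones(10, int))

    def test_perfect_separation_raises_convergence_error(self):
        # covariate perfectly orders survival: monotone likelihood
        t = np.arange(1.0, 21.0)
        x = (t > 10).astype(float)
        with pytest.raises(ConvergenceError):
            cox_ph(x, t, np.ones(20, int))


def brute_force_fisher(table):
    """Exhaustive enumeration over tables with the observed margins."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = comb(r1, x) * comb(r2, c1 - x) / denom
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


class TestFisherChisq:
    def test_diagonal_table_enumeration(self):
        res = fisher_exact([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252)

    def test_proportional_rows_no_association(self):
        res = fisher_exact([[4, 7], [4, 7]])
        assert res.p_value == pytest.approx(1.0)
        assert res.effect["odds_ratio"] == pytest.approx(1.0)

    def test_random_tables_match_enumeration_oracle(self, rng):
        for _ in range(25):
            tab = rng.integers(0, 9, size=(2, 2))
            res = fisher_exact(tab)
            assert res.p_value == pytest.approx(brute_force_fisher(tab), rel=1e-9)

    def test_zero_margin_p_one(self):
        assert fisher_exact([[0, 0], [3, 5]]).p_value == pytest.approx(1.0)

    def test_chisq_uniform_table_statistic_zero(self):
        res = chisq_test([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chisq_2x3_hand_arithmetic(self):
        tab = np.array([[10, 20, 30], [20, 20, 20]], float)
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        stat = ((tab - expected) ** 2 / expected).sum()
        res = chisq_test(tab)
        assert res.statistic == pytest.approx(stat)
        assert res.df == 2

    def test_chisq_permutation_invariance(self, rng):
        tab = rng.integers(1, 30, size=(3, 4))
        a = chisq_test(tab)
        b = chisq_test(tab[np.argsort(rng.random(3))][:, np.argsort(rng.random(4))])
        assert a.statistic == pytest.approx(b.statistic)

    def test_chisq_zero_expected_errors(self):
        with pytest.raises(ValueError, match="exact"):
            chisq_test([[0, 0], [1, 2]])


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_order_preserved(self):
        p = [0.04, 0.01, 0.03, 0.02]
        adj = bh_adjust(p)
        assert adj[1] == min(adj)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=80)
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
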