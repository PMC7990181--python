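import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from evorisk import survival_core as sc


def simulate(n, beta, seed=0, censor_rate=0.02, base_rate=0.02):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    eta = X @ np.asarray(beta)
    T = rng.exponential(1.0 / (base_rate * np.exp(eta)))
    C = rng.exponential(1.0 / censor_rate, size=n)
    return X, np.minimum(T, C), (T <= C).astype(int)


class TestCoxNLL:
    def test_closed_form_three_events(self):
        nll, _ = sc.cox_nll(np.zeros(1), np.zeros((3, 1)), [1.0, 2.0, 3.0], [1, 1, 1])
        assert nll == pytest.approx(np.log(3) + np.log(2))

    def test_closed_form_two_events(self):
        nll, _ = sc.cox_nll(np.zeros(2), np.zeros((2, 2)), [1.0, 2.0], [1, 1])
        assert nll == pytest.approx(np.log(2))

    def test_risk_set_closed_form_any_instance(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.exponential(size=20)
        delta = (rng.random(20) < 0.6).astype(int)
        delta[0] = 1
        nll, _ = sc.cox_nll(np.zeros(3), X, y, delta)
        expected = sum(np.log((y >= t).sum()) for t in y[delta == 1])
        assert nll == pytest.approx(expected)

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.exponential(size=5)
        delta = np.array([1, 0, 1, 1, 1])
        beta = rng.normal(size=3)
        _, grad = sc.cox_nll(beta, X, y, delta)
        for j in range(3):
            e = np.zeros(3)
            e[j] = 1e-6
            fd = (sc.cox_nll(beta + e, X, y, delta)[0] - sc.cox_nll(beta - e, X, y, delta)[0]) / 2e-6
            assert abs(fd - grad[j]) < 1e-6

    def test_all_censored_degenerate(self):
        with pytest.raises(sc.DegenerateLikelihoodError):
            sc.cox_nll(np.zeros(1), np.zeros((3, 1)), [1.0, 2.0, 3.0], [0, 0, 0])


class TestCoxFit:
    def test_matches_lifelines(self):
        X, y, delta = simulate(400, [0.8, -0.5], seed=1)
        model = sc.cox_fit(X, y, delta)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = y, delta
        cph = CoxPHFitter().fit(df, "T", "E")
        # lifelines uses hazard = h0 exp(+beta X); ours flips the sign
        np.testing.assert_allclose(model.beta, -cph.params_.values, atol=1e-4)

    def test_separation_flagged(self):
        X = np.array([[1.0], [1.0], [0.0], [0.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        delta = np.ones(4, dtype=int)
        model = sc.cox_fit(X, y, delta)
        assert ("separation" in model.flags) or ("non_convergence" in model.flags)
        assert not model.converged

    def test_lasso_shrinks_to_zero(self):
        X, y, delta = simulate(100, [0.5], seed=2)
        _, grad = sc.cox_nll(np.zeros(1), X, y, delta)
        model = sc.cox_fit(X, y, delta, l1_penalty=10 * abs(grad[0]))
        assert model.beta[0] == 0.0

    def test_lasso_zero_penalty_equals_newton(self):
        X, y, delta = simulate(150, [0.7, 0.2], seed=3)
        a = sc.cox_fit(X, y, delta)
        b = sc.cox_fit(X, y, delta, l1_penalty=1e-9)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-3)

    def test_risk_score_sign_convention(self):
        # a covariate with negative beta raises eta and lowers survival
        X, y, delta = simulate(500, [1.0], seed=4)
        model = sc.cox_fit(X, y, delta)
        assert model.beta[0] < 0  # fitted beta is negative for a hazardous covariate
        hi = model.risk_scores(np.array([[2.0]]))[0]
        lo = model.risk_scores(np.array([[-2.0]]))[0]
        assert hi > lo


class TestConcordance:
    def test_perfect_reversal(self):
        y = np.arange(1.0, 11.0)
        eta = -y  # highest risk dies first
        assert sc.concordance_index(eta, y, np.ones(10, dtype=int)) == 1.0

    def test_hand_example(self):
        assert sc.concordance_index([3.0, 1.0, 2.0], [1.0, 2.0, 3.0], [1, 1, 1]) == pytest.approx(2 / 3)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        n = 2000
        y = rng.exponential(size=n)
        delta = (rng.random(n) < 0.5).astype(int)
        eta = rng.normal(size=n)
        assert sc.concordance_index(eta, y, delta) == pytest.approx(0.5, abs=0.03)

    def test_ties_contribute_zero(self):
        # tied risk scores: numerator 0, denominator counts the pair
        assert sc.concordance_index([1.0, 1.0], [1.0, 2.0], [1, 1]) == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(3, 50))
            y = np.round(rng.exponential(size=n), 1)  # induce some ties
            delta = (rng.random(n) < 0.7).astype(int)
            eta = np.round(rng.normal(size=n), 1)
            if not ((delta == 1)[:, None] & (y[None, :] > y[:, None])).any():
                continue
            num = den = 0
            for i in range(n):
                for j in range(n):
                    if delta[i] == 1 and y[j] > y[i]:
                        den += 1
                        if eta[j] < eta[i]:
                            num += 1
            assert sc.concordance_index(eta, y, delta) == pytest.approx(num / den)

    def test_monotone_transform_invariance(self, rng):
        n = 100
        y = rng.exponential(size=n)
        delta = (rng.random(n) < 0.7).astype(int)
        eta = rng.normal(size=n)
        base = sc.concordance_index(eta, y, delta)
        assert sc.concordance_index(3 * eta + 7, y, delta) == base
        assert sc.concordance_index(np.exp(eta), y, delta) == base

    def test_no_comparable_pairs(self):
        with pytest.raises(sc.UndefinedMetricError):
            sc.concordance_index([1.0, 2.0], [5.0, 5.0], [1, 1])


class TestLogrank:
    def test_identical_groups(self):
        res = sc.logrank([1.0, 2.0, 3.0], [1, 0, 1], [1.0, 2.0, 3.0], [1, 0, 1])
        assert res.z2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = sc.logrank([1.0, 3.0], [1, 1], [2.0, 4.0], [1, 1])
        assert res.z2 == pytest.approx(8 / 13, abs=1e-9)

    def test_extreme_separation(self, rng):
        y_a = rng.uniform(0.1, 1.0, 100)
        y_b = rng.uniform(10.0, 20.0, 100)
        ones = np.ones(100, dtype=int)
        assert sc.logrank(y_a, ones, y_b, ones).p < 1e-3

    def test_label_swap_invariance(self, rng):
        y_a, y_b = rng.exponential(size=30), rng.exponential(size=40)
        d_a = (rng.random(30) < 0.7).astype(int)
        d_b = (rng.random(40) < 0.7).astype(int)
        d_a[0] = d_b[0] = 1
        r1 = sc.logrank(y_a, d_a, y_b, d_b)
        r2 = sc.logrank(y_b, d_b, y_a, d_a)
        assert r1.z2 == pytest.approx(r2.z2)

    def test_matches_lifelines(self, rng):
        y_a, y_b = rng.exponential(2.0, 50), rng.exponential(1.0, 60)
        d_a = (rng.random(50) < 0.8).astype(int)
        d_b = (rng.random(60) < 0.8).astype(int)
        ours = sc.logrank(y_a, d_a, y_b, d_b)
        theirs = logrank_test(y_a, y_b, event_observed_A=d_a, event_observed_B=d_b)
        assert ours.z2 == pytest.approx(theirs.test_statistic, rel=1e-6)
        assert ours.p == pytest.approx(theirs.p_value, rel=1e-6)

    def test_no_events_undefined(self):
        with pytest.raises(sc.UndefinedMetricError):
            sc.logrank([1.0], [0], [2.0], [0])


class TestKaplanMeier:
    def test_all_censored_flat(self):
        km = sc.km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert len(km.times) == 0
        assert km.at(100.0) == 1.0

    def test_product_limit_hand_example(self):
        km = sc.km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.at(1.0) == pytest.approx(2 / 3)
        assert km.at(3.0) == pytest.approx(0.0)

    def test_all_events_closed_form(self):
        n = 8
        km = sc.km_curve(np.arange(1.0, n + 1), np.ones(n, dtype=int))
        for k in range(1, n + 1):
            assert km.survival[k - 1] == pytest.approx((n - k) / n)

    def test_matches_lifelines(self, rng):
        y = rng.exponential(size=80)
        d = (rng.random(80) < 0.6).astype(int)
        d[0] = 1
        km = sc.km_curve(y, d)
        kmf = KaplanMeierFitter().fit(y, d)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(kmf.predict(t), abs=1e-9)

    def test_curve_monotone_in_unit_interval(self, rng):
        y = rng.exponential(size=50)
        d = (rng.random(50) < 0.7).astype(int)
        d[0] = 1
        km = sc.km_curve(y, d)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()

    def test_merged_curve_between_groups(self, rng):
        y_a = rng.exponential(1.0, 60)
        y_b = rng.exponential(3.0, 60)
        ones = np.ones(60, dtype=int)
        km_a = sc.km_curve(y_a, ones)
        km_b = sc.km_curve(y_b, ones)
        km_m = sc.km_curve(np.concatenate([y_a, y_b]), np.ones(120, dtype=int))
        for t in np.quantile(np.concatenate([y_a, y_b]), [0.2, 0.5, 0.8]):
            lo, hi = sorted((km_a.at(t), km_b.at(t)))
            assert lo - 1e-9 <= km_m.at(t) <= hi + 1e-9
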