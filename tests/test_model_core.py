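"""Conditional-mean recursion, conditional likelihood, and CML fitting."""

import numpy as np
import pytest

from rbsarmax import distribution as rbs
from rbsarmax.data import SeriesData
from rbsarmax.model import Gamma, ModelOrder, RBSARMAX

from .conftest import simulate_feasible


def unrolled_alpha(y, x, delta, eta, beta, phi, theta):
    """Hand-unrolled recursion for p=q=r=1, written independently of the
    package's kernel: alpha_t = eta + x_t b + phi (y_{t-1} - x_{t-1} b)
    + theta (y_{t-1} - alpha_{t-1}), innovations 0 before conditioning."""
    n = len(y)
    alpha = [np.nan] * n
    for t in range(1, n):
        a = eta + beta * x[t] + phi * (y[t - 1] - beta * x[t - 1])
        if t - 1 >= 1:  # innovation defined only after the conditioning head
            a += theta * (y[t - 1] - alpha[t - 1])
        alpha[t] = a
    return np.array(alpha)


class TestLinearPredictor:
    def test_static_regression_case(self):
        # p = q = 0 collapses to alpha_t = eta + x_t' beta
        rng = np.random.default_rng(0)
        X = rng.random((20, 2))
        y = np.full(20, 2.0)
        model = RBSARMAX(y, exog=X, order=(0, 0))
        params = np.array([8.0, 1.0, 0.5, -0.25])
        alpha, mu = model.linear_predictor(params)
        np.testing.assert_allclose(alpha, 1.0 + X @ [0.5, -0.25])
        np.testing.assert_allclose(mu, alpha)

    def test_pure_ar_arithmetic(self):
        # p=1, q=0, r=0: alpha_t = eta + phi * y_{t-1}
        y = np.array([2.0, 3.0, 1.5])
        model = RBSARMAX(y, order=(1, 0))
        alpha, _ = model.linear_predictor(np.array([8.0, 1.0, 0.5]))
        assert np.isnan(alpha[0])
        assert alpha[1] == pytest.approx(1.0 + 0.5 * 2.0)
        assert alpha[2] == pytest.approx(1.0 + 0.5 * 3.0)

    def test_matches_hand_unrolled_oracle(self):
        y = np.array([1.2, 0.8, 2.5, 1.9, 3.1, 1.1])
        x = np.array([0.3, 0.9, 0.1, 0.5, 0.7, 0.2])
        g = (8.0, 1.0, 0.7, 0.7, 0.5)  # delta, eta, beta, phi, theta
        model = RBSARMAX(y, exog=x[:, None], order=(1, 1))
        alpha, _ = model.linear_predictor(np.array(g))
        expected = unrolled_alpha(y, x, *g)
        np.testing.assert_allclose(alpha[1:], expected[1:], rtol=1e-12)
        assert np.isnan(alpha[0]) and np.isnan(expected[0])

    def test_length_mismatch_rejected(self):
        model = RBSARMAX(np.ones(10) * 2, order=(1, 1))
        with pytest.raises(ValueError):
            model.linear_predictor(np.array([8.0, 1.0]))  # too short

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            RBSARMAX(np.array([1.0, 2.0]), order=(2, 0))


class TestConditionalLoglik:
    def test_equals_sum_of_logpdfs(self, fitted_111):
        data, res = fitted_111
        model = res.model
        delta = res.params["delta"]
        terms = [
            rbs.logpdf(y, m, delta)
            for y, m in zip(model.y[model.m :], res.mu[model.m :])
        ]
        assert res.llf == pytest.approx(sum(terms), rel=1e-10)

    def test_single_point_static_density(self):
        # one observation at its own mean: contribution is logpdf(mu; mu, delta)
        y = np.array([2.0])
        model = RBSARMAX(y, order=(0, 0))
        ll = model.loglike(np.array([8.0, 2.0]))
        assert ll == pytest.approx(rbs.logpdf(2.0, 2.0, 8.0), rel=1e-12)

    def test_truth_beats_perturbation(self, mild_gamma):
        wins = 0
        for s in range(20):
            data = simulate_feasible(mild_gamma, 200, seed=300 + s)
            model = RBSARMAX(data, order=(1, 1))
            g = mild_gamma.to_array()
            g_pert = g.copy()
            g_pert[1] += 0.5
            wins += model.loglike(g) > model.loglike(g_pert)
        assert wins >= 18

    def test_scale_equivariance(self, mild_gamma):
        # y -> c y with eta, beta scaled shifts loglik by -(n-m) log c
        data = simulate_feasible(mild_gamma, 150, seed=77)
        c = 3.7
        g = mild_gamma.to_array()
        g_scaled = g.copy()
        g_scaled[1] *= c
        g_scaled[2] *= c
        m1 = RBSARMAX(data.y, exog=data.X, order=(1, 1))
        m2 = RBSARMAX(c * data.y, exog=data.X, order=(1, 1))
        n_used = data.n - 1
        assert m2.loglike(g_scaled) == pytest.approx(
            m1.loglike(g) - n_used * np.log(c), rel=1e-10
        )

    def test_infeasible_mean_penalized(self):
        y = np.array([1.0, 0.1, 5.0, 0.1, 5.0])
        model = RBSARMAX(y, order=(1, 1))
        # wildly negative intercept forces mu_t <= 0
        assert model.loglike(np.array([8.0, -50.0, 0.9, 0.9])) <= -1e10


class TestFit:
    def test_refit_from_optimum_is_stationary(self, fitted_111):
        data, res = fitted_111
        res2 = RBSARMAX(data, order=(1, 1)).fit(start_params=res._params)
        assert abs(res2.llf - res.llf) < 1e-6

    def test_static_large_sample_recovery(self):
        # p=q=0, r=1: beta_hat within 3 standard errors of truth at n=5000
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.random(n)
        mu = 1.0 + 0.7 * x
        y = np.array([rbs.rvs(m, 8.0, 1, rng)[0] for m in mu])
        res = RBSARMAX(y, exog=x[:, None], order=(0, 0)).fit()
        assert res.converged
        assert abs(res.params["x1"] - 0.7) < 3 * res.bse["x1"]
        assert abs(res.params["const"] - 1.0) < 3 * res.bse["const"]

    def test_matches_independent_iid_fit(self):
        """With p=q=0 the model is an independent-observation RBS regression;
        an independent scipy fit of the same likelihood must agree."""
        from scipy import optimize, stats

        rng = np.random.default_rng(9)
        n = 400
        x = rng.random(n)
        y = np.array([rbs.rvs(1.0 + 0.7 * xi, 8.0, 1, rng)[0] for xi in x])
        res = RBSARMAX(y, exog=x[:, None], order=(0, 0)).fit()

        def negll(v):
            log_d, eta, b = v
            d = np.exp(log_d)
            mu = eta + b * x
            if np.any(mu <= 0):
                return 1e12
            lam = d * mu / (d + 1.0)
            alph = np.sqrt(2.0 / d)
            return -np.sum(stats.fatiguelife.logpdf(y, alph, scale=lam))

        ind = optimize.minimize(negll, [np.log(8.0), 1.0, 0.7], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        assert res.llf == pytest.approx(-ind.fun, abs=1e-5)
        np.testing.assert_allclose(
            res._params, np.concatenate(([np.exp(ind.x[0])], ind.x[1:])), rtol=1e-3
        )

    def test_default_init_rules(self):
        rng = np.random.default_rng(3)
        X = rng.random((50, 1))
        y = np.exp(rng.normal(1.0, 0.2, 50))
        model = RBSARMAX(y, exog=X, order=(2, 1))
        start = model.start_params()
        np.testing.assert_array_equal(start[-3:], 0.0)  # phi and theta start at 0
        assert start[0] >= 0.5
        # constant response, no regressors: intercept starts at the constant
        m2 = RBSARMAX(np.full(30, 4.2), order=(1, 0))
        assert m2.start_params()[1] == pytest.approx(4.2)

    def test_dynamic_parameter_recovery(self, mild_gamma):
        data = simulate_feasible(mild_gamma, 2000, seed=404)
        res = RBSARMAX(data, order=(1, 1)).fit()
        assert res.converged
        g = mild_gamma
        assert res.params["delta"] == pytest.approx(g.delta, rel=0.15)
        assert res.params["ar.L1"] == pytest.approx(g.phi[0], abs=0.12)
        assert res.params["ma.L1"] == pytest.approx(g.theta[0], abs=0.12)

    def test_time_index_irrelevant(self, fitted_111):
        # likelihood depends only on values and their order
        data, res = fitted_111
        again = RBSARMAX(SeriesData(data.y.copy(), data.X.copy()), order=(1, 1))
        assert again.loglike(res._params) == pytest.approx(res.llf, rel=1e-12)


class TestForecast:
    def test_static_forecast_is_regression_mean(self):
        rng = np.random.default_rng(1)
        x = rng.random(100)
        y = np.array([rbs.rvs(1.0 + 0.7 * xi, 25.0, 1, rng)[0] for xi in x])
        res = RBSARMAX(y, exog=x[:, None], order=(0, 0)).fit()
        xf = np.array([[0.2], [0.9]])
        fc = res.forecast(2, exog_future=xf)
        np.testing.assert_allclose(
            fc, res.params["const"] + res.params["x1"] * xf[:, 0], rtol=1e-12
        )

    def test_one_step_forecast_continues_recursion(self, fitted_111):
        data, res = fitted_111
        fc = res.forecast(1, exog_future=np.array([[0.5]]))
        # recompute by extending the series with a dummy and reading alpha
        assert fc.shape == (1,) and fc[0] > 0

    def test_ar_forecast_converges_to_fixed_point(self):
        rng = np.random.default_rng(11)
        # persistent AR(1), no regressors
        y = [2.0]
        for _ in range(800):
            mu = 1.0 + 0.6 * y[-1]
            y.append(rbs.rvs(mu, 50.0, 1, rng)[0])
        res = RBSARMAX(np.array(y[1:]), order=(1, 0)).fit()
        eta, phi = res.params["const"], res.params["ar.L1"]
        fixed_point = eta / (1.0 - phi)
        fc = res.forecast(60)
        gaps = np.abs(fc - fixed_point)
        assert np.all(np.diff(gaps) <= 1e-12)  # monotone approach
        assert gaps[-1] < 1e-3 * max(1.0, abs(fixed_point))


class TestGammaContainer:
    def test_round_trip(self):
        g = Gamma(delta=8.0, eta=1.0, beta=[0.7], phi=[0.5], theta=[0.3])
        back = Gamma.from_array(g.to_array(), ModelOrder(1, 1, 1))
        assert back == g

    def test_order_mismatch(self):
        with pytest.raises(ValueError):
            Gamma.from_array(np.ones(3), ModelOrder(1, 1, 1))

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            Gamma(delta=-1.0, eta=0.0)
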