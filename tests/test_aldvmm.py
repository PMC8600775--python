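"""Censored normal mixture: likelihood, estimation, prediction, simulation."""

import numpy as np
import pytest
from scipy import integrate, stats

from qlqmap.aldvmm import (AldvmmParams, AldvmmSpec, EstimationError,
                           FitOptions, component_density,
                           component_membership, fit, loglik, loglik_obs,
                           predict_mean, score_obs, simulate)
from qlqmap.tariff import FLOOR, GAP_LOWER, InfeasibleUtilityError

SPEC2 = AldvmmSpec(2, ("const", "x"), ("const", "z"))
SPEC1 = AldvmmSpec(1, ("const", "x"), ("const",))


def _sim_data(n=400, seed=5, params=None, spec=SPEC2):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.uniform(0, 1, n)])
    Z = np.column_stack([np.ones(n), rng.uniform(0, 1, n)]) \
        if len(spec.membership_covariates) == 2 else np.ones((n, 1))
    if params is None:
        params = AldvmmParams(beta=[[0.25, 0.15], [0.75, 0.1]],
                              lnsigma=np.log([0.15, 0.28]),
                              gamma=[[0.3, -0.4]])
    draws, _ = simulate(params, X, Z, spec, n_draws=1, seed=seed + 1)
    return draws[:, 0], X, Z, params


class TestMembership:
    def test_single_component_is_certain(self):
        assert component_membership(np.ones((4, 1)), np.zeros((0, 1))
                                    ).tolist() == [[1.0]] * 4

    def test_zero_coefficients_split_evenly(self):
        Z = np.column_stack([np.ones(3), np.linspace(0, 1, 3)])
        pi = component_membership(Z, np.zeros((1, 2)))
        np.testing.assert_allclose(pi, 0.5)

    def test_softmax_arithmetic_three_components(self):
        # linear predictors (ln 2, ln 1) against reference 0
        gamma = np.array([[np.log(2.0)], [0.0]])
        pi = component_membership(np.ones((1, 1)), gamma)
        np.testing.assert_allclose(pi[0], [0.5, 0.25, 0.25], atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        Z = np.column_stack([np.ones(50), rng.normal(size=50)])
        pi = component_membership(Z, rng.normal(size=(3, 2)))
        np.testing.assert_allclose(pi.sum(axis=1), 1.0, atol=1e-14)
        assert (pi > 0).all()


class TestComponentDensity:
    def test_interior_density_matches_normal_pdf(self):
        # phi(0)/sigma with sigma = 0.2
        expect = stats.norm.pdf(0.5, loc=0.5, scale=0.2)
        assert component_density(0.5, 0.5, 0.2, SPEC2) == pytest.approx(
            expect, rel=1e-12)
        assert expect == pytest.approx(1.99471, abs=5e-6)

    def test_full_health_mass_at_gap_edge_mean_is_half(self):
        assert component_density(1.0, GAP_LOWER, 0.3, SPEC2) == pytest.approx(0.5)

    def test_floor_mass_at_floor_mean_is_half(self):
        assert component_density(FLOOR, FLOOR, 0.1, SPEC2) == pytest.approx(0.5)

    def test_gap_value_rejected(self):
        with pytest.raises(InfeasibleUtilityError):
            component_density(0.95, 0.5, 0.2, SPEC2)
        with pytest.raises(InfeasibleUtilityError):
            component_density(1.2, 0.5, 0.2, SPEC2)

    @pytest.mark.parametrize("mu, sigma", [(0.5, 0.2), (0.9, 0.3), (-0.3, 0.5)])
    def test_density_integrates_to_one_over_outcome_space(self, mu, sigma):
        interior, _ = integrate.quad(
            lambda y: component_density(y, mu, sigma, SPEC2), FLOOR, GAP_LOWER)
        mass_one = component_density(1.0, mu, sigma, SPEC2)
        mass_floor = component_density(FLOOR, mu, sigma, SPEC2)
        assert interior + mass_one + mass_floor == pytest.approx(1.0, abs=1e-8)


def _oracle_censored_loglik(y, mu, sigma):
    """Independent single-component censored-normal log-likelihood."""
    out = np.empty_like(y)
    at_one = y >= 1.0 - 1e-9
    at_floor = y <= FLOOR + 1e-9
    interior = ~(at_one | at_floor)
    out[at_one] = stats.norm.logsf(GAP_LOWER, loc=mu[at_one], scale=sigma)
    out[at_floor] = stats.norm.logcdf(FLOOR, loc=mu[at_floor], scale=sigma)
    out[interior] = stats.norm.logpdf(y[interior], loc=mu[interior],
                                      scale=sigma)
    return out.sum()


class TestLoglik:
    def test_single_component_matches_censored_normal_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = 60
            X = np.column_stack([np.ones(n), rng.uniform(0, 1, n)])
            beta = rng.normal([0.5, 0.1], 0.3)
            sigma = rng.uniform(0.08, 0.5)
            params = AldvmmParams(beta=[beta], lnsigma=[np.log(sigma)],
                                  gamma=np.zeros((0, 1)))
            draws, _ = simulate(params, X, np.ones((n, 1)), SPEC1,
                                n_draws=1, seed=int(rng.integers(1e6)))
            y = draws[:, 0]
            ours = loglik(params, y, X, np.ones((n, 1)), SPEC1)
            oracle = _oracle_censored_loglik(y, X @ beta, sigma)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_duplicating_rows_doubles_loglik(self):
        y, X, Z, params = _sim_data(100)
        single = loglik(params, y, X, Z, SPEC2)
        double = loglik(params, np.tile(y, 2), np.tile(X, (2, 1)),
                        np.tile(Z, (2, 1)), SPEC2)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_analytic_score_matches_numeric_gradient(self):
        y, X, Z, params = _sim_data(150)
        theta = params.pack()
        analytic = score_obs(params, y, X, Z, SPEC2).sum(axis=0)
        numeric = np.empty_like(theta)
        for j in range(len(theta)):
            eps = 1e-6
            up, dn = theta.copy(), theta.copy()
            up[j] += eps
            dn[j] -= eps
            numeric[j] = (
                loglik(AldvmmParams.unpack(up, 2, 2, 2), y, X, Z, SPEC2)
                - loglik(AldvmmParams.unpack(dn, 2, 2, 2), y, X, Z, SPEC2)
            ) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, atol=1e-5)


class TestPredictMean:
    def test_limit_all_mass_at_full_health(self):
        params = AldvmmParams(beta=[[50.0, 0.0]], lnsigma=[np.log(0.2)],
                              gamma=np.zeros((0, 1)))
        pred = predict_mean(params, [[1.0, 0.0]], [[1.0]], SPEC1)
        assert pred[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_monte_carlo(self):
        # manual MC: draw latent normals, censor by hand
        mu, sigma = 0.3, 0.2
        params = AldvmmParams(beta=[[mu, 0.0]], lnsigma=[np.log(sigma)],
                              gamma=np.zeros((0, 1)))
        pred = predict_mean(params, [[1.0, 0.0]], [[1.0]], SPEC1)[0]
        rng = np.random.default_rng(77)
        lat = rng.normal(mu, sigma, 400_000)
        mc = np.where(lat >= GAP_LOWER, 1.0, np.maximum(lat, FLOOR))
        se = mc.std() / np.sqrt(len(mc))
        assert abs(pred - mc.mean()) < 3 * se

    def test_weighted_component_means_reproduce_published_mean(self):
        # degenerate components pinned at the published component means,
        # mixed with the published probabilities
        probs = np.array([0.2213, 0.3213, 0.1686, 0.2888])
        means = np.array([0.6720, 0.8238, 0.4740, 0.7781])
        spec = AldvmmSpec(4, ("const",), ("const",))
        params = AldvmmParams(
            beta=means[:, None], lnsigma=np.log([1e-7] * 4),
            gamma=np.log(probs[:3] / probs[3])[:, None])
        pred = predict_mean(params, [[1.0]], [[1.0]], spec)
        assert round(pred[0], 4) == pytest.approx(0.7180)

    def test_always_inside_feasible_hull(self):
        y, X, Z, params = _sim_data(200)
        pred = predict_mean(params, X, Z, SPEC2)
        assert (pred >= FLOOR).all() and (pred <= 1.0).all()


class TestSimulate:
    def test_draws_respect_the_gap(self):
        y, X, Z, params = _sim_data(300)
        draws, labels = simulate(params, X, Z, SPEC2, n_draws=50, seed=3)
        flat = draws.ravel()
        assert ((flat <= GAP_LOWER + 1e-12) | (flat == 1.0)).all()
        assert flat.min() >= FLOOR
        assert labels.shape == draws.shape

    def test_degenerate_scale_returns_the_mean(self):
        params = AldvmmParams(beta=[[0.5, 0.0]], lnsigma=[np.log(1e-10)],
                              gamma=np.zeros((0, 1)))
        draws, _ = simulate(params, [[1.0, 0.0]], [[1.0]], SPEC1,
                            n_draws=100, seed=0)
        np.testing.assert_allclose(draws, 0.5, atol=1e-8)

    def test_empirical_mean_agrees_with_analytic(self):
        y, X, Z, params = _sim_data(50)
        draws, _ = simulate(params, X, Z, SPEC2, n_draws=4000, seed=11)
        analytic = predict_mean(params, X, Z, SPEC2)
        emp = draws.mean(axis=1)
        se = draws.std(axis=1) / np.sqrt(draws.shape[1])
        assert (np.abs(emp - analytic) < 4 * se + 1e-4).all()

    def test_reproducible_under_seed(self):
        y, X, Z, params = _sim_data(40)
        d1, l1 = simulate(params, X, Z, SPEC2, n_draws=20, seed=9)
        d2, l2 = simulate(params, X, Z, SPEC2, n_draws=20, seed=9)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_array_equal(l1, l2)


class TestFit:
    def test_single_component_parameter_recovery(self):
        rng = np.random.default_rng(4)
        n = 4000
        X = np.column_stack([np.ones(n), rng.uniform(0, 1, n)])
        truth = AldvmmParams(beta=[[0.45, 0.3]], lnsigma=[np.log(0.22)],
                             gamma=np.zeros((0, 1)))
        draws, _ = simulate(truth, X, np.ones((n, 1)), SPEC1, 1, seed=8)
        y = draws[:, 0]
        est, report = fit(y, X, np.ones((n, 1)), SPEC1,
                          options=FitOptions(n_restarts=3, seed=0))
        assert report.converged
        np.testing.assert_allclose(est.beta, truth.beta, atol=0.05)
        assert est.sigma[0] == pytest.approx(0.22, abs=0.02)

    def test_fitted_loglik_dominates_truth(self):
        y, X, Z, truth = _sim_data(600, seed=21)
        est, report = fit(y, X, Z, SPEC2,
                          options=FitOptions(n_restarts=4, seed=0))
        assert report.loglik >= loglik(truth, y, X, Z, SPEC2) - 1e-6

    def test_more_components_never_fit_worse(self):
        y, X, Z, _ = _sim_data(500, seed=33)
        _, rep1 = fit(y, X, np.ones((len(y), 1)), SPEC1,
                      options=FitOptions(n_restarts=3, seed=0))
        spec2 = AldvmmSpec(2, ("const", "x"), ("const",))
        _, rep2 = fit(y, X, np.ones((len(y), 1)), spec2,
                      options=FitOptions(n_restarts=6, seed=0))
        assert rep2.loglik >= rep1.loglik - 1e-4

    def test_components_relabelled_by_average_membership(self):
        y, X, Z, _ = _sim_data(800, seed=44)
        est, _ = fit(y, X, Z, SPEC2, options=FitOptions(n_restarts=4, seed=0))
        pi = component_membership(Z, est.gamma).mean(axis=0)
        assert (np.diff(pi) <= 1e-10).all()

    def test_information_criteria_identities(self):
        y, X, Z, _ = _sim_data(300, seed=55)
        est, rep = fit(y, X, Z, SPEC2, options=FitOptions(n_restarts=2, seed=0))
        assert rep.aic == pytest.approx(2 * rep.n_params - 2 * rep.loglik)
        assert rep.bic == pytest.approx(
            rep.n_params * np.log(rep.n_obs) - 2 * rep.loglik)
        assert rep.vcov_robust.shape == (SPEC2.n_params, SPEC2.n_params)
        assert np.isfinite(np.diag(rep.vcov_robust)).all()

    def test_infeasible_outcome_rejected(self):
        y, X, Z, _ = _sim_data(100)
        y[0] = 0.95  # inside the gap
        with pytest.raises(InfeasibleUtilityError):
            fit(y, X, Z, SPEC2, options=FitOptions(n_restarts=1, seed=0))

    def test_too_few_observations_rejected(self):
        y, X, Z, _ = _sim_data(8)
        with pytest.raises(EstimationError):
            fit(y, X, Z, SPEC2, options=FitOptions(n_restarts=1, seed=0))
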