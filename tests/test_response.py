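"""Ordered-probit response mapping: stage 1 fits and stage 2 expectations."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtri

from qlqmap.response import (OrderedProbitDim, OrderedProbitSystem,
                             estimate_latent_correlation, expected_utility,
                             fit_ordered_probits, ghk_rectangle_probability,
                             level_probabilities, state_probabilities)
from qlqmap.tariff import DIMENSIONS, UK_TTO, enumerate_states, score_state


def _flat_system(coef=0.0, cut1=None, cut2=None, corr=None):
    cut1 = ndtri(1 / 3) if cut1 is None else cut1
    cut2 = ndtri(2 / 3) if cut2 is None else cut2
    dims = {d: OrderedProbitDim(d, {"x": coef}, cut1, cut2)
            for d in DIMENSIONS}
    return OrderedProbitSystem(dims=dims, covariates=("x",), corr=corr)


def _simulate_responses(system, X, seed=0):
    rng = np.random.default_rng(seed)
    idx = X @ system.coef_matrix().T
    corr = system.corr if system.corr is not None else np.eye(5)
    eps = rng.standard_normal((len(X), 5)) @ np.linalg.cholesky(corr).T
    lat = idx + eps
    cuts = system.cutpoints()
    levels = 1 + (lat > cuts[:, 0]).astype(int) + (lat > cuts[:, 1]).astype(int)
    return pd.DataFrame(levels, columns=list(DIMENSIONS))


def test_zero_coefficients_tercile_cutpoints_give_equal_levels():
    system = _flat_system()
    probs = level_probabilities(system, np.array([[0.7]]))
    np.testing.assert_allclose(probs[0], 1 / 3, atol=1e-12)


def test_level_probabilities_sum_to_one():
    rng = np.random.default_rng(1)
    system = _flat_system(coef=-1.4, cut1=-1.0, cut2=0.8)
    probs = level_probabilities(system, rng.uniform(0, 1, (40, 1)))
    np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-14)


def test_parameter_recovery_on_simulated_ordered_probit_data():
    n = 5000
    rng = np.random.default_rng(7)
    X = rng.uniform(0, 1, (n, 1))
    truth = _flat_system(coef=-2.0, cut1=-1.8, cut2=-0.3)
    frame = _simulate_responses(truth, X, seed=8)
    frame["x"] = X[:, 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = fit_ordered_probits(frame, ("x",))
    for d in DIMENSIONS:
        assert est.dims[d].coef["x"] == pytest.approx(-2.0, abs=0.25)
        assert est.dims[d].cut1 == pytest.approx(-1.8, abs=0.15)
        assert est.dims[d].cut2 == pytest.approx(-0.3, abs=0.15)


def test_unobserved_level3_pins_second_cutpoint():
    n = 600
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 1, (n, 1))
    # cut2 far out: level 3 never observed for any dimension
    truth = _flat_system(coef=-1.0, cut1=0.2, cut2=9.0)
    frame = _simulate_responses(truth, X, seed=4)
    assert (frame[list(DIMENSIONS)] < 3).all().all()
    frame["x"] = X[:, 0]
    with pytest.warns(UserWarning, match="pinned"):
        est = fit_ordered_probits(frame, ("x",))
    for d in DIMENSIONS:
        assert est.dims[d].pinned
        assert est.dims[d].cut2 == pytest.approx(6.0)
        # the identified part still recovers
        assert est.dims[d].coef["x"] == pytest.approx(-1.0, abs=0.4)


def test_degenerate_marginals_put_all_mass_on_full_health():
    system = _flat_system(coef=0.0, cut1=8.0, cut2=9.0)  # P(level1) ~ 1
    probs = state_probabilities(system, np.array([0.0]))
    assert probs[0] == pytest.approx(1.0, abs=1e-9)
    assert probs[1:].max() < 1e-9
    eu = expected_utility(system, np.array([[0.0]]))
    assert eu[0] == pytest.approx(1.0, abs=1e-9)


def test_state_probabilities_sum_to_one_and_expected_utility_bounds():
    system = _flat_system(coef=-1.2, cut1=-1.5, cut2=0.4)
    probs = state_probabilities(system, np.array([0.5]))
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    eu = expected_utility(system, np.array([[0.5]]))
    assert -0.594 <= eu[0] <= 1.0


def test_uniform_state_probabilities_give_mean_tariff():
    # brute-force enumeration oracle
    mean_tariff = np.mean([score_state(s) for s in enumerate_states()])
    system = _flat_system()  # equal level probs -> uniform over 243 states
    eu = expected_utility(system, np.array([[0.0]]))
    assert eu[0] == pytest.approx(mean_tariff, abs=1e-12)


def test_all_mass_on_pits_state_scores_floor():
    system = _flat_system(coef=0.0, cut1=-9.0, cut2=-8.0)  # P(level3) ~ 1
    eu = expected_utility(system, np.array([[0.0]]))
    assert eu[0] == pytest.approx(-0.594, abs=1e-9)


def test_ghk_identity_correlation_reproduces_product_rule():
    system = _flat_system(coef=-1.0, cut1=-1.2, cut2=0.5)
    x = np.array([0.4])
    product = state_probabilities(system, x, method="product")
    ghk = state_probabilities(system, x, method="ghk", n_draws=2000, seed=2)
    assert np.abs(product - ghk).max() < 0.01
    assert ghk.sum() == pytest.approx(1.0)


def test_ghk_against_scipy_mvn_rectangles():
    corr = np.full((5, 5), 0.45)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(6)
    u = rng.random((4000, 5))
    mvn = stats.multivariate_normal(mean=np.zeros(5), cov=corr)
    for lower, upper in [
        (np.full(5, -np.inf), np.zeros(5)),
        (np.full(5, -1.0), np.full(5, 0.5)),
        (np.array([-np.inf, -1, 0, -2, -0.5]), np.array([0.0, 1, 2, 0, 0.5])),
    ]:
        est = ghk_rectangle_probability(lower, upper, chol, u)
        # inclusion-exclusion via scipy's mvn cdf over the 2^5 corners
        oracle = 0.0
        for mask in range(32):
            corner = np.where([(mask >> d) & 1 for d in range(5)],
                              upper, lower)
            sign = (-1) ** (5 - bin(mask).count("1"))
            finite = np.clip(corner, -35, 35)
            oracle += sign * float(mvn.cdf(finite))
        assert est == pytest.approx(oracle, abs=0.02)


def test_latent_correlation_estimated_from_pairwise_association():
    n = 3000
    rng = np.random.default_rng(9)
    X = rng.uniform(0, 1, (n, 1))
    corr = np.full((5, 5), 0.45)
    np.fill_diagonal(corr, 1.0)
    truth = _flat_system(coef=-1.0, cut1=-1.5, cut2=0.3, corr=corr)
    frame = _simulate_responses(truth, X, seed=10)
    frame["x"] = X[:, 0]
    # estimate with the true marginals plugged in
    marginal = _flat_system(coef=-1.0, cut1=-1.5, cut2=0.3)
    est = estimate_latent_correlation(marginal, frame, max_rows=1200, seed=1)
    off = est[np.triu_indices(5, 1)]
    assert np.all(np.abs(off - 0.45) < 0.15)
    assert np.linalg.eigvalsh(est).min() > 0
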