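"""Adjusted limited dependent variable mixture model (ALDVMM).

The model is a finite mixture of K normal components, each censored to
the feasible EQ-5D-3L utility space: a point mass at full health (1),
an infeasible gap (0.883, 1), a continuous interior [-0.594, 0.883] and
a point mass at the floor -0.594.  Component membership probabilities
follow a multinomial logit in a second covariate block (global health
and its square), with component K as the reference category.

For observation i with component mean ``mu_ic = x_i @ beta_c`` and scale
``sigma_c``, writing ``Psi`` for the gap edge and ``L`` for the floor,
the component likelihood contribution is

* ``y = 1``:   ``1 - Phi((Psi - mu)/sigma)``   (all latent mass above the
  gap edge collapses onto full health),
* ``y = L``:   ``Phi((L - mu)/sigma)``          (floor censoring),
* otherwise:   ``phi((y - mu)/sigma)/sigma``    (interior density).

An observed ``y`` exactly at ``Psi`` is treated as interior; values in
the open gap are rejected as infeasible input.  Scales are estimated on
the log scale; estimation is maximum likelihood with multiple
randomised starts, analytic gradients and a cluster-robust (sandwich)
covariance for repeated observations per patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize
from scipy.special import log_ndtr, logsumexp, ndtr

from .tariff import FLOOR, GAP_LOWER, InfeasibleUtilityError

__all__ = [
    "AldvmmSpec",
    "AldvmmParams",
    "FitReport",
    "FitOptions",
    "EstimationError",
    "DegenerateComponentError",
    "component_membership",
    "component_density",
    "loglik",
    "loglik_obs",
    "score_obs",
    "fit",
    "predict_mean",
    "simulate",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_ATOL = 1e-9


class EstimationError(RuntimeError):
    """No optimisation start converged to a usable optimum."""


class DegenerateComponentError(EstimationError):
    """A component scale collapsed towards zero at the optimum."""


@dataclass(frozen=True)
class AldvmmSpec:
    """Model layout: component count, covariate lists and censoring bounds."""

    n_components: int
    component_covariates: tuple[str, ...]
    membership_covariates: tuple[str, ...]
    upper_threshold: float = GAP_LOWER
    floor: float = FLOOR
    full_health: float = 1.0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not self.upper_threshold < self.full_health:
            raise ValueError("upper_threshold must lie below full health")
        if not self.floor < self.upper_threshold:
            raise ValueError("floor must lie below upper_threshold")
        object.__setattr__(self, "component_covariates",
                           tuple(self.component_covariates))
        object.__setattr__(self, "membership_covariates",
                           tuple(self.membership_covariates))

    @property
    def n_params(self) -> int:
        K, p, q = self.n_components, len(self.component_covariates), len(
            self.membership_covariates)
        return K * (p + 1) + (K - 1) * q


@dataclass
class AldvmmParams:
    """Fitted or true parameters: per-component coefficients and scales,
    membership logit coefficients (component K is the reference)."""

    beta: np.ndarray      # (K, p)
    lnsigma: np.ndarray   # (K,)
    gamma: np.ndarray     # (K-1, q); empty (0, q) when K == 1

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.lnsigma = np.asarray(self.lnsigma, dtype=float).ravel()
        self.gamma = np.asarray(self.gamma, dtype=float).reshape(
            len(self.lnsigma) - 1, -1) if np.size(self.gamma) else np.zeros(
                (len(self.lnsigma) - 1, 0))
        if self.beta.shape[0] != len(self.lnsigma):
            raise ValueError("beta rows must match number of scales")

    @property
    def n_components(self) -> int:
        return len(self.lnsigma)

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.lnsigma)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta.ravel(), self.lnsigma,
                               self.gamma.ravel()])

    @classmethod
    def unpack(cls, theta: np.ndarray, K: int, p: int, q: int) -> "AldvmmParams":
        theta = np.asarray(theta, dtype=float)
        beta = theta[: K * p].reshape(K, p)
        lnsigma = theta[K * p: K * p + K]
        gamma = theta[K * p + K:].reshape(K - 1, q)
        return cls(beta=beta, lnsigma=lnsigma, gamma=gamma)


@dataclass
class FitOptions:
    n_restarts: int = 20
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 500
    #: lower bound on component scales.  Censored-normal mixtures have
    #: unbounded likelihood when a scale collapses onto interior data;
    #: the bound keeps every likelihood evaluation finite.  A component
    #: may legitimately sit at the bound when it models the full-health
    #: mass; a bound-hitting component that is mostly interior AND
    #: carries almost no posterior mass is a spurious spike on a handful
    #: of points and the start is rejected.
    min_sigma: float = 4e-2


@dataclass
class FitReport:
    """Estimation diagnostics and information criteria.

    AIC = 2k - 2*loglik and BIC = k*ln(n) - 2*loglik over observations
    (not patients).  QIC penalises with the trace of the model-based
    information times the robust covariance, the working-independence
    analogue of AIC for clustered data.
    """

    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    qic: float | None
    vcov_robust: np.ndarray | None
    converged: bool
    n_restarts_used: int
    best_start_seed: int
    grad_norm: float = np.nan
    param_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# likelihood pieces

def component_membership(Z: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Softmax membership probabilities, shape (n, K); component K is the
    reference with linear predictor 0.  Rows sum to 1 exactly."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    gamma = np.asarray(gamma, dtype=float)
    K = gamma.shape[0] + 1 if gamma.ndim == 2 else 1
    if K == 1:
        return np.ones((Z.shape[0], 1))
    eta = np.column_stack([Z @ gamma.T, np.zeros(Z.shape[0])])
    eta -= eta.max(axis=1, keepdims=True)
    w = np.exp(eta)
    return w / w.sum(axis=1, keepdims=True)


def _log_membership(Z: np.ndarray, gamma: np.ndarray, K: int) -> np.ndarray:
    if K == 1:
        return np.zeros((Z.shape[0], 1))
    eta = np.column_stack([Z @ gamma.T, np.zeros(Z.shape[0])])
    return eta - logsumexp(eta, axis=1, keepdims=True)


def _case_masks(y: np.ndarray, spec: AldvmmSpec):
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise InfeasibleUtilityError("missing utilities in estimation data")
    bad = (y > spec.full_health + _ATOL) | (y < spec.floor - _ATOL)
    gap = (y > spec.upper_threshold + _ATOL) & (y < spec.full_health - _ATOL)
    if bad.any() or gap.any():
        raise InfeasibleUtilityError(
            "utilities outside the feasible space "
            f"[{spec.floor}, {spec.upper_threshold}] U {{{spec.full_health}}}"
        )
    at_one = y >= spec.full_health - _ATOL
    at_floor = y <= spec.floor + _ATOL
    interior = ~(at_one | at_floor)
    return y, at_one, at_floor, interior


def _component_logdensity(y, mu, sigma, spec, masks=None):
    """(n, K) log likelihood contributions per component."""
    if masks is None:
        y, at_one, at_floor, interior = _case_masks(y, spec)
    else:
        y, at_one, at_floor, interior = masks
    yk = y[:, None]
    a_up = (spec.upper_threshold - mu) / sigma     # standardised gap edge
    a_lo = (spec.floor - mu) / sigma               # standardised floor
    out = np.empty_like(mu)
    z = (yk - mu) / sigma
    out[interior] = (-_LOG_SQRT_2PI - 0.5 * z[interior] ** 2
                     - np.log(sigma)[None, :].repeat(len(y), 0)[interior])
    out[at_one] = log_ndtr(-a_up)[at_one]
    out[at_floor] = log_ndtr(a_lo)[at_floor]
    return out


def component_density(y, mu: float, sigma: float, spec: AldvmmSpec) -> float:
    """Scalar component likelihood contribution (density or point mass)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = _component_logdensity(np.atleast_1d(float(y)),
                                np.array([[mu]]), np.array([sigma]), spec)
    return float(np.exp(out[0, 0]))


def _prepare(params: AldvmmParams, X, Z, spec: AldvmmSpec):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    mu = X @ params.beta.T                        # (n, K)
    sigma = params.sigma
    logpi = _log_membership(Z, params.gamma, params.n_components)
    return X, Z, mu, sigma, logpi


def loglik_obs(params: AldvmmParams, y, X, Z, spec: AldvmmSpec) -> np.ndarray:
    """Per-observation log-likelihood contributions, shape (n,)."""
    X, Z, mu, sigma, logpi = _prepare(params, X, Z, spec)
    logf = _component_logdensity(y, mu, sigma, spec)
    return logsumexp(logpi + logf, axis=1)


def loglik(params: AldvmmParams, y, X, Z, spec: AldvmmSpec) -> float:
    """Sample log-likelihood."""
    return float(loglik_obs(params, y, X, Z, spec).sum())


def score_obs(params: AldvmmParams, y, X, Z, spec: AldvmmSpec) -> np.ndarray:
    """Analytic per-observation score matrix, shape (n, n_params).

    Columns follow :meth:`AldvmmParams.pack` order: beta (row-major),
    log-scales, membership gammas.
    """
    X, Z, mu, sigma, logpi = _prepare(params, X, Z, spec)
    masks = _case_masks(y, spec)
    y_arr, at_one, at_floor, interior = masks
    n, K = mu.shape
    p = X.shape[1]
    q = Z.shape[1]

    logf = _component_logdensity(y_arr, mu, sigma, spec, masks)
    logpost = logpi + logf
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    w = np.exp(logpost)                            # responsibilities (n, K)

    a_up = (spec.upper_threshold - mu) / sigma
    a_lo = (spec.floor - mu) / sigma
    zres = (y_arr[:, None] - mu) / sigma

    dmu = np.empty_like(mu)      # d log f / d mu
    dls = np.empty_like(mu)      # d log f / d ln sigma
    # interior: Gaussian density derivatives
    dmu[interior] = (zres / sigma)[interior]
    dls[interior] = (zres**2 - 1.0)[interior]
    # upper mass: inverse Mills ratio of the gap edge
    log_phi_up = -_LOG_SQRT_2PI - 0.5 * a_up**2
    r_up = np.exp(log_phi_up - log_ndtr(-a_up))
    dmu[at_one] = (r_up / sigma)[at_one]
    dls[at_one] = (r_up * a_up)[at_one]
    # floor mass
    log_phi_lo = -_LOG_SQRT_2PI - 0.5 * a_lo**2
    r_lo = np.exp(log_phi_lo - log_ndtr(a_lo))
    dmu[at_floor] = (-r_lo / sigma)[at_floor]
    dls[at_floor] = (-r_lo * a_lo)[at_floor]

    scores = np.empty((n, K * p + K + (K - 1) * q))
    wdmu = w * dmu
    for c in range(K):
        scores[:, c * p:(c + 1) * p] = wdmu[:, [c]] * X
    scores[:, K * p:K * p + K] = w * dls
    if K > 1:
        pi = np.exp(logpi)
        diff = w[:, :-1] - pi[:, :-1]
        for c in range(K - 1):
            scores[:, K * p + K + c * q:K * p + K + (c + 1) * q] = \
                diff[:, [c]] * Z
    return scores


# ---------------------------------------------------------------------------
# estimation

def _standardise(M: np.ndarray):
    """Centre/scale non-constant columns; returns (M_std, means, sds)."""
    M = np.asarray(M, dtype=float)
    means = M.mean(axis=0)
    sds = M.std(axis=0)
    const = sds < 1e-12
    means[const] = 0.0
    sds[const] = 1.0
    return (M - means) / sds, means, sds


def _destd_transform(p: int, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Linear map T with beta_orig = T @ beta_std for one coefficient block.

    Column 0 is the intercept (constant columns are left uncentred by
    :func:`_standardise`, so means[0] = 0 and sds[0] = 1); it absorbs
    the centring shifts of the other columns."""
    T = np.diag(1.0 / sds)
    T[0, 1:] = -means[1:] / sds[1:]
    return T


def _start_values(y, Xs, K, p, q, rng, jitter):
    """Quantile-block starting values in the standardised parameterisation."""
    order = np.sort(np.asarray(y, dtype=float))
    blocks = np.array_split(order, K)
    beta = np.zeros((K, p))
    lnsigma = np.zeros(K)
    for c, blk in enumerate(blocks):
        beta[c, 0] = blk.mean()
        lnsigma[c] = np.log(np.clip(blk.std(), 0.05, 0.5))
    gamma = np.zeros((K - 1, q))
    theta = np.concatenate([beta.ravel(), lnsigma, gamma.ravel()])
    if jitter > 0:
        theta = theta + rng.normal(0.0, jitter, size=theta.shape)
    return theta


def _numeric_hessian(grad_fn, theta, eps=1e-5):
    n = len(theta)
    H = np.empty((n, n))
    for j in range(n):
        step = eps * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += step
        tm = theta.copy(); tm[j] -= step
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * step)
    return 0.5 * (H + H.T)


def _interior_collapse(params: AldvmmParams, y, Xs, Zs, spec, masks,
                       min_sigma: float) -> bool:
    """True when a bound-hitting component carries interior data — the
    unbounded-likelihood spike of censored normal mixtures."""
    at_bound = params.sigma <= min_sigma * 1.01
    if not at_bound.any():
        return False
    ll_i = loglik_obs(params, y, Xs, Zs, spec)
    logf = _component_logdensity(y, Xs @ params.beta.T, params.sigma,
                                 spec, masks)
    logpi = _log_membership(Zs, params.gamma, params.n_components)
    post = np.exp(logpi + logf - ll_i[:, None])
    interior = masks[3]
    n = len(ll_i)
    for c in np.where(at_bound)[0]:
        total = post[:, c].sum()
        if total <= 0:
            continue
        mostly_interior = post[interior, c].sum() / total > 0.5
        if mostly_interior and total < 0.02 * n:
            return True
    return False


def _relabel(params: AldvmmParams, Z: np.ndarray) -> AldvmmParams:
    """Order components by decreasing average membership probability."""
    pi = component_membership(Z, params.gamma).mean(axis=0)
    order = np.argsort(-pi, kind="stable")
    if np.array_equal(order, np.arange(params.n_components)):
        return params
    K = params.n_components
    eta = np.vstack([params.gamma, np.zeros((1, params.gamma.shape[1]))])
    eta = eta[order]
    gamma_new = eta[:-1] - eta[-1]
    return AldvmmParams(beta=params.beta[order], lnsigma=params.lnsigma[order],
                        gamma=gamma_new)


def fit(
    y,
    X,
    Z,
    spec: AldvmmSpec,
    groups: Sequence | None = None,
    options: FitOptions | None = None,
) -> tuple[AldvmmParams, FitReport]:
    """Maximum-likelihood estimation with multiple randomised starts.

    ``groups`` (patient ids) drives the cluster-robust sandwich
    covariance; when omitted each row is its own cluster.  Components in
    the returned parameters are ordered by decreasing average membership
    probability, a fixed labelling convention that makes results
    comparable across runs.
    """
    opts = options or FitOptions()
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    K, p, q = spec.n_components, X.shape[1], Z.shape[1]
    if p != len(spec.component_covariates) or q != len(spec.membership_covariates):
        raise ValueError("design widths do not match spec covariate lists")
    n = len(y)
    if n <= spec.n_params:
        raise EstimationError(
            f"n_obs={n} must exceed n_params={spec.n_params}")
    _case_masks(y, spec)  # validate outcomes up front

    Xs, mx, sx = _standardise(X)
    Zs, mz, sz = _standardise(Z)
    masks = _case_masks(y, spec)

    def negll_grad(theta):
        params = AldvmmParams.unpack(theta, K, p, q)
        try:
            ll = loglik_obs(params, y, Xs, Zs, spec)
            sc = score_obs(params, y, Xs, Zs, spec)
        except (FloatingPointError, ValueError):
            return 1e12, np.zeros_like(theta)
        total = ll.sum()
        if not np.isfinite(total):
            return 1e12, np.zeros_like(theta)
        g = sc.sum(axis=0)
        if not np.isfinite(g).all():
            return 1e12, np.zeros_like(theta)
        return -total, -g

    rng = np.random.default_rng(opts.seed)
    n_degenerate = 0
    lb = np.full(spec.n_params, -np.inf)
    ub = np.full(spec.n_params, np.inf)
    lb[K * p:K * p + K] = np.log(opts.min_sigma)
    ub[K * p:K * p + K] = 3.0
    bounds = list(zip(lb, ub))

    def minimise(theta0):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return optimize.minimize(
                negll_grad, theta0, jac=True, method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": opts.max_iter, "gtol": opts.tol,
                         "ftol": 1e-12},
            )

    def projected_gnorm(res) -> float:
        # at an active bound the raw gradient may push outward; the KKT
        # measure of convergence is the projected gradient
        g = res.jac.copy()
        g[(res.x <= lb + 1e-10) & (g > 0)] = 0.0
        g[(res.x >= ub - 1e-10) & (g < 0)] = 0.0
        return float(np.max(np.abs(g)))

    best = None
    for start_idx in range(opts.n_restarts):
        jitter = 0.0 if start_idx == 0 else 0.25
        res = minimise(_start_values(y, Xs, K, p, q, rng, jitter))
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            continue
        cand_params = AldvmmParams.unpack(res.x, K, p, q)
        if _interior_collapse(cand_params, y, Xs, Zs, spec, masks,
                              opts.min_sigma):
            n_degenerate += 1
            continue
        cand = (res.fun, start_idx, res)
        if best is None or cand[0] < best[0] - 1e-9:
            best = cand
    if best is None:
        if n_degenerate:
            raise DegenerateComponentError(
                f"all {n_degenerate} usable starts collapsed a component "
                "scale onto interior data")
        raise EstimationError("no optimisation start produced a finite optimum")

    # polish: restarting L-BFGS-B from the incumbent resets its curvature
    # approximation and makes further progress on flat mixture ridges
    fun, best_start, res = best
    for _ in range(2):
        if res.success and projected_gnorm(res) < opts.tol:
            break
        res2 = minimise(res.x)
        if np.isfinite(res2.fun) and res2.fun < res.fun - 1e-10:
            res = res2
        else:
            break
    theta_hat = res.x
    gnorm = projected_gnorm(res)
    converged = bool(res.success or gnorm <= 1e-3 * max(1.0, abs(res.fun)))
    params_std = AldvmmParams.unpack(theta_hat, K, p, q)
    if _interior_collapse(params_std, y, Xs, Zs, spec, masks,
                          opts.min_sigma):
        raise DegenerateComponentError(
            "polished optimum collapsed a component scale onto interior data")
    if (params_std.sigma <= opts.min_sigma * 1.01).any():
        warnings.warn("component scale at lower bound (point-mass limit)",
                      stacklevel=2)

    # sandwich covariance in the standardised space, then map back
    def grad_only(theta):
        return negll_grad(theta)[1]

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        H = _numeric_hessian(grad_only, theta_hat)   # hessian of -loglik
        sc = score_obs(params_std, y, Xs, Zs, spec)
    if groups is None:
        cluster_scores = sc
    else:
        gi = pd.factorize(np.asarray(groups))[0]
        cluster_scores = np.zeros((gi.max() + 1, sc.shape[1]))
        np.add.at(cluster_scores, gi, sc)
    B = cluster_scores.T @ cluster_scores
    try:
        Ainv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian; using pseudo-inverse", stacklevel=2)
        Ainv = np.linalg.pinv(H)
    vcov_std = Ainv @ B @ Ainv

    # map standardised parameters/covariance back to the raw design scale
    Tx = _destd_transform(p, mx, sx)
    Tz = _destd_transform(q, mz, sz)
    import scipy.linalg as sla
    blocks = [Tx] * K + [np.eye(K)] + [Tz] * (K - 1)
    J = sla.block_diag(*blocks)
    theta_orig = np.concatenate([
        (params_std.beta @ Tx.T).ravel(),
        params_std.lnsigma,
        (params_std.gamma @ Tz.T).ravel() if K > 1 else np.empty(0),
    ])
    params = AldvmmParams.unpack(theta_orig, K, p, q)
    vcov = J @ vcov_std @ J.T

    # relabel components by decreasing average membership probability;
    # the covariance transforms exactly (permutation for beta/lnsigma,
    # a reference-category change of basis for gamma)
    pi_mean = component_membership(Z, params.gamma).mean(axis=0)
    order = np.argsort(-pi_mean, kind="stable")
    params = _relabel(params, Z)
    if not np.array_equal(order, np.arange(K)):
        R = np.zeros((spec.n_params, spec.n_params))
        for new_c, old_c in enumerate(order):
            R[new_c * p:(new_c + 1) * p, old_c * p:(old_c + 1) * p] = np.eye(p)
            R[K * p + new_c, K * p + old_c] = 1.0
        # new gamma_c = eta_{order[c]} - eta_{order[K-1]}, eta_{K-1} := 0
        g0 = K * p + K
        for new_c in range(K - 1):
            for old_k in (order[new_c], order[K - 1]):
                if old_k < K - 1:
                    sign = 1.0 if old_k == order[new_c] else -1.0
                    if order[new_c] == order[K - 1]:
                        sign = 0.0
                    R[g0 + new_c * q:g0 + (new_c + 1) * q,
                      g0 + old_k * q:g0 + (old_k + 1) * q] += sign * np.eye(q)
        vcov = R @ vcov @ R.T

    ll_hat = loglik(params, y, X, Z, spec)
    k = spec.n_params
    penalty = float(np.trace(H @ vcov_std))
    report = FitReport(
        loglik=ll_hat,
        n_params=k,
        n_obs=n,
        aic=2 * k - 2 * ll_hat,
        bic=k * np.log(n) - 2 * ll_hat,
        qic=-2 * ll_hat + 2 * penalty,
        vcov_robust=vcov,
        converged=converged,
        n_restarts_used=opts.n_restarts,
        best_start_seed=best_start,
        grad_norm=gnorm,
        param_names=_param_names(spec),
    )
    return params, report


def _param_names(spec: AldvmmSpec) -> list[str]:
    names = []
    for c in range(spec.n_components):
        names += [f"beta{c + 1}:{v}" for v in spec.component_covariates]
    names += [f"lnsigma{c + 1}" for c in range(spec.n_components)]
    for c in range(spec.n_components - 1):
        names += [f"gamma{c + 1}:{v}" for v in spec.membership_covariates]
    return names


# ---------------------------------------------------------------------------
# prediction and simulation

def predict_mean(params: AldvmmParams, X, Z, spec: AldvmmSpec) -> np.ndarray:
    """Analytic expected utility per row.

    E[y | x, z] mixes, per component, the full-health mass, the floor
    mass and the doubly-truncated normal mean over the interior; the
    result always lies in [floor, 1] — predictions cannot leave the
    feasible space.
    """
    X, Z, mu, sigma, logpi = _prepare(params, X, Z, spec)
    pi = np.exp(logpi)
    a_lo = (spec.floor - mu) / sigma
    a_up = (spec.upper_threshold - mu) / sigma
    Phi_lo = ndtr(a_lo)
    Phi_up = ndtr(a_up)
    phi_lo = np.exp(-_LOG_SQRT_2PI - 0.5 * a_lo**2)
    phi_up = np.exp(-_LOG_SQRT_2PI - 0.5 * a_up**2)
    # (Phi_up - Phi_lo) * truncated mean, written to avoid 0/0 at the tails
    interior_part = mu * (Phi_up - Phi_lo) + sigma * (phi_lo - phi_up)
    Ec = (1.0 - Phi_up) * spec.full_health + Phi_lo * spec.floor + interior_part
    return np.clip((pi * Ec).sum(axis=1), spec.floor, spec.full_health)


def simulate(
    params: AldvmmParams,
    X,
    Z,
    spec: AldvmmSpec,
    n_draws: int = 1000,
    seed: int = 0,
    offset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw utilities from the fitted model, (n, n_draws) plus labels.

    For each row and draw: sample a component from the membership
    probabilities, sample the latent normal, then censor — latent values
    at or above the gap edge map to full health, values at or below the
    floor map to the floor.  ``offset`` (n,) shifts every component mean,
    used by the synthetic generator for patient-level random effects.
    Returns ``(draws, component_labels)``.
    """
    X, Z, mu, sigma, logpi = _prepare(params, X, Z, spec)
    if offset is not None:
        mu = mu + np.asarray(offset, dtype=float)[:, None]
    n, K = mu.shape
    rng = np.random.default_rng(seed)
    pi = np.exp(logpi)
    cum = np.cumsum(pi, axis=1)
    u = rng.random((n, n_draws))
    labels = (u[:, :, None] > cum[:, None, :]).sum(axis=2).astype(np.int8)
    idx = labels.astype(int)
    mu_sel = np.take_along_axis(mu, idx, axis=1)
    latent = rng.normal(mu_sel, sigma[idx])
    draws = np.where(latent >= spec.upper_threshold, spec.full_health,
                     np.maximum(latent, spec.floor))
    return draws, labels
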