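"""Indirect (response) mapping: ordered probits per EQ-5D dimension.

Stage one fits an ordered probit for each of the five EQ-5D-3L
dimensions as a function of the QLQ-C30 covariates (including age and
age squared).  With latent index ``x @ beta`` and cutpoints
``kappa1 < kappa2``,

    P(level 1) = Phi(kappa1 - x @ beta)
    P(level 2) = Phi(kappa2 - x @ beta) - Phi(kappa1 - x @ beta)
    P(level 3) = 1 - Phi(kappa2 - x @ beta)

Stage two turns the five marginal level distributions into
probabilities over all 243 health states and takes the tariff-weighted
expectation.  The default combines dimensions under independent latent
errors (product rule); an optional Gaussian-copula layer estimates a
latent error correlation matrix from pairwise bivariate-probit
likelihoods and evaluates state probabilities with a seeded GHK
simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .tariff import DIMENSIONS, UK_TTO, ValueSet, enumerate_states, score_levels

__all__ = [
    "OrderedProbitDim",
    "OrderedProbitSystem",
    "fit_ordered_probits",
    "level_probabilities",
    "state_probabilities",
    "expected_utility",
    "estimate_latent_correlation",
    "ghk_rectangle_probability",
]

#: Latent-scale value used to pin a cutpoint whose level-3 cell is empty.
PINNED_CUTPOINT = 6.0


@dataclass
class OrderedProbitDim:
    """One dimension's ordered probit: coefficients and two cutpoints."""

    dimension: str
    coef: dict[str, float]
    cut1: float
    cut2: float
    pinned: bool = False

    def __post_init__(self) -> None:
        if not self.cut1 < self.cut2:
            raise ValueError(
                f"{self.dimension}: cutpoints must satisfy cut1 < cut2")


@dataclass
class OrderedProbitSystem:
    """Five per-dimension probits plus an optional latent error correlation.

    ``covariates`` fixes the design column order; ``corr`` is None for
    the independent-errors default, otherwise a symmetric positive
    definite 5x5 matrix with unit diagonal.
    """

    dims: dict[str, OrderedProbitDim]
    covariates: tuple[str, ...]
    corr: np.ndarray | None = None
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [d for d in DIMENSIONS if d not in self.dims]
        if missing:
            raise ValueError(f"missing dimensions: {missing}")
        self.covariates = tuple(self.covariates)
        if self.corr is not None:
            C = np.asarray(self.corr, dtype=float)
            if C.shape != (5, 5) or not np.allclose(C, C.T):
                raise ValueError("corr must be a symmetric 5x5 matrix")
            if not np.allclose(np.diag(C), 1.0):
                raise ValueError("corr must have unit diagonal")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError("corr must be positive definite")
            self.corr = C

    def coef_matrix(self) -> np.ndarray:
        """(5, p) coefficient matrix in DIMENSIONS x covariates order."""
        return np.array([
            [self.dims[d].coef.get(c, 0.0) for c in self.covariates]
            for d in DIMENSIONS
        ])

    def cutpoints(self) -> np.ndarray:
        """(5, 2) cutpoint matrix in DIMENSIONS order."""
        return np.array([[self.dims[d].cut1, self.dims[d].cut2]
                         for d in DIMENSIONS])


def _design_array(X, covariates: Sequence[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in covariates if c not in X.columns]
        if missing:
            raise ValueError(f"design missing covariates: {missing}")
        return X[list(covariates)].to_numpy(dtype=float)
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    if arr.shape[1] != len(covariates):
        raise ValueError("design width does not match system covariates")
    return arr


def level_probabilities(system: OrderedProbitSystem, X) -> np.ndarray:
    """Marginal level probabilities, shape (n, 5, 3); rows sum to 1."""
    Xa = _design_array(X, system.covariates)
    idx = Xa @ system.coef_matrix().T            # (n, 5)
    cuts = system.cutpoints()                    # (5, 2)
    p1 = ndtr(cuts[:, 0] - idx)
    p2 = ndtr(cuts[:, 1] - idx) - p1
    p3 = 1.0 - ndtr(cuts[:, 1] - idx)
    return np.stack([p1, p2, p3], axis=2)


# ---------------------------------------------------------------------------
# stage 1: estimation

def _fit_one_dimension(endog: np.ndarray, exog: np.ndarray,
                       names: Sequence[str], dim: str):
    """Ordered probit for one dimension via statsmodels; handles an
    empty level-3 cell by fitting a binary probit and pinning cut2."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    levels = np.unique(endog)
    if len(levels) < 2:
        raise ValueError(f"{dim}: fewer than 2 observed levels")
    if 3 not in levels:
        # binary probit on level 1 vs 2; kappa2 unidentified -> pinned
        import statsmodels.api as sm
        warnings.warn(
            f"{dim}: no level-3 responses; cutpoint 2 pinned at "
            f"+{PINNED_CUTPOINT} on the latent scale", stacklevel=3)
        res = sm.Probit((endog == 2).astype(int), exog).fit(disp=0)
        # P(level 2) = Phi(xb - kappa1): probit constant = -kappa1 requires
        # an explicit intercept column appended last
        coef = res.params[:-1]
        cut1 = -res.params[-1]
        return coef, cut1, PINNED_CUTPOINT, True, res
    model = OrderedModel(endog, exog, distr="probit")
    res = model.fit(method="bfgs", maxiter=500, disp=0)
    k = exog.shape[1]
    coef = res.params[:k]
    # statsmodels parameterises thresholds as (t1, log(t2 - t1))
    cut1 = res.params[k]
    cut2 = cut1 + np.exp(res.params[k + 1])
    return coef, cut1, cut2, False, res


def fit_ordered_probits(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    groups: Sequence | None = None,
) -> OrderedProbitSystem:
    """Fit the five per-dimension ordered probits by maximum likelihood.

    ``covariates`` must not contain a constant column (the cutpoints
    absorb the intercept).  Designs are standardised internally for the
    optimiser and coefficients returned on the original scale.  Cluster-
    robust covariances per dimension are stored in ``fit_info``.
    """
    covariates = [c for c in covariates if c != "const"]
    X = frame[list(covariates)].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds[sds < 1e-12] = 1.0
    Xs = (X - means) / sds

    dims: dict[str, OrderedProbitDim] = {}
    info: dict[str, dict] = {}
    for d_idx, dim in enumerate(DIMENSIONS):
        endog = frame[dim].to_numpy(dtype=int)
        pinned = 3 not in np.unique(endog)
        if pinned:
            exog = np.column_stack([Xs, np.ones(len(Xs))])
            coef_s, cut1_s, cut2_s, pinned, res = _fit_one_dimension(
                endog, exog, covariates, dim)
        else:
            coef_s, cut1_s, cut2_s, pinned, res = _fit_one_dimension(
                endog, Xs, covariates, dim)
        coef_s = np.asarray(coef_s, dtype=float)
        # back-transform: beta_j = b_j / s_j; cutpoints shift by sum(b m / s)
        coef = coef_s / sds
        shift = float((coef_s * means / sds).sum())
        cut1 = cut1_s + shift
        cut2 = cut2_s + shift if not pinned else PINNED_CUTPOINT
        dims[dim] = OrderedProbitDim(
            dimension=dim,
            coef=dict(zip(covariates, coef)),
            cut1=float(cut1),
            cut2=float(max(cut2, cut1 + 1e-6)),
            pinned=pinned,
        )
        entry = {"loglik": float(res.llf), "converged": bool(res.mle_retvals.get(
            "converged", True)) if hasattr(res, "mle_retvals") else True}
        if groups is not None and hasattr(res.model, "score_obs"):
            try:
                sc = res.model.score_obs(res.params)
                H = res.model.hessian(res.params)
                gi = pd.factorize(np.asarray(groups))[0]
                cl = np.zeros((gi.max() + 1, sc.shape[1]))
                np.add.at(cl, gi, sc)
                Ainv = np.linalg.inv(-H)
                entry["vcov_robust"] = Ainv @ (cl.T @ cl) @ Ainv
            except np.linalg.LinAlgError:
                entry["vcov_robust"] = None
        info[dim] = entry
    return OrderedProbitSystem(dims=dims, covariates=tuple(covariates),
                               corr=None, fit_info=info)


# ---------------------------------------------------------------------------
# stage 2: state probabilities and expected utility

_STATE_LEVELS = None


def _state_level_array() -> np.ndarray:
    """(243, 5) integer level array in enumeration order (cached)."""
    global _STATE_LEVELS
    if _STATE_LEVELS is None:
        _STATE_LEVELS = np.array([s.levels for s in enumerate_states()])
    return _STATE_LEVELS


def ghk_rectangle_probability(lower: np.ndarray, upper: np.ndarray,
                              chol: np.ndarray, u: np.ndarray) -> float:
    """GHK estimate of P(lower < eps < upper) for eps ~ N(0, L L').

    ``u`` is an (n_draws, d) array of uniforms shared across rectangles
    so that probabilities vary smoothly across states.
    """
    n_draws, d = u.shape
    eta = np.zeros((n_draws, d))
    weight = np.ones(n_draws)
    for j in range(d):
        drift = eta[:, :j] @ chol[j, :j] if j else 0.0
        lo = ndtr((lower[j] - drift) / chol[j, j])
        hi = ndtr((upper[j] - drift) / chol[j, j])
        weight *= np.maximum(hi - lo, 0.0)
        frac = lo + u[:, j] * np.maximum(hi - lo, 1e-300)
        eta[:, j] = ndtri(np.clip(frac, 1e-15, 1 - 1e-15))
    return float(weight.mean())


def state_probabilities(
    system: OrderedProbitSystem,
    x_row,
    method: str = "product",
    n_draws: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Probabilities of the 243 states for one covariate row.

    ``method='product'`` multiplies the marginal level probabilities
    (independent latent errors).  ``method='ghk'`` uses the system's
    correlation matrix (identity when absent) and a seeded GHK
    simulator, normalised to sum to 1.
    """
    x = np.atleast_2d(np.asarray(
        x_row[list(system.covariates)] if isinstance(x_row, (pd.Series,))
        else x_row, dtype=float))
    probs = level_probabilities(system, x)[0]    # (5, 3)
    levels = _state_level_array()
    if method == "product":
        out = np.ones(243)
        for d in range(5):
            out *= probs[d, levels[:, d] - 1]
        return out
    if method != "ghk":
        raise ValueError(f"unknown method {method!r}")
    corr = system.corr if system.corr is not None else np.eye(5)
    chol = np.linalg.cholesky(corr)
    idx = (x @ system.coef_matrix().T)[0]
    cuts = system.cutpoints()
    # per-dimension latent bounds for each level: (-inf, k1], (k1, k2], (k2, inf)
    bounds = np.full((5, 3, 2), 0.0)
    for d in range(5):
        k1, k2 = cuts[d] - idx[d]
        bounds[d, 0] = (-np.inf, k1)
        bounds[d, 1] = (k1, k2)
        bounds[d, 2] = (k2, np.inf)
    rng = np.random.default_rng(seed)
    u = rng.random((n_draws, 5))
    out = np.empty(243)
    for s in range(243):
        lv = levels[s] - 1
        lower = bounds[np.arange(5), lv, 0]
        upper = bounds[np.arange(5), lv, 1]
        out[s] = ghk_rectangle_probability(lower, upper, chol, u)
    total = out.sum()
    if total <= 0:
        raise RuntimeError("GHK produced a zero total probability")
    return out / total


def expected_utility(
    system: OrderedProbitSystem,
    X,
    value_set: ValueSet = UK_TTO,
    method: str = "product",
    n_draws: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Tariff-weighted expected utility per row; always in [-0.594, 1]."""
    utilities = score_levels(_state_level_array(), value_set)
    Xa = _design_array(X, system.covariates)
    if method == "product":
        probs = level_probabilities(system, Xa)  # (n, 5, 3)
        levels = _state_level_array()
        acc = np.zeros((Xa.shape[0], 243))
        acc[:] = 1.0
        for d in range(5):
            acc *= probs[:, d, :][:, levels[:, d] - 1]
        return acc @ utilities
    out = np.empty(Xa.shape[0])
    for i in range(Xa.shape[0]):
        p = state_probabilities(system, Xa[i], method=method,
                                n_draws=n_draws, seed=seed)
        out[i] = p @ utilities
    return out


# ---------------------------------------------------------------------------
# optional correlation layer

def _pair_negll(rho: float, b1, b2) -> float:
    """Negative bivariate-probit log-likelihood for one dimension pair.

    ``b1``/``b2`` are (n, 2) latent rectangle bounds per observation.
    """
    cov = np.array([[1.0, rho], [rho, 1.0]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov,
                                    allow_singular=False)

    def F(a, b):
        pts = np.column_stack([a, b])
        neg = (pts <= -30).any(axis=1)
        out = np.atleast_1d(mvn.cdf(np.clip(pts, -30, 30)))
        out[neg] = 0.0
        return out

    p = (F(b1[:, 1], b2[:, 1]) - F(b1[:, 0], b2[:, 1])
         - F(b1[:, 1], b2[:, 0]) + F(b1[:, 0], b2[:, 0]))
    return -float(np.log(np.clip(p, 1e-12, None)).sum())


def estimate_latent_correlation(
    system: OrderedProbitSystem,
    frame: pd.DataFrame,
    max_rows: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Pairwise latent error correlations given fitted marginal probits.

    For each of the 10 dimension pairs, maximises the bivariate normal
    rectangle likelihood of the observed level pairs in the correlation
    parameter (a polychoric-style estimate conditional on covariates).
    The assembled matrix is projected to the nearest positive definite
    correlation matrix if needed.  ``max_rows`` subsamples for speed.
    """
    rng = np.random.default_rng(seed)
    if len(frame) > max_rows:
        frame = frame.iloc[rng.choice(len(frame), max_rows, replace=False)]
    Xa = _design_array(frame, system.covariates)
    idx = Xa @ system.coef_matrix().T
    cuts = system.cutpoints()

    def bounds_for(d: int) -> np.ndarray:
        lv = frame[DIMENSIONS[d]].to_numpy(dtype=int)
        k = cuts[d]
        lower = np.where(lv == 1, -np.inf, np.where(lv == 2, k[0], k[1]))
        upper = np.where(lv == 1, k[0], np.where(lv == 2, k[1], np.inf))
        return np.column_stack([lower - idx[:, d], upper - idx[:, d]])

    C = np.eye(5)
    all_bounds = [bounds_for(d) for d in range(5)]
    for i in range(5):
        for j in range(i + 1, 5):
            res = optimize.minimize_scalar(
                _pair_negll, args=(all_bounds[i], all_bounds[j]),
                bounds=(-0.95, 0.95), method="bounded",
                options={"xatol": 1e-3})
            C[i, j] = C[j, i] = float(res.x)
    # nearest-PD projection (clip eigenvalues, renormalise diagonal)
    w, V = np.linalg.eigh(C)
    if w.min() <= 1e-8:
        w = np.clip(w, 1e-6, None)
        C = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C
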