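"""Random-effects linear regression benchmark.

A random-intercept linear model of the utility on the comparator design
(the 15 rescaled QLQ-C30 scores, age and age squared), estimated by
maximum likelihood.  Predictions use the fixed effects only — the
mapping use-case targets out-of-sample patients with no estimated
intercept.  Predictions are deliberately NOT clamped to the feasible
utility space: leaving the scale is the documented flaw of linear
mapping models and must remain observable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aldvmm import FitReport

__all__ = ["LinearReParams", "fit_linear_re", "predict_linear",
           "CollinearityError"]


class CollinearityError(ValueError):
    """The comparator design matrix is singular."""


@dataclass
class LinearReParams:
    """Fixed effects plus the two variance components."""

    coef: dict[str, float]
    re_var: float
    resid_var: float

    def __post_init__(self) -> None:
        if self.re_var < 0 or self.resid_var < 0:
            raise ValueError("variance components must be non-negative")

    def coef_array(self, covariates) -> np.ndarray:
        return np.array([self.coef[c] for c in covariates])


def _cluster_sandwich(X: np.ndarray, resid: np.ndarray, gi: np.ndarray,
                      re_var: float, resid_var: float) -> np.ndarray:
    """GEE-style sandwich for the fixed effects under the random-intercept
    marginal covariance V_i = re_var * J + resid_var * I per cluster."""
    p = X.shape[1]
    A = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in np.unique(gi):
        sel = gi == g
        Xg = X[sel]
        rg = resid[sel]
        m = len(rg)
        V = re_var * np.ones((m, m)) + resid_var * np.eye(m)
        Vi = np.linalg.inv(V)
        XtVi = Xg.T @ Vi
        A += XtVi @ Xg
        u = XtVi @ rg
        B += np.outer(u, u)
    Ainv = np.linalg.inv(A)
    return Ainv @ B @ Ainv


def fit_linear_re(
    frame: pd.DataFrame,
    covariates,
    outcome: str = "eq5d",
    group_col: str = "patient_id",
) -> tuple[LinearReParams, FitReport]:
    """ML random-intercept regression with a cluster-robust covariance.

    With no within-patient replication the model collapses to pooled
    OLS (zero random-intercept variance).
    """
    import statsmodels.api as sm

    covariates = list(covariates)
    X = frame[covariates].to_numpy(dtype=float)
    y = frame[outcome].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("comparator design matrix is singular")
    gi = pd.factorize(frame[group_col])[0]
    n, p = X.shape

    max_size = np.bincount(gi).max()
    if max_size == 1:
        res = sm.OLS(y, X).fit()
        coef = np.asarray(res.params)
        resid_var = float(res.ssr / n)  # ML estimate
        re_var = 0.0
        llf = float(res.llf)
        vcov = _cluster_sandwich(X, y - X @ coef, gi, re_var, resid_var)
        converged = True
    else:
        model = sm.MixedLM(y, X, groups=gi)
        res = model.fit(reml=False)
        coef = np.asarray(res.fe_params)
        re_var = float(np.asarray(res.cov_re)[0, 0])
        resid_var = float(res.scale)
        llf = float(res.llf)
        vcov = _cluster_sandwich(X, y - X @ coef, gi, re_var, resid_var)
        converged = bool(res.converged)

    k = p + 2  # fixed effects + two variance components
    report = FitReport(
        loglik=llf,
        n_params=k,
        n_obs=n,
        aic=2 * k - 2 * llf,
        bic=k * np.log(n) - 2 * llf,
        qic=None,
        vcov_robust=vcov,
        converged=converged,
        n_restarts_used=1,
        best_start_seed=0,
        param_names=list(covariates),
    )
    params = LinearReParams(coef=dict(zip(covariates, coef)),
                            re_var=re_var, resid_var=resid_var)
    return params, report


def predict_linear(params: LinearReParams, X) -> np.ndarray:
    """Fixed-effect linear predictions; unclamped by design."""
    covariates = list(params.coef)
    if isinstance(X, pd.DataFrame):
        Xa = X[covariates].to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
    return Xa @ params.coef_array(covariates)
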