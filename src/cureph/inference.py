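"""Asymptotic inference: sandwich covariance, Wald tests, delta-method curves.

Coefficients of the non-negative spline vector theta that are estimated on
the boundary (active constraints) must be excluded before inverting the
information, otherwise the resulting "covariance" can have negative
variances.  A constraint is flagged active when theta_u < 1e-3 and the
corresponding penalized-likelihood gradient is below -1e-2.

With M = -d2l/deta2 and P = lambda * d2J/deta2 = 2 lambda R (theta block),
the large-sample covariance of eta_hat is the sandwich

    cov = (M + P)^-1  M  (M + P)^-1

computed on the rows/columns off the active set and padded back with zeros.
With lambda = 0 and no active constraints this collapses to the usual inverse
observed information.

Curves (baseline hazard, baseline survival, population survival) carry
point-wise delta-method standard errors and 95% confidence intervals,
clipped to their natural range; a log(-log) transformed interval is offered
as an option for the survival curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import (LikelihoodWorkspace, ModelParameters, incidence_prob)
from .splines import SplineBasis

__all__ = [
    "FitResult",
    "find_active_constraints",
    "sandwich_covariance",
    "wald_table",
    "baseline_hazard_curve",
    "baseline_survival_curve",
    "population_survival_curve",
]

ACTIVE_THETA_TOL = 1e-3
ACTIVE_GRAD_EPS = 1e-2
Z975 = stats.norm.ppf(0.975)


@dataclass
class FitResult:
    """Everything produced by a penalized fit.

    ``covariance`` is the (p+q+m) x (p+q+m) sandwich matrix with exact zero
    rows/columns at the active constraints; it is ``None`` until
    :func:`sandwich_covariance` (or the high-level driver) fills it in.
    """

    params: ModelParameters
    basis: SplineBasis
    loglik: float
    penloglik: float
    lam: float
    sigma2: float
    nu: float
    active_set: np.ndarray
    covariance: Optional[np.ndarray]
    converged: bool
    n_iter: int = 0
    outer_iter: int = 0
    trace: list = field(default_factory=list)
    workspace: Optional[LikelihoodWorkspace] = None

    @property
    def theta_covariance(self) -> np.ndarray:
        k = self.params.p + self.params.q
        return self.covariance[k:, k:]

    def summary(self) -> dict:
        return {
            "loglik": self.loglik, "penloglik": self.penloglik,
            "lambda": self.lam, "sigma2": self.sigma2, "nu": self.nu,
            "converged": bool(self.converged), "n_iter": self.n_iter,
            "active_set": self.active_set.tolist(),
        }


def find_active_constraints(params: ModelParameters, score_theta: np.ndarray,
                            theta_tol: float = ACTIVE_THETA_TOL,
                            grad_eps: float = ACTIVE_GRAD_EPS) -> np.ndarray:
    """Indices u with theta_u ~ 0 held down by a negative gradient."""
    return np.flatnonzero((params.theta < theta_tol) & (score_theta < -grad_eps))


def sandwich_covariance(fit: FitResult,
                        workspace: LikelihoodWorkspace | None = None) -> np.ndarray:
    """Fill in ``fit.covariance`` (and ``fit.active_set``); returns the matrix."""
    ws = workspace or fit.workspace
    if ws is None:
        raise ValueError("a likelihood workspace is required")
    params = fit.params
    p, q, m = params.p, params.q, params.m
    _, _, g_theta = ws.score_blocks(params, fit.lam)
    active = find_active_constraints(params, g_theta)
    fit.active_set = active

    H_l = ws.hessian(params, lam=0.0, penalized=False)
    M = -H_l
    P = np.zeros_like(M)
    P[p + q:, p + q:] = 2.0 * fit.lam * ws.R
    dim = p + q + m
    keep = np.setdiff1d(np.arange(dim), p + q + active)
    A = (M + P)[np.ix_(keep, keep)]
    Mk = M[np.ix_(keep, keep)]
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        warnings.warn("singular reduced information: using pseudo-inverse")
        Ainv = np.linalg.pinv(A)
    # clip tiny negative curvature of the unpenalized information (it is
    # evaluated at the *penalized* optimum) so the sandwich is PSD
    w, V = np.linalg.eigh(0.5 * (Mk + Mk.T))
    Mk = (V * np.maximum(w, 0.0)) @ V.T
    cov_red = Ainv @ Mk @ Ainv
    cov = np.zeros((dim, dim))
    cov[np.ix_(keep, keep)] = 0.5 * (cov_red + cov_red.T)
    fit.covariance = cov
    return cov


def wald_table(fit: FitResult, x_names=None, z_names=None) -> pd.DataFrame:
    """Per-coefficient Wald summary with OR (incidence) / HR (latency) columns."""
    if fit.covariance is None:
        raise ValueError("covariance not computed; call sandwich_covariance first")
    params = fit.params
    p, q = params.p, params.q
    z_names = list(z_names) if z_names else (
        ["(intercept)"] + [f"z{j}" for j in range(1, p)])
    x_names = list(x_names) if x_names else [f"x{j+1}" for j in range(q)]
    rows = []
    se_all = np.sqrt(np.maximum(np.diag(fit.covariance), 0.0))
    if params.beta is not None:
        for j in range(p):
            rows.append(("incidence", z_names[j], params.beta[j], se_all[j]))
    for j in range(q):
        rows.append(("latency", x_names[j], params.gamma[j], se_all[p + j]))
    out = []
    for part, name, est, se in rows:
        if se > 0:
            zval = est / se
            pval = 2.0 * stats.norm.sf(abs(zval))
        else:
            zval, pval = np.nan, np.nan
        out.append({
            "model": part, "term": name, "estimate": est, "se": se,
            "z": zval, "p_value": pval,
            "ratio": np.exp(est),
            "ci_low": np.exp(est - Z975 * se) if se > 0 else np.nan,
            "ci_high": np.exp(est + Z975 * se) if se > 0 else np.nan,
        })
    return pd.DataFrame(out)


def _curve_frame(times, est, se, lo, hi) -> pd.DataFrame:
    return pd.DataFrame({"time": times, "estimate": est, "se": se,
                         "lo95": lo, "hi95": hi})


def baseline_hazard_curve(fit: FitResult, times) -> pd.DataFrame:
    """h0_hat(t) with point-wise delta-method 95% CI (floored at 0)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    psi = fit.basis.eval_m(times)
    h = psi @ fit.params.theta
    cov_t = fit.theta_covariance
    var = np.einsum("ij,jk,ik->i", psi, cov_t, psi)
    se = np.sqrt(np.maximum(var, 0.0))
    lo = np.maximum(h - Z975 * se, 0.0)
    hi = h + Z975 * se
    return _curve_frame(times, h, se, lo, hi)


def baseline_survival_curve(fit: FitResult, times,
                            transform: str = "plain") -> pd.DataFrame:
    """S0_hat(t) = exp(-Psi(t)' theta_hat) with point-wise 95% CI.

    ``transform='loglog'`` builds the interval on the log(-log S) scale.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    Psi = fit.basis.eval_i(times)
    H0 = Psi @ fit.params.theta
    S0 = np.exp(-H0)
    grad = -S0[:, None] * Psi  # dS0/dtheta
    cov_t = fit.theta_covariance
    var = np.einsum("ij,jk,ik->i", grad, cov_t, grad)
    se = np.sqrt(np.maximum(var, 0.0))
    lo, hi = _survival_ci(S0, H0, se, transform)
    return _curve_frame(times, S0, se, lo, hi)


def _survival_ci(S, H, se_S, transform):
    if transform == "loglog":
        with np.errstate(divide="ignore", invalid="ignore"):
            # se of log(-log S) = se(S) / (S |log S|)
            se_t = np.where((S > 0) & (S < 1) & (H > 0),
                            se_S / np.maximum(S * H, 1e-300), 0.0)
            loglogS = np.log(np.maximum(H, 1e-300))
            lo = np.exp(-np.exp(loglogS + Z975 * se_t))
            hi = np.exp(-np.exp(loglogS - Z975 * se_t))
        lo = np.where(se_t == 0, S, lo)
        hi = np.where(se_t == 0, S, hi)
        return np.minimum(lo, hi), np.maximum(lo, hi)
    lo = np.clip(S - Z975 * se_S, 0.0, 1.0)
    hi = np.clip(S + Z975 * se_S, 0.0, 1.0)
    return lo, hi


def population_survival_gradient(fit: FitResult, x, z, times):
    """Analytic gradient of Spop(t | x, z) w.r.t. (beta, gamma, theta)."""
    params = fit.params
    x = np.asarray(x, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    Psi = fit.basis.eval_i(times)
    mu = float(np.exp(x @ params.gamma))
    H = Psi @ params.theta
    S = np.exp(-H * mu)
    nt = times.size
    if params.beta is None:
        pi = 1.0
        g_beta = np.empty((nt, 0))
    else:
        z = np.asarray(z, dtype=float)
        pi = float(incidence_prob(z, params.beta))
        g_beta = ((S - 1.0) * pi * (1.0 - pi))[:, None] * z[None, :]
    dS_dgamma = (-S * H * mu)[:, None] * x[None, :]
    dS_dtheta = (-S * mu)[:, None] * Psi
    grad = np.hstack([g_beta, pi * dS_dgamma, pi * dS_dtheta])
    Spop = pi * S + (1.0 - pi)
    return Spop, grad


def population_survival_curve(fit: FitResult, x, z, times,
                              transform: str = "plain") -> pd.DataFrame:
    """Spop_hat(t | x, z) with point-wise delta-method 95% CI."""
    if fit.covariance is None:
        raise ValueError("covariance not computed")
    Spop, grad = population_survival_gradient(fit, x, z, times)
    var = np.einsum("ij,jk,ik->i", grad, fit.covariance, grad)
    se = np.sqrt(np.maximum(var, 0.0))
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if transform == "loglog":
        H = -np.log(np.maximum(Spop, 1e-300))
        lo, hi = _survival_ci(Spop, H, se, "loglog")
    else:
        lo, hi = _survival_ci(Spop, None, se, "plain")
    return _curve_frame(times, Spop, se, lo, hi)
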