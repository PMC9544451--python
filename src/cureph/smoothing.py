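"""Automatic smoothing-parameter selection by approximate marginal likelihood.

The quadratic penalty lambda * theta' R theta corresponds to a normal prior
theta ~ N(0, sigma2 R^-1) with sigma2 = 1 / (2 lambda).  Laplace-approximating
the marginal likelihood of sigma2 and maximizing gives the fixed-point update

    sigma2_hat = theta_hat' R theta_hat / (m - nu),
    nu = tr{ (G_hat + Q(sigma2))^-1 Q(sigma2) },

where G_hat is the negative Hessian of the (unpenalized) log-likelihood at
the current estimates and Q is block-diagonal with zeros for (beta, gamma)
and R / sigma2 for theta.  nu plays the role of the effective model degrees
of freedom.  The driver alternates (a) an inner penalized fit at the current
lambda and (b) the sigma2 update, stopping when two consecutive nu values
differ by less than 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .data import Dataset
from .likelihood import LikelihoodWorkspace, ModelParameters
from .optimize import OptimizerConfig, fit, initial_parameters
from .splines import SplineBasis

__all__ = ["SmoothingConfig", "effective_df", "select_smoothing"]

SIGMA2_MIN = 1e-8
SIGMA2_MAX = 1e8


@dataclass
class SmoothingConfig:
    outer_max: int = 20
    nu_tol: float = 1.0           # stop when |nu_new - nu_old| < 1
    theta_only: bool = False      # use only the theta block of G_hat
    nu_init_frac: float = 0.5     # target nu/m for the initial sigma2


def effective_df(G_hat: np.ndarray, R: np.ndarray, sigma2: float,
                 n_fixed: int) -> float:
    """nu = trace((G_hat + Q)^-1 Q) with Q = blockdiag(0_{n_fixed}, R/sigma2)."""
    dim = G_hat.shape[0]
    m = R.shape[0]
    if n_fixed + m != dim:
        raise ValueError("dimension mismatch between G_hat and R")
    Q = np.zeros_like(G_hat)
    Q[n_fixed:, n_fixed:] = R / sigma2
    A = G_hat + Q
    try:
        sol = np.linalg.solve(A, Q)
    except np.linalg.LinAlgError:
        warnings.warn("singular G_hat + Q: adding 1e-10 ridge")
        sol = np.linalg.solve(A + 1e-10 * np.eye(dim), Q)
    nu = float(np.trace(sol))
    # round-off guard: nu is a trace of a product of PSD-like matrices
    return min(max(nu, 0.0), float(m))


def _nu_for(ws: LikelihoodWorkspace, params: ModelParameters, sigma2: float,
            theta_only: bool) -> float:
    G = -ws.hessian(params, lam=0.0, penalized=False)
    n_fixed = params.p + params.q
    if theta_only:
        G = G[n_fixed:, n_fixed:]
        n_fixed = 0
    return effective_df(G, ws.R, sigma2, n_fixed)


def _log_marginal(ws: LikelihoodWorkspace, params: ModelParameters,
                  sigma2: float, m: int) -> float:
    """Laplace-approximate log marginal likelihood of sigma2 (up to const)."""
    G = -ws.hessian(params, lam=0.0, penalized=False)
    n_fixed = params.p + params.q
    Q = np.zeros_like(G)
    Q[n_fixed:, n_fixed:] = ws.R / sigma2
    sign, logdet = np.linalg.slogdet(G + Q)
    if sign <= 0:
        return -np.inf
    pen = float(params.theta @ ws.R @ params.theta)
    return (-0.5 * m * np.log(sigma2) + ws.loglik(params)
            - pen / (2.0 * sigma2) - 0.5 * logdet)


def select_smoothing(dataset: Dataset, basis: SplineBasis,
                     opt_config: OptimizerConfig | None = None,
                     smooth_config: SmoothingConfig | None = None,
                     init: ModelParameters | None = None,
                     cure: bool = True,
                     workspace: LikelihoodWorkspace | None = None):
    """Fit with automatically selected smoothing parameter.

    Returns a :class:`cureph.inference.FitResult` whose ``lam``, ``sigma2``
    and ``nu`` fields reflect the converged marginal-likelihood solution;
    ``nu`` is recomputed once at the final estimates.
    """
    cfg = opt_config or OptimizerConfig()
    scfg = smooth_config or SmoothingConfig()
    ws = workspace or LikelihoodWorkspace(dataset, basis)
    m = ws.m

    params0 = init.copy() if init is not None else initial_parameters(
        ws, cure=cure, boundary_survival=cfg.init_boundary_survival)
    # initialize sigma2 so the effective degrees of freedom start mid-range
    # (nu ~ m/2): an interior starting point for the fixed-point iteration.
    # Extreme starts (penalty negligible or overwhelming) can trap the
    # sigma2 update near a degenerate self-consistent state.
    G0 = -ws.hessian(params0, lam=0.0, penalized=False)
    target = scfg.nu_init_frac * m
    lo, hi = np.log(SIGMA2_MIN), np.log(SIGMA2_MAX)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        nu0 = effective_df(G0, ws.R, np.exp(mid), params0.p + params0.q)
        if abs(nu0 - target) < 0.05:
            break
        lo, hi = (mid, hi) if nu0 > target else (lo, mid)
    sigma2 = float(np.exp(mid))
    lam = 1.0 / (2.0 * sigma2)

    nu_old = np.inf
    result = None
    params = params0
    best = None   # (lm value, sigma2, params snapshot)
    # the MI warm-up only matters for the first, cold-started inner fit;
    # later fits resume from the previous optimum
    warm_cfg = dc_replace(cfg, theta_newton_warmup=0)
    for outer in range(scfg.outer_max):
        result = fit(dataset, basis, lam=lam, config=cfg if outer == 0 else warm_cfg,
                     init=params, cure=cure, workspace=ws)
        params = result.params
        lm_val = _log_marginal(ws, params, sigma2, m)
        if best is None or lm_val > best[0]:
            best = (lm_val, sigma2, params.copy())
        nu = _nu_for(ws, params, sigma2, scfg.theta_only)
        pen = float(params.theta @ ws.R @ params.theta)
        if m - nu <= 0:
            warnings.warn("m - nu <= 0: stopping smoothing iterations")
            break
        sigma2_new = pen / (m - nu)
        if sigma2_new <= SIGMA2_MIN:
            sigma2_new = SIGMA2_MIN
        # damp the fixed-point update: at most one order of magnitude per
        # outer iteration, guarding against runaway to either extreme
        sigma2_new = float(np.clip(sigma2_new, sigma2 / 10.0, sigma2 * 10.0))
        sigma2 = min(max(sigma2_new, SIGMA2_MIN), SIGMA2_MAX)
        lam = 1.0 / (2.0 * sigma2)
        if abs(nu - nu_old) < scfg.nu_tol:
            nu_old = nu
            break
        nu_old = nu

    # if the fixed point drifted to a state with lower marginal likelihood
    # than an earlier iterate, return to the best visited sigma2
    if best is not None and np.isfinite(best[0]):
        lm_last = _log_marginal(ws, params, sigma2, m)
        if best[0] > lm_last + 1e-8:
            sigma2 = best[1]
            lam = 1.0 / (2.0 * sigma2)
            params = best[2]

    # final refit at the converged lambda, then recompute nu consistently
    result = fit(dataset, basis, lam=lam, config=warm_cfg, init=params,
                 cure=cure, workspace=ws)
    nu_final = _nu_for(ws, result.params, sigma2, scfg.theta_only)
    result.sigma2 = sigma2
    result.lam = lam
    result.nu = nu_final
    result.outer_iter = outer + 1
    return result
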