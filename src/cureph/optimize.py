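"""Constrained maximization of the penalized likelihood.

One sweep of the algorithm performs three block updates:

1. Newton step for the incidence parameters beta, with Armijo backtracking
   (ridge-damped when the beta Hessian block is not negative definite);
2. Newton step for the latency parameters gamma, evaluated at the freshly
   updated beta;
3. a multiplicative-iterative (MI) step for the spline coefficients theta:

       theta_new = theta + omega * diag(theta_u / d_u) * grad_theta(Phi)

   with d_u = [negative part of dl/dtheta_u] + lambda * [positive part of
   dJ/dtheta_u] + xi.  For omega <= 1 this preserves theta >= 0 structurally
   (no projection), and coefficients resting at 0 with negative gradient stay
   at 0 — the active constraints of the KKT system.

Sweeps repeat until the parameter change is negligible or the KKT conditions
hold: zero gradients for beta/gamma and for the positive theta components,
non-positive gradients for theta components at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .data import CensoringType, Dataset
from .likelihood import LikelihoodWorkspace, ModelParameters
from .splines import SplineBasis

__all__ = ["OptimizerConfig", "IterationTrace", "fit",
           "update_beta", "update_gamma", "update_theta", "initial_parameters"]


@dataclass
class OptimizerConfig:
    max_iter: int = 2000
    tol_param: float = 1e-6       # sup-norm parameter change
    tol_kkt: float = 1e-5         # gradient threshold (per-subject scale, see fit)
    armijo_rho: float = 0.5
    armijo_c: float = 1e-4
    max_halvings: int = 30
    xi: float = 1e-3              # MI denominator guard
    ridge_init: float = 1e-4
    theta_newton: bool = True     # Newton acceleration on the free theta set
    theta_newton_warmup: int = 50  # pure-MI sweeps before acceleration starts
    init_boundary_survival: float = 1e-4  # S0(b) implied by the theta start

    def __post_init__(self):
        if not (0.0 < self.armijo_rho < 1.0):
            raise ValueError("armijo_rho must be in (0, 1)")
        for name in ("max_iter", "tol_param", "tol_kkt", "armijo_c", "xi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "OptimizerConfig":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class IterationTrace:
    iteration: int
    phi: float
    omega1: float
    omega2: float
    omega3: float
    kkt: float


def initial_parameters(ws: LikelihoodWorkspace, cure: bool = True,
                       boundary_survival: float = 1e-4) -> ModelParameters:
    """Starting values with a deliberately heavy baseline hazard.

    beta starts at (logit of the non-right-censored fraction, 0, ...) and
    gamma at 0.  theta starts at the constant -ln(boundary_survival)/m, so
    the implied susceptible survival S0 almost vanishes at the right
    boundary.  The mixture likelihood is multimodal: starting with a light
    hazard lets the logistic part absorb late right-censored susceptible
    subjects and the fit can lock into a spurious mode with a collapsed
    tail hazard, whereas shrinking an over-heavy hazard toward the data is
    fast for the multiplicative update and reliably lands in the
    substantive mode (a soft analogue of the classical zero-tail
    constraint of cure models).
    """
    d = ws.dataset
    m = ws.m
    n0 = d.n0
    frac = min(max(n0 / d.n, 1e-3), 1 - 1e-3)
    beta = None
    if cure and d.p > 0:
        beta = np.zeros(d.p)
        beta[0] = np.log(frac / (1.0 - frac))
    # exactly-constant initial hazard c with S0(b) = boundary_survival;
    # theta proportional to the knot-span weights keeps the start in the
    # null space of the roughness penalty even on uneven knots
    basis = ws.basis
    c = -np.log(boundary_survival) / (basis.b - basis.a)
    theta = np.maximum(c * basis.span_weights, 1e-10)
    return ModelParameters(beta, np.zeros(d.q), theta)


def _newton_direction(H: np.ndarray, g: np.ndarray, ridge0: float) -> np.ndarray:
    """Ascent direction solving (-H + tau I) d = g, damping until SPD."""
    M = -H
    tau = 0.0
    for _ in range(40):
        try:
            cf = cho_factor(M + tau * np.eye(M.shape[0]), lower=True)
            d = cho_solve(cf, g)
            if d @ g > 0 or not np.any(g):
                return d
        except LinAlgError:
            pass
        tau = ridge0 if tau == 0.0 else 2.0 * tau
    return g / max(np.max(np.abs(np.diag(M))), 1.0)  # gradient fallback


def _armijo(ws, params, lam, direction_setter, g_dot_d, phi_old, cfg):
    """Backtracking line search; returns (accepted params, omega, phi)."""
    omega = 1.0
    for _ in range(cfg.max_halvings):
        cand = direction_setter(omega)
        phi_new = ws.penalized_loglik(cand, lam)
        if phi_new >= phi_old + cfg.armijo_c * omega * g_dot_d and np.isfinite(phi_new):
            return cand, omega, phi_new
        omega *= cfg.armijo_rho
    return params, 0.0, phi_old


def update_beta(ws, params, lam, cfg):
    """Newton-with-line-search update of beta. Returns (params, omega, phi)."""
    if params.beta is None:
        return params, 0.0, ws.penalized_loglik(params, lam)
    g_beta, _, _ = ws.score_blocks(params, lam)
    phi_old = ws.penalized_loglik(params, lam)
    if np.max(np.abs(g_beta)) == 0.0:
        return params, 0.0, phi_old
    Hbb, _, _ = _beta_gamma_hessian(ws, params, lam)
    d = _newton_direction(Hbb, g_beta, cfg.ridge_init)

    def setter(omega):
        out = params.copy()
        out.beta = params.beta + omega * d
        return out

    return _armijo(ws, params, lam, setter, g_beta @ d, phi_old, cfg)


def update_gamma(ws, params, lam, cfg):
    """Newton-with-line-search update of gamma. Returns (params, omega, phi)."""
    _, g_gamma, _ = ws.score_blocks(params, lam)
    phi_old = ws.penalized_loglik(params, lam)
    if g_gamma.size == 0 or np.max(np.abs(g_gamma)) == 0.0:
        return params, 0.0, phi_old
    _, Hgg, _ = _beta_gamma_hessian(ws, params, lam)
    d = _newton_direction(Hgg, g_gamma, cfg.ridge_init)

    def setter(omega):
        out = params.copy()
        out.gamma = params.gamma + omega * d
        return out

    return _armijo(ws, params, lam, setter, g_gamma @ d, phi_old, cfg)


def _beta_gamma_hessian(ws, params, lam):
    # Only the (beta, gamma) diagonal blocks are needed per sweep; the full
    # Hessian is assembled once at convergence for inference/smoothing.
    Hbb, Hgg = ws.hessian_beta_gamma(params)
    return Hbb, Hgg, None


def update_theta(ws, params, lam, cfg):
    """Multiplicative-iterative update of theta. Returns (params, omega, phi)."""
    pos, neg = ws.theta_score_parts(params)
    pen_grad = 2.0 * lam * (ws.R @ params.theta)
    g_theta = pos - neg - pen_grad
    phi_old = ws.penalized_loglik(params, lam)
    du = neg + np.maximum(pen_grad, 0.0) + cfg.xi
    step = params.theta / du * g_theta
    if np.max(np.abs(step)) == 0.0:
        return params, 0.0, phi_old

    def setter(omega):
        out = params.copy()
        out.theta = np.maximum(params.theta + omega * step, 0.0)
        return out

    return _armijo(ws, params, lam, setter, g_theta @ step, phi_old, cfg)


def _accelerate_theta(ws, params, lam, cfg):
    """Constrained Newton refinement on the free theta components.

    The MI update owns the active-set dynamics (coefficients at 0 with a
    negative gradient stay at 0); this step merely speeds up the interior
    components, whose strongly overlapping spline supports make pure
    gradient-type updates zigzag.  The Newton direction is scaled back so
    the iterate never leaves theta >= 0 (no projection), and is accepted
    only if it increases Phi.
    """
    pos, neg = ws.theta_score_parts(params)
    g_theta = pos - neg - 2.0 * lam * (ws.R @ params.theta)
    free = (params.theta > 0.0) | (g_theta > 0.0)
    phi_old = ws.penalized_loglik(params, lam)
    if free.sum() == 0:
        return params, phi_old
    p, q = params.p, params.q
    H = ws.hessian(params, lam, penalized=True)
    Htt = H[p + q:, p + q:]
    idx = np.flatnonzero(free)
    # inner active-set rounds: components whose Newton step would cross zero
    # are dropped and the direction re-solved, so a few vanishing
    # coefficients cannot truncate the step of every interior component
    for _ in range(4):
        d_free = _newton_direction(Htt[np.ix_(idx, idx)], g_theta[idx],
                                   cfg.ridge_init)
        crossing = d_free < -params.theta[idx]
        if not np.any(crossing) or crossing.all():
            break
        idx = idx[~crossing]
    if idx.size == 0 or d_free @ g_theta[idx] <= 0:
        return params, phi_old
    d = np.zeros_like(params.theta)
    d[idx] = d_free
    # fraction-to-boundary rule: the accelerated step stays strictly interior
    # (each component shrinks at most 95%); only the MI update may park a
    # coefficient exactly at zero.  Without this the Newton step can slam
    # tail coefficients onto the boundary and lock in a spurious local
    # maximum with a collapsed tail hazard.
    shrink = d < 0
    omega_max = 1.0
    if np.any(shrink):
        omega_max = min(1.0, 0.95 * float(
            np.min(params.theta[shrink] / -d[shrink])))
    if omega_max <= 0:
        return params, phi_old
    omega = omega_max
    gd = g_theta @ d
    for _ in range(cfg.max_halvings):
        cand = params.copy()
        cand.theta = np.maximum(params.theta + omega * d, 0.0)
        phi_new = ws.penalized_loglik(cand, lam)
        if np.isfinite(phi_new) and phi_new >= phi_old + cfg.armijo_c * omega * gd:
            return cand, phi_new
        omega *= cfg.armijo_rho
    return params, phi_old


def kkt_residual(ws, params, lam, boundary_tol: float = 1e-3) -> float:
    """Largest violation of the first-order conditions of the constrained fit.

    theta components below ``boundary_tol`` with a negative gradient are
    treated as (approaching) active constraints: the multiplicative update
    drives them to zero only geometrically, so insisting on a small gradient
    there would stall convergence over a statistically irrelevant tail.
    """
    g_beta, g_gamma, g_theta = ws.score_blocks(params, lam)
    res = np.max(np.abs(g_gamma)) if g_gamma.size else 0.0
    if g_beta is not None and g_beta.size:
        res = max(res, np.max(np.abs(g_beta)))
    active_like = (params.theta < boundary_tol) & (g_theta < 0.0)
    if np.any(~active_like):
        res = max(res, np.max(np.abs(g_theta[~active_like])))
    return float(res)


def fit(dataset: Dataset, basis: SplineBasis, lam: float = 0.0,
        config: OptimizerConfig | None = None,
        init: ModelParameters | None = None,
        cure: bool = True,
        workspace: LikelihoodWorkspace | None = None,
        keep_trace: bool = False):
    """Maximize Phi(eta) = l(eta) - lambda theta' R theta subject to theta >= 0.

    Returns a :class:`cureph.inference.FitResult` (without covariance; use
    :func:`cureph.inference.sandwich_covariance` or the smoothing driver to
    complete it).  ``cure=False`` pins pi == 1 (plain penalized Cox model).
    """
    from .inference import FitResult  # local import avoids a cycle at import time

    cfg = config or OptimizerConfig()
    ws = workspace or LikelihoodWorkspace(dataset, basis)
    if dataset.n0 == 0:
        raise ValueError("no non-right-censored records: model unidentifiable")
    params = init.copy() if init is not None else initial_parameters(
        ws, cure=cure, boundary_survival=cfg.init_boundary_survival)

    trace: list[IterationTrace] = []
    phi = ws.penalized_loglik(params, lam)
    converged = False
    # gradient tolerance scales with n: the score is a sum over subjects
    kkt_tol = cfg.tol_kkt * max(1.0, dataset.n)
    for k in range(cfg.max_iter):
        old_vec = params.pack()
        params, w1, phi = update_beta(ws, params, lam, cfg)
        params, w2, phi = update_gamma(ws, params, lam, cfg)
        params, w3, phi = update_theta(ws, params, lam, cfg)
        if cfg.theta_newton and k >= cfg.theta_newton_warmup:
            params, phi = _accelerate_theta(ws, params, lam, cfg)
        delta = np.max(np.abs(params.pack() - old_vec))
        res = kkt_residual(ws, params, lam)
        if keep_trace:
            trace.append(IterationTrace(k, phi, w1, w2, w3, res))
        if res < kkt_tol or delta < cfg.tol_param:
            converged = True
            break
    if not converged:
        warnings.warn(f"fit did not converge in {cfg.max_iter} iterations "
                      f"(KKT residual {res:.3g})")

    return FitResult(
        params=params, basis=basis,
        loglik=ws.loglik(params),
        penloglik=ws.penalized_loglik(params, lam),
        lam=lam, sigma2=(np.inf if lam == 0 else 1.0 / (2.0 * lam)), nu=np.nan,
        active_set=np.array([], dtype=int), covariance=None,
        converged=converged, n_iter=k + 1, trace=trace, workspace=ws)
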