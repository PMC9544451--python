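"""Log-likelihood, penalized likelihood, and analytic derivatives.

Model
-----
Incidence (probability of being susceptible / non-cured):
    pi(z) = expit(z' beta)
Latency (susceptible subjects), Cox proportional hazards:
    h(t | x) = h0(t) exp(x' gamma),   h0(t) = sum_u theta_u psi_u(t),
    S(t | x) = exp(-H0(t) exp(x' gamma)),   H0(t) = sum_u theta_u Psi_u(t)
Population survival:
    Spop(t | x, z) = pi(z) S(t | x) + (1 - pi(z))

Log-likelihood contributions by censoring type (t = observed time(s)):
    event:    ln pi + ln h0(t) + x' gamma + ln S(t | x)
    right:    ln(1 - pi + pi S(t | x))
    left:     ln pi + ln(1 - S(t | x))
    interval: ln pi + ln(S(t_L | x) - S(t_R | x))

The penalized objective is Phi = l - lambda * theta' R theta.

All derivatives (score vector and full Hessian over eta = (beta, gamma,
theta)) are analytic; they are exercised against central finite differences
in the test suite.  Probabilities and densities inside logarithms are floored
at 1e-12 so that line searches remain finite on degenerate intervals.

Setting ``beta=None`` in :class:`ModelParameters` pins pi == 1 (no cured
fraction), reducing the model to a plain penalized Cox model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .data import CensoringType, Dataset
from .splines import SplineBasis

__all__ = [
    "ModelParameters",
    "LikelihoodWorkspace",
    "incidence_prob",
    "conditional_survival",
    "population_survival",
]

LIK_FLOOR = 1e-12


@dataclass
class ModelParameters:
    """eta = (beta, gamma, theta); theta >= 0 elementwise.

    ``beta is None`` disables the incidence model (pi == 1).
    """

    beta: Optional[np.ndarray]
    gamma: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta < 0):
            raise ValueError("theta must be non-negative")

    @property
    def p(self) -> int:
        return 0 if self.beta is None else self.beta.size

    @property
    def q(self) -> int:
        return self.gamma.size

    @property
    def m(self) -> int:
        return self.theta.size

    def pack(self) -> np.ndarray:
        parts = [] if self.beta is None else [self.beta]
        return np.concatenate(parts + [self.gamma, self.theta])

    def unpack_like(self, vec: np.ndarray) -> "ModelParameters":
        p, q = self.p, self.q
        beta = vec[:p] if self.beta is not None else None
        return ModelParameters(beta, vec[p:p + q], vec[p + q:])

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            None if self.beta is None else self.beta.copy(),
            self.gamma.copy(), self.theta.copy())


def incidence_prob(z, beta) -> np.ndarray:
    """pi(z) = expit(z' beta), overflow-safe."""
    z = np.asarray(z, dtype=float)
    return expit(z @ np.asarray(beta, dtype=float))


def conditional_survival(t, x, gamma, theta, basis: SplineBasis) -> np.ndarray:
    """S(t | susceptible, x) = exp(-H0(t) e^{x'gamma})."""
    theta = np.asarray(theta, dtype=float)
    H0 = basis.eval_i(t) @ theta
    mu = np.exp(np.asarray(x, dtype=float) @ np.asarray(gamma, dtype=float))
    return np.exp(-H0 * mu)


def population_survival(t, x, z, params: ModelParameters, basis: SplineBasis) -> np.ndarray:
    """Spop = pi S + (1 - pi); bounded below by the cure probability 1 - pi."""
    S = conditional_survival(t, x, params.gamma, params.theta, basis)
    if params.beta is None:
        return S
    pi = incidence_prob(z, params.beta)
    return pi * S + (1.0 - pi)


class LikelihoodWorkspace:
    """Precomputed spline matrices and grouped views of one dataset.

    All spline evaluations happen once at construction (observation times
    never change during a fit), so likelihood/score/Hessian evaluations are
    pure matrix algebra.
    """

    def __init__(self, dataset: Dataset, basis: SplineBasis):
        self.dataset = dataset
        self.basis = basis
        st = dataset.status
        self.ie = np.flatnonzero(st == CensoringType.EVENT)
        self.ir = np.flatnonzero(st == CensoringType.RIGHT)
        self.il = np.flatnonzero(st == CensoringType.LEFT)
        self.ii = np.flatnonzero(st == CensoringType.INTERVAL)
        self.X = dataset.X
        self.Z = dataset.Z
        self.psi_e = basis.eval_m(dataset.t_left[self.ie])
        self.Psi_e = basis.eval_i(dataset.t_left[self.ie])
        self.Psi_r = basis.eval_i(dataset.t_left[self.ir])
        self.Psi_l = basis.eval_i(dataset.t_right[self.il])
        self.Psi_iL = basis.eval_i(dataset.t_left[self.ii])
        self.Psi_iR = basis.eval_i(dataset.t_right[self.ii])
        self.m = basis.m
        self.R = basis.penalty_matrix()
        self._cache_key = None
        self._comp = None

    # -- parameter-dependent common quantities --------------------------
    def _components(self, params: ModelParameters) -> dict:
        key = (None if params.beta is None else params.beta.tobytes(),
               params.gamma.tobytes(), params.theta.tobytes())
        if key == self._cache_key:
            return self._comp
        th, ga = params.theta, params.gamma
        c = {}
        mu = np.exp(self.X @ ga)
        c["mu"] = mu
        if params.beta is None:
            c["pi"] = None
        else:
            c["pi"] = expit(self.Z @ params.beta)
        # event group
        c["h"] = np.maximum(self.psi_e @ th, LIK_FLOOR)
        c["He"] = self.Psi_e @ th
        # right group
        HLr = self.Psi_r @ th
        SLr = np.exp(-HLr * mu[self.ir])
        c["HLr"], c["SLr"] = HLr, SLr
        pir = 1.0 if c["pi"] is None else c["pi"][self.ir]
        c["gden"] = np.maximum(1.0 - pir + pir * SLr, LIK_FLOOR)
        # left group
        HRl = self.Psi_l @ th
        SRl = np.exp(-HRl * mu[self.il])
        c["HRl"], c["SRl"] = HRl, SRl
        c["Dden"] = np.maximum(1.0 - SRl, LIK_FLOOR)
        # interval group
        HLi = self.Psi_iL @ th
        HRi = self.Psi_iR @ th
        mui = mu[self.ii]
        SLi = np.exp(-HLi * mui)
        SRi = np.exp(-HRi * mui)
        c["HLi"], c["HRi"], c["SLi"], c["SRi"] = HLi, HRi, SLi, SRi
        c["Wden"] = np.maximum(SLi - SRi, LIK_FLOOR)
        self._cache_key, self._comp = key, c
        return c

    # -- objective -------------------------------------------------------
    def loglik(self, params: ModelParameters) -> float:
        c = self._components(params)
        mu, pi = c["mu"], c["pi"]
        ll = 0.0
        if pi is not None:
            lp = np.log(np.maximum(pi, LIK_FLOOR))
            ll += lp[self.ie].sum() + lp[self.il].sum() + lp[self.ii].sum()
        ll += (np.log(c["h"]) + self.X[self.ie] @ params.gamma
               - c["He"] * mu[self.ie]).sum()
        ll += np.log(c["gden"]).sum()
        ll += np.log(c["Dden"]).sum()
        ll += np.log(c["Wden"]).sum()
        return float(ll)

    def penalty(self, params: ModelParameters) -> float:
        return float(params.theta @ self.R @ params.theta)

    def penalized_loglik(self, params: ModelParameters, lam: float) -> float:
        return self.loglik(params) - lam * self.penalty(params)

    # -- score -----------------------------------------------------------
    def score_blocks(self, params: ModelParameters, lam: float):
        """Gradient of Phi split into (g_beta or None, g_gamma, g_theta).

        The theta block is also available decomposed via
        :meth:`theta_score_parts`.
        """
        c = self._components(params)
        mu = c["mu"]
        X, Z = self.X, self.Z

        g_beta = None
        if c["pi"] is not None:
            pi = c["pi"]
            g_beta = np.zeros(params.p)
            for idx in (self.ie, self.il, self.ii):
                if idx.size:
                    g_beta += (1.0 - pi[idx]) @ Z[idx]
            if self.ir.size:
                pir = pi[self.ir]
                w = pir * (1.0 - pir) * (c["SLr"] - 1.0) / c["gden"]
                g_beta += w @ Z[self.ir]

        g_gamma = np.zeros(params.q)
        if self.ie.size:
            g_gamma += (1.0 - c["He"] * mu[self.ie]) @ X[self.ie]
        if self.ir.size:
            pir = 1.0 if c["pi"] is None else c["pi"][self.ir]
            w = -pir * c["SLr"] * c["HLr"] * mu[self.ir] / c["gden"]
            g_gamma += w @ X[self.ir]
        if self.il.size:
            w = c["SRl"] * c["HRl"] * mu[self.il] / c["Dden"]
            g_gamma += w @ X[self.il]
        if self.ii.size:
            mui = mu[self.ii]
            w = mui * (c["SRi"] * c["HRi"] - c["SLi"] * c["HLi"]) / c["Wden"]
            g_gamma += w @ X[self.ii]

        pos, neg = self.theta_score_parts(params)
        g_theta = pos - neg - 2.0 * lam * (self.R @ params.theta)
        return g_beta, g_gamma, g_theta

    def theta_score_parts(self, params: ModelParameters):
        """Positive and negative parts of the unpenalized theta score.

        Returns (pos, neg), both elementwise >= 0, with
        d l / d theta = pos - neg.  The negative part feeds the d_u
        denominators of the multiplicative-iterative update.
        """
        c = self._components(params)
        mu = c["mu"]
        m = self.m
        pos = np.zeros(m)
        neg = np.zeros(m)
        if self.ie.size:
            pos += (1.0 / c["h"]) @ self.psi_e
            neg += mu[self.ie] @ self.Psi_e
        if self.ir.size:
            pir = 1.0 if c["pi"] is None else c["pi"][self.ir]
            neg += (pir * c["SLr"] * mu[self.ir] / c["gden"]) @ self.Psi_r
        if self.il.size:
            pos += (c["SRl"] * mu[self.il] / c["Dden"]) @ self.Psi_l
        if self.ii.size:
            mui = mu[self.ii]
            pos += (mui * c["SRi"] / c["Wden"]) @ self.Psi_iR
            neg += (mui * c["SLi"] / c["Wden"]) @ self.Psi_iL
        return pos, neg

    def score(self, params: ModelParameters, lam: float) -> np.ndarray:
        g_beta, g_gamma, g_theta = self.score_blocks(params, lam)
        parts = [] if g_beta is None else [g_beta]
        return np.concatenate(parts + [g_gamma, g_theta])

    # -- Hessian ---------------------------------------------------------
    def hessian(self, params: ModelParameters, lam: float = 0.0,
                penalized: bool = True) -> np.ndarray:
        """Full symmetric Hessian of Phi (or of l when penalized=False)."""
        c = self._components(params)
        mu = c["mu"]
        X, Z = self.X, self.Z
        p, q, m = params.p, params.q, self.m
        ndim = p + q + m
        H = np.zeros((ndim, ndim))
        sl_b = slice(0, p)
        sl_g = slice(p, p + q)
        sl_t = slice(p + q, ndim)

        def _wouter(A, w, B):
            return (A * w[:, None]).T @ B

        # ---- beta blocks ------------------------------------------------
        if p:
            pi = c["pi"]
            Hbb = np.zeros((p, p))
            for idx in (self.ie, self.il, self.ii):
                if idx.size:
                    Hbb += _wouter(Z[idx], -pi[idx] * (1.0 - pi[idx]), Z[idx])
            if self.ir.size:
                pir = pi[self.ir]
                SL, g = c["SLr"], c["gden"]
                A = pir * (1.0 - pir) * (SL - 1.0)
                w = (1.0 - 2.0 * pir) * pir * (1.0 - pir) * (SL - 1.0) / g \
                    - A * A / (g * g)
                Hbb += _wouter(Z[self.ir], w, Z[self.ir])
                # beta-gamma and beta-theta cross terms (right-censored only)
                HL, mur = c["HLr"], mu[self.ir]
                base = pir * SL * mur * (-(1.0 - pir) / g + A / (g * g))
                H[sl_b, sl_g] += _wouter(Z[self.ir], base * HL, X[self.ir])
                H[sl_b, sl_t] += _wouter(Z[self.ir], base, self.Psi_r)
            H[sl_b, sl_b] = Hbb

        # ---- gamma-gamma ------------------------------------------------
        Hgg = np.zeros((q, q))
        if self.ie.size:
            Hgg += _wouter(X[self.ie], -c["He"] * mu[self.ie], X[self.ie])
        if self.ir.size:
            pir = 1.0 if c["pi"] is None else c["pi"][self.ir]
            SL, HL, g, mur = c["SLr"], c["HLr"], c["gden"], mu[self.ir]
            B = -pir * SL * HL * mur
            w = -pir * HL * mur * SL * (1.0 - HL * mur) / g - B * B / (g * g)
            Hgg += _wouter(X[self.ir], w, X[self.ir])
        if self.il.size:
            SR, HR, D, mul = c["SRl"], c["HRl"], c["Dden"], mu[self.il]
            E = SR * HR * mul
            w = HR * mul * SR * (1.0 - HR * mul) / D - E * E / (D * D)
            Hgg += _wouter(X[self.il], w, X[self.il])
        if self.ii.size:
            SL, SR = c["SLi"], c["SRi"]
            HL, HR = c["HLi"], c["HRi"]
            W, mui = c["Wden"], mu[self.ii]
            G = mui * (SR * HR - SL * HL)
            Gp = HR * mui * SR * (1.0 - HR * mui) - HL * mui * SL * (1.0 - HL * mui)
            w = Gp / W - G * G / (W * W)
            Hgg += _wouter(X[self.ii], w, X[self.ii])
        H[sl_g, sl_g] = Hgg

        # ---- gamma-theta ------------------------------------------------
        Hgt = np.zeros((q, m))
        if self.ie.size:
            Hgt += -(X[self.ie] * mu[self.ie][:, None]).T @ self.Psi_e
        if self.ir.size:
            pir = 1.0 if c["pi"] is None else c["pi"][self.ir]
            SL, HL, g, mur = c["SLr"], c["HLr"], c["gden"], mu[self.ir]
            B = -pir * SL * HL * mur
            w = -pir * mur * SL * (1.0 - HL * mur) / g + B * pir * SL * mur / (g * g)
            Hgt += _wouter(X[self.ir], w, self.Psi_r)
        if self.il.size:
            SR, HR, D, mul = c["SRl"], c["HRl"], c["Dden"], mu[self.il]
            E = SR * HR * mul
            w = mul * SR * (1.0 - HR * mul) / D - E * SR * mul / (D * D)
            Hgt += _wouter(X[self.il], w, self.Psi_l)
        if self.ii.size:
            SL, SR = c["SLi"], c["SRi"]
            HL, HR = c["HLi"], c["HRi"]
            W, mui = c["Wden"], mu[self.ii]
            G = mui * (SR * HR - SL * HL)
            V = (mui * SR)[:, None] * self.Psi_iR - (mui * SL)[:, None] * self.Psi_iL
            T = ((mui * SR * (1.0 - HR * mui) / W)[:, None] * self.Psi_iR
                 - (mui * SL * (1.0 - HL * mui) / W)[:, None] * self.Psi_iL
                 - (G / (W * W))[:, None] * V)
            Hgt += X[self.ii].T @ T
        H[sl_g, sl_t] = Hgt

        # ---- theta-theta ------------------------------------------------
        Htt = np.zeros((m, m))
        if self.ie.size:
            P = self.psi_e / c["h"][:, None]
            Htt += -P.T @ P
        if self.ir.size:
            pir = 1.0 if c["pi"] is None else c["pi"][self.ir]
            SL, g, mur = c["SLr"], c["gden"], mu[self.ir]
            C = -pir * SL * mur
            w = pir * SL * mur * mur / g - C * C / (g * g)
            Htt += _wouter(self.Psi_r, w, self.Psi_r)
        if self.il.size:
            SR, D, mul = c["SRl"], c["Dden"], mu[self.il]
            F = SR * mul
            w = -SR * mul * mul / D - F * F / (D * D)
            Htt += _wouter(self.Psi_l, w, self.Psi_l)
        if self.ii.size:
            SL, SR = c["SLi"], c["SRi"]
            W, mui = c["Wden"], mu[self.ii]
            mu2 = mui * mui
            Htt += _wouter(self.Psi_iL, mu2 * SL / W, self.Psi_iL)
            Htt += _wouter(self.Psi_iR, -mu2 * SR / W, self.Psi_iR)
            V = ((mui * SR)[:, None] * self.Psi_iR
                 - (mui * SL)[:, None] * self.Psi_iL) / W[:, None]
            Htt += -V.T @ V
        if penalized:
            Htt = Htt - 2.0 * lam * self.R
        H[sl_t, sl_t] = Htt

        # symmetrise cross blocks
        H[sl_g, sl_b] = H[sl_b, sl_g].T
        H[sl_t, sl_b] = H[sl_b, sl_t].T
        H[sl_t, sl_g] = H[sl_g, sl_t].T
        return H

    def hessian_beta_gamma(self, params: ModelParameters):
        """Diagonal (beta, beta) and (gamma, gamma) Hessian blocks only.

        The penalty does not touch these blocks, so they are the same for l
        and Phi.  Used by the per-sweep Newton updates; the full Hessian is
        assembled once at convergence.
        """
        c = self._components(params)
        mu = c["mu"]
        X, Z = self.X, self.Z
        p, q = params.p, params.q

        def _wouter(A, w, B):
            return (A * w[:, None]).T @ B

        Hbb = None
        if p:
            pi = c["pi"]
            Hbb = np.zeros((p, p))
            for idx in (self.ie, self.il, self.ii):
                if idx.size:
                    Hbb += _wouter(Z[idx], -pi[idx] * (1.0 - pi[idx]), Z[idx])
            if self.ir.size:
                pir = pi[self.ir]
                SL, g = c["SLr"], c["gden"]
                A = pir * (1.0 - pir) * (SL - 1.0)
                w = (1.0 - 2.0 * pir) * pir * (1.0 - pir) * (SL - 1.0) / g \
                    - A * A / (g * g)
                Hbb += _wouter(Z[self.ir], w, Z[self.ir])

        Hgg = np.zeros((q, q))
        if self.ie.size:
            Hgg += _wouter(X[self.ie], -c["He"] * mu[self.ie], X[self.ie])
        if self.ir.size:
            pir = 1.0 if c["pi"] is None else c["pi"][self.ir]
            SL, HL, g, mur = c["SLr"], c["HLr"], c["gden"], mu[self.ir]
            B = -pir * SL * HL * mur
            w = -pir * HL * mur * SL * (1.0 - HL * mur) / g - B * B / (g * g)
            Hgg += _wouter(X[self.ir], w, X[self.ir])
        if self.il.size:
            SR, HR, D, mul = c["SRl"], c["HRl"], c["Dden"], mu[self.il]
            E = SR * HR * mul
            w = HR * mul * SR * (1.0 - HR * mul) / D - E * E / (D * D)
            Hgg += _wouter(X[self.il], w, X[self.il])
        if self.ii.size:
            SL, SR = c["SLi"], c["SRi"]
            HL, HR = c["HLi"], c["HRi"]
            W, mui = c["Wden"], mu[self.ii]
            G = mui * (SR * HR - SL * HL)
            Gp = HR * mui * SR * (1.0 - HR * mui) - HL * mui * SL * (1.0 - HL * mui)
            w = Gp / W - G * G / (W * W)
            Hgg += _wouter(X[self.ii], w, X[self.ii])
        return Hbb, Hgg

    def hessian_blocks(self, params: ModelParameters, lam: float):
        """(H_bb, H_gg, full H) of the penalized objective."""
        H = self.hessian(params, lam, penalized=True)
        p, q = params.p, params.q
        Hbb = H[:p, :p] if p else None
        Hgg = H[p:p + q, p:p + q]
        return Hbb, Hgg, H
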