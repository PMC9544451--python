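"""Cubic M-spline / I-spline bases for the baseline hazard.

The baseline hazard is approximated as h0(t) = sum_u theta_u psi_u(t) with
non-negative M-spline basis functions psi_u, so h0 >= 0 iff theta >= 0.  The
cumulative hazard uses the integrated (I-spline) basis, H0(t) =
sum_u theta_u Psi_u(t), with Psi_u non-decreasing from 0 at the left boundary
to 1 at the right boundary.

M-splines of order k are rescaled B-splines, M_u = k / (t_{u+k} - t_u) * B_u,
which normalises each basis function to unit integral; the I-splines are their
exact antiderivatives.  Beyond the right boundary the hazard is extended as a
constant (h0(t) = h0(b) for t > b) so the implied survival function remains
valid at follow-up times past the last observed time.

The roughness penalty matrix R has entries r_uv = integral of
psi_u''(t) psi_v''(t) dt, computed exactly by per-span Gauss-Legendre
quadrature (the integrand is piecewise polynomial).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .data import Dataset, pseudo_times

__all__ = ["SplineBasis", "place_knots"]

_DEDUP_TOL = 1e-10


@dataclass
class SplineBasis:
    """Knots, order and penalty matrix for the M-/I-spline hazard basis."""

    order: int
    interior_knots: np.ndarray
    boundary: tuple[float, float]

    def __post_init__(self):
        a, b = float(self.boundary[0]), float(self.boundary[1])
        if not a < b:
            raise ValueError("boundary must satisfy a < b")
        ik = np.sort(np.asarray(self.interior_knots, dtype=float))
        if ik.size and not (a < ik[0] and ik[-1] < b):
            raise ValueError("interior knots must lie strictly inside the boundary")
        self.interior_knots = ik
        self.boundary = (a, b)
        k = int(self.order)
        self.order = k
        # full (clamped) knot vector for B-splines of degree k-1
        self._knots = np.concatenate([np.full(k, a), ik, np.full(k, b)])
        # column scale turning B-splines into unit-integral M-splines
        span = self._knots[k:] - self._knots[:-k]
        self._scale = k / span
        self._bspl = BSpline(self._knots, np.eye(self.m), k - 1, extrapolate=True)
        self._ispl = self._bspl.antiderivative()
        self._R = None

    @property
    def m(self) -> int:
        """Basis dimension: number of interior knots + order."""
        return self.interior_knots.size + self.order

    @property
    def span_weights(self) -> np.ndarray:
        """Weights w_u = (t_{u+k} - t_u)/k; theta = c * w gives h0(t) = c exactly.

        Follows from the B-spline partition of unity: sum_u w_u psi_u(t) = 1
        on [a, b].
        """
        return 1.0 / self._scale

    @property
    def a(self) -> float:
        return self.boundary[0]

    @property
    def b(self) -> float:
        return self.boundary[1]

    # ------------------------------------------------------------------
    def eval_m(self, t) -> np.ndarray:
        """M-spline design matrix psi_u(t), shape (len(t), m), entries >= 0.

        t > b uses the constant-hazard extension psi(t) = psi(b); t < a
        (before the first observed time, where the hazard carries no
        likelihood information) evaluates to 0.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValueError("negative time")
        tc = np.clip(t, self.a, self.b)
        out = self._bspl(tc) * self._scale
        np.maximum(out, 0.0, out=out)  # clip B-spline round-off
        out[t < self.a] = 0.0
        return out

    def eval_i(self, t) -> np.ndarray:
        """I-spline design matrix Psi_u(t) in [0, 1] on [a, b].

        For t > b the cumulative hazard basis is extended linearly,
        Psi_u(t) = 1 + (t - b) psi_u(b); for t < a it is 0.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValueError("negative time")
        tc = np.clip(t, self.a, self.b)
        out = self._ispl(tc) * self._scale
        np.clip(out, 0.0, 1.0, out=out)
        over = t > self.b
        if np.any(over):
            psi_b = self._bspl(np.array([self.b])) * self._scale
            np.maximum(psi_b, 0.0, out=psi_b)
            out[over] = 1.0 + np.outer(t[over] - self.b, psi_b[0])
        out[t < self.a] = 0.0
        return out

    def eval_m_deriv2(self, t) -> np.ndarray:
        """Second derivatives psi_u''(t) (no extrapolation handling)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self._bspl.derivative(2)(t) * self._scale

    # ------------------------------------------------------------------
    def penalty_matrix(self) -> np.ndarray:
        """Roughness penalty R with r_uv = int psi_u'' psi_v'' dt (symmetric PSD)."""
        if self._R is not None:
            return self._R
        m = self.m
        if self.order < 3:
            warnings.warn("order < 3: second derivatives vanish, penalty is zero")
            self._R = np.zeros((m, m))
            return self._R
        spans = np.unique(np.concatenate([[self.a], self.interior_knots, [self.b]]))
        # psi'' is piecewise degree order-3; products have degree <= 2*(order-3):
        # 3-point Gauss-Legendre is exact up to degree 5 >= 2 for cubics.
        nodes, weights = np.polynomial.legendre.leggauss(max(3, self.order - 2))
        R = np.zeros((m, m))
        for lo, hi in zip(spans[:-1], spans[1:]):
            half = 0.5 * (hi - lo)
            ts = lo + half * (nodes + 1.0)
            D = self.eval_m_deriv2(ts)
            R += half * (D * weights[:, None]).T @ D
        self._R = 0.5 * (R + R.T)
        return self._R

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "order": self.order,
            "interior_knots": self.interior_knots.tolist(),
            "boundary": list(self.boundary),
        })

    @classmethod
    def from_json(cls, text: str) -> "SplineBasis":
        obj = json.loads(text)
        return cls(order=obj["order"],
                   interior_knots=np.asarray(obj["interior_knots"]),
                   boundary=tuple(obj["boundary"]))


def place_knots(d: Dataset, n_internal: int | str = "auto",
                order: int = 4) -> SplineBasis:
    """Construct a basis with data-driven knots.

    Boundary knots sit at the smallest and largest finite observed times
    (censoring times included).  Interior knots are placed at equally spaced
    quantiles of the pseudo-times restricted to their [5th, 95th] percentile
    range.  ``n_internal='auto'`` uses the cube-root rule
    ``round(n0 ** (1/3))`` where n0 is the non-right-censored count.
    """
    pt = pseudo_times(d)
    obs = d.observed_times()
    a, b = float(np.min(obs)), float(np.max(obs))
    if n_internal == "auto":
        n_internal = max(1, int(round(d.n0 ** (1.0 / 3.0))))
    n_internal = int(n_internal)
    if n_internal < 1:
        raise ValueError("n_internal must be >= 1")
    lo, hi = np.percentile(pt, [5.0, 95.0])
    qs = np.linspace(0.0, 1.0, n_internal + 2)[1:-1]
    inner = pt[(pt >= lo) & (pt <= hi)]
    if inner.size == 0:
        inner = pt
    knots = np.quantile(inner, qs)
    # keep knots strictly interior and deduplicated
    eps = _DEDUP_TOL * max(1.0, abs(b))
    knots = knots[(knots > a + eps) & (knots < b - eps)]
    if knots.size:
        keep = [knots[0]]
        for kv in knots[1:]:
            if kv - keep[-1] > eps:
                keep.append(kv)
        knots = np.asarray(keep)
    if knots.size < n_internal:
        warnings.warn(
            f"only {knots.size} distinct interior knots available "
            f"(requested {n_internal})")
    if knots.size == 0:
        knots = np.array([0.5 * (a + b)])
    return SplineBasis(order=order, interior_knots=knots, boundary=(a, b))
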