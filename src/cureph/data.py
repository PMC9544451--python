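"""Partly interval-censored mixture-cure survival datasets.

A subject's observation is an interval ``(t_left, t_right]`` together with a
censoring status:

* ``EVENT``    — exact event time, ``t_left == t_right`` finite;
* ``RIGHT``    — right-censored, ``t_right == +inf``;
* ``LEFT``     — left-censored, interval ``(0, t_right]``;
* ``INTERVAL`` — event bracketed by ``0 < t_left < t_right < inf``.

Each subject carries two covariate vectors: ``x`` (latency, proportional
hazards part, length q) and ``z`` (incidence, logistic part, length p with
``z[0] == 1`` for the intercept).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CensoringType",
    "SurvivalRecord",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "pseudo_times",
]


class CensoringType(IntEnum):
    """Status codes (interval2-style convention: 0=right, 1=event, 2=left, 3=interval)."""

    RIGHT = 0
    EVENT = 1
    LEFT = 2
    INTERVAL = 3


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: censoring interval, status and covariates."""

    t_left: float
    t_right: float
    status: CensoringType
    x: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        tl, tr = float(self.t_left), float(self.t_right)
        st = CensoringType(self.status)
        if not np.isfinite(tl) or tl < 0:
            raise ValueError(f"t_left must be finite and >= 0, got {tl}")
        if st is CensoringType.EVENT:
            if not (np.isfinite(tr) and tl == tr):
                raise ValueError("EVENT requires finite t_left == t_right")
        elif st is CensoringType.RIGHT:
            if not np.isinf(tr):
                raise ValueError("RIGHT requires t_right == +inf")
        elif st is CensoringType.LEFT:
            if not (tl == 0.0 and 0.0 < tr < np.inf):
                raise ValueError("LEFT requires t_left == 0 and 0 < t_right < inf")
        else:  # INTERVAL
            if not (0.0 < tl < tr < np.inf):
                raise ValueError("INTERVAL requires 0 < t_left < t_right < inf")
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if x.ndim != 1 or z.ndim != 1:
            raise ValueError("covariate vectors must be one-dimensional")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
            raise ValueError("covariates must be finite")
        object.__setattr__(self, "t_left", tl)
        object.__setattr__(self, "t_right", tr)
        object.__setattr__(self, "status", st)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)


class Dataset:
    """Column-major container for n subjects (validated on construction).

    Parameters
    ----------
    t_left, t_right : array-like, shape (n,)
        Interval endpoints; ``t_right`` is ``+inf`` for right censoring.
    status : array-like of CensoringType codes, shape (n,)
    X : array-like, shape (n, q)
        Latency (Cox) covariates.
    Z : array-like, shape (n, p)
        Incidence (logistic) covariates including the leading intercept column.
    """

    def __init__(self, t_left, t_right, status, X, Z):
        self.t_left = np.ascontiguousarray(t_left, dtype=float)
        self.t_right = np.ascontiguousarray(t_right, dtype=float)
        self.status = np.asarray(status, dtype=np.int8)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(Z, dtype=float))
        n = self.t_left.shape[0]
        if n < 1:
            raise ValueError("dataset must contain at least one record")
        if self.X.shape[0] != n:
            self.X = self.X.reshape(n, -1)
        if self.Z.shape[0] != n:
            self.Z = self.Z.reshape(n, -1)
        for arr, name in ((self.t_right, "t_right"), (self.status, "status")):
            if arr.shape[0] != n:
                raise ValueError(f"{name} length mismatch")
        self._validate()

    def _validate(self):
        tl, tr, st = self.t_left, self.t_right, self.status
        if not np.all(np.isfinite(tl)) or np.any(tl < 0):
            raise ValueError("t_left must be finite and non-negative")
        ev = st == CensoringType.EVENT
        ri = st == CensoringType.RIGHT
        le = st == CensoringType.LEFT
        iv = st == CensoringType.INTERVAL
        if not np.all(ev | ri | le | iv):
            raise ValueError("unknown status code present")
        bad = np.flatnonzero(
            (ev & ~(np.isfinite(tr) & (tl == tr)))
            | (ri & ~np.isinf(tr))
            | (le & ~((tl == 0) & np.isfinite(tr) & (tr > 0)))
            | (iv & ~((tl > 0) & np.isfinite(tr) & (tr > tl)))
        )
        if bad.size:
            raise ValueError(f"inconsistent interval/status at rows {bad[:10].tolist()}")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Z))):
            raise ValueError("covariates must be finite")

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        return self.t_left.shape[0]

    @property
    def n0(self) -> int:
        """Number of non-right-censored subjects."""
        return int(np.sum(self.status != CensoringType.RIGHT))

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def records(self) -> list[SurvivalRecord]:
        return [
            SurvivalRecord(self.t_left[i], self.t_right[i],
                           CensoringType(int(self.status[i])), self.X[i], self.Z[i])
            for i in range(self.n)
        ]

    def status_counts(self) -> dict[str, int]:
        return {ct.name: int(np.sum(self.status == ct)) for ct in CensoringType}

    @classmethod
    def from_records(cls, records: Iterable[SurvivalRecord]) -> "Dataset":
        records = list(records)
        if not records:
            raise ValueError("empty record list")
        q = records[0].x.shape[0]
        p = records[0].z.shape[0]
        for i, r in enumerate(records):
            if r.x.shape[0] != q or r.z.shape[0] != p:
                raise ValueError(f"covariate length mismatch at record {i}")
        return cls(
            [r.t_left for r in records],
            [r.t_right for r in records],
            [int(r.status) for r in records],
            np.vstack([r.x for r in records]),
            np.vstack([r.z for r in records]),
        )

    def observed_times(self) -> np.ndarray:
        """All finite interval endpoints (used for spline boundary knots)."""
        t = np.concatenate([self.t_left, self.t_right])
        t = t[np.isfinite(t)]
        return t[t > 0] if np.any(t > 0) else t

    def to_dataframe(self, x_names: Sequence[str] | None = None,
                     z_names: Sequence[str] | None = None) -> pd.DataFrame:
        x_names = list(x_names) if x_names else [f"x{j+1}" for j in range(self.q)]
        z_names = list(z_names) if z_names else [f"z{j}" for j in range(self.p)]
        df = pd.DataFrame({"t_left": self.t_left, "t_right": self.t_right,
                           "status": self.status.astype(int)})
        for j, name in enumerate(x_names):
            df[name] = self.X[:, j]
        for j, name in enumerate(z_names):
            df[name] = self.Z[:, j]
        return df


_INF_SENTINELS = {"", "inf", "Inf", "INF", "infinity", "Infinity", "NA", "NaN", "nan"}


def _derive_status(tl: float, tr: float) -> CensoringType:
    if np.isinf(tr):
        return CensoringType.RIGHT
    if tl == tr:
        return CensoringType.EVENT
    if tl == 0.0:
        return CensoringType.LEFT
    return CensoringType.INTERVAL


def read_dataset(
    path,
    column_map: Mapping[str, object] | None = None,
    intercept: bool = True,
    sep: str | None = None,
) -> Dataset:
    """Read a delimited text table into a :class:`Dataset`.

    ``column_map`` names the roles: ``t_left``, ``t_right`` (required),
    ``status`` (optional explicit codes 0=RIGHT 1=EVENT 2=LEFT 3=INTERVAL,
    which win over endpoint-derived status on conflict), ``x`` and ``z``
    (lists of covariate column names).  ``t_right`` may encode +inf as an
    empty field, ``Inf`` or ``NA``.  If ``intercept`` is set a constant-1
    column is prepended to Z.
    """
    cm = dict(column_map or {})
    tl_col = cm.get("t_left", "t_left")
    tr_col = cm.get("t_right", "t_right")
    st_col = cm.get("status", None)
    x_cols = list(cm.get("x", []))
    z_cols = list(cm.get("z", []))

    # dtype=str + float() below: exact round-trip parsing (the csv engines'
    # fast float paths can be off in the last bit)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     keep_default_na=False, na_values=[], dtype=str)
    for col in [tl_col, tr_col] + x_cols + z_cols + ([st_col] if st_col else []):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")

    def _num(series, allow_inf_sentinel=False):
        out = np.empty(len(series), dtype=float)
        for i, v in enumerate(series):
            if isinstance(v, str):
                v = v.strip()
                if allow_inf_sentinel and v in _INF_SENTINELS:
                    out[i] = np.inf
                    continue
            try:
                out[i] = float(v)
            except (TypeError, ValueError):
                raise ValueError(f"non-numeric value {v!r} at row {i}") from None
        return out

    tl = _num(df[tl_col])
    tr = _num(df[tr_col], allow_inf_sentinel=True)
    bad = np.flatnonzero(~np.isfinite(tl) | (tl < 0))
    if bad.size:
        raise ValueError(f"negative or non-finite t_left at row {bad[0]}")
    bad = np.flatnonzero(np.isfinite(tr) & (tl > tr))
    if bad.size:
        raise ValueError(f"t_left > t_right at row {bad[0]}")

    if st_col:
        status = _num(df[st_col]).astype(int)
        # explicit status wins: coerce interval representation accordingly
        tr = tr.copy()
        tr[status == CensoringType.RIGHT] = np.inf
        tl = tl.copy()
        tl[status == CensoringType.LEFT] = 0.0
    else:
        status = np.array([_derive_status(a, b) for a, b in zip(tl, tr)], dtype=int)

    X = np.column_stack([_num(df[c]) for c in x_cols]) if x_cols else np.empty((len(df), 0))
    Z = np.column_stack([_num(df[c]) for c in z_cols]) if z_cols else np.empty((len(df), 0))
    if intercept:
        Z = np.column_stack([np.ones(len(df)), Z])
    return Dataset(tl, tr, status, X, Z)


def write_dataset(d: Dataset, path, x_names=None, z_names=None, sep: str = ",") -> None:
    """Write a dataset as delimited text; +inf right endpoints become ``Inf``."""
    df = d.to_dataframe(x_names, z_names)
    # drop the intercept column (re-added by read_dataset(intercept=True))
    if d.p >= 1 and np.allclose(d.Z[:, 0], 1.0):
        df = df.drop(columns=[df.columns[3 + d.q]])
    buf = io.StringIO()
    df.to_csv(buf, index=False, sep=sep)
    text = buf.getvalue().replace("inf", "Inf")
    with open(path, "w") as fh:
        fh.write(text)


def pseudo_times(d: Dataset) -> np.ndarray:
    """Sorted surrogate event times used for knot placement.

    One value per non-right-censored subject: the event time itself, or the
    mid-point of the left/interval censoring interval.
    """
    st = d.status
    out = []
    ev = st == CensoringType.EVENT
    le = st == CensoringType.LEFT
    iv = st == CensoringType.INTERVAL
    out.append(d.t_left[ev])
    out.append(d.t_right[le] / 2.0)
    out.append((d.t_left[iv] + d.t_right[iv]) / 2.0)
    t = np.concatenate(out)
    if t.size == 0:
        raise ValueError(
            "all records are right-censored: baseline hazard is unidentifiable")
    return np.sort(t)
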