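"""Natural cubic spline design columns for the FEV1 term of backward-age models.

A natural cubic spline with interior knots ``xi_1 < ... < xi_K`` inside
boundary knots ``(a, b)`` is piecewise cubic with continuous second
derivatives and is constrained to be *linear* beyond the boundary knots.
Excluding the intercept, the space of such functions has dimension ``K + 1``.

Two constructions of the same function space are provided:

* :func:`natural_cubic_basis` — a numerically well-conditioned basis built
  from cubic B-splines with the two second-derivative boundary constraints
  projected out (the construction used by R's ``ns``).  This is the basis
  used for model fitting.
* :func:`truncated_power_basis` — the classical truncated-power construction
  with the natural constraints substituted in.  It spans the identical
  space and serves as an independent cross-check of the fitted values.

Both evaluate points outside the boundary knots by linear extrapolation,
which is the defining boundary behaviour of the natural spline; very low
patient FEV1 values therefore receive a linear, not cubic, extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "KnotSet",
    "place_knots",
    "natural_cubic_basis",
    "truncated_power_basis",
]


@dataclass(frozen=True)
class KnotSet:
    """Boundary and interior knots for a natural cubic spline in FEV1 (L)."""

    boundary_low: float
    boundary_high: float
    interior: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        knots = self.all_knots
        if not np.all(np.isfinite(knots)):
            raise ValueError(f"knots must be finite, got {knots}")
        if not np.all(np.diff(knots) > 0):
            raise ValueError(
                "knots must be strictly increasing: "
                f"boundary_low={self.boundary_low}, interior={self.interior}, "
                f"boundary_high={self.boundary_high}"
            )
        object.__setattr__(self, "interior", tuple(float(k) for k in self.interior))

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray(
            [self.boundary_low, *self.interior, self.boundary_high], dtype=float
        )

    @property
    def n_columns(self) -> int:
        """Dimension of the natural-spline space without intercept."""
        return len(self.interior) + 1

    def to_dict(self) -> dict:
        return {
            "boundary_low": self.boundary_low,
            "boundary_high": self.boundary_high,
            "interior": list(self.interior),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnotSet":
        return cls(
            boundary_low=float(d["boundary_low"]),
            boundary_high=float(d["boundary_high"]),
            interior=tuple(float(k) for k in d["interior"]),
        )


def place_knots(
    values,
    n_interior: int = 3,
    boundary_quantiles: tuple[float, float] = (0.05, 0.95),
) -> KnotSet:
    """Place knots at quantiles of the observed FEV1 values.

    Interior knots sit at equally spaced quantiles — e.g. ``n_interior=3``
    gives the 25th/50th/75th percentiles.  Boundary knots sit at the requested
    quantiles; pass ``(0, 1)`` for the sample minimum/maximum.  Quantiles are
    computed by linear interpolation between order statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot place knots on an empty sample")
    if not np.all(np.isfinite(values)):
        raise ValueError("FEV1 values must be finite to place knots")
    if n_interior < 0:
        raise ValueError(f"n_interior must be >= 0, got {n_interior}")
    lo_q, hi_q = boundary_quantiles
    if not (0 <= lo_q < hi_q <= 1):
        raise ValueError(f"boundary quantiles must satisfy 0 <= lo < hi <= 1, got {boundary_quantiles}")

    n_distinct = np.unique(values).size
    n_needed = n_interior + 2
    if n_distinct < n_needed:
        raise ValueError(
            f"need at least {n_needed} distinct values for {n_interior} interior "
            f"knots, got {n_distinct} (short by {n_needed - n_distinct})"
        )

    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    interior = np.quantile(values, probs) if n_interior else np.array([])
    lo = np.quantile(values, lo_q)
    hi = np.quantile(values, hi_q)
    knots = np.concatenate([[lo], interior, [hi]])
    if not np.all(np.diff(knots) > 0):
        raise ValueError(
            f"quantile knots are not distinct ({knots.tolist()}); "
            "reduce n_interior or supply knots explicitly"
        )
    return KnotSet(float(lo), float(hi), tuple(float(k) for k in interior))


def _bspline_design(t: np.ndarray, x: np.ndarray, nu: int = 0) -> np.ndarray:
    """Dense design matrix of all cubic B-splines on knot vector ``t`` at ``x``."""
    n_basis = len(t) - 4
    cols = np.empty((x.size, n_basis))
    coef = np.zeros(n_basis)
    for j in range(n_basis):
        coef[:] = 0.0
        coef[j] = 1.0
        spl = BSpline(t, coef.copy(), 3, extrapolate=True)
        if nu:
            spl = spl.derivative(nu)
        cols[:, j] = spl(x)
    return cols


def natural_cubic_basis(x, knots: KnotSet) -> np.ndarray:
    """Natural cubic spline design matrix (without intercept).

    Returns an ``(n, K + 1)`` array for ``K`` interior knots.  Columns are
    cubic B-spline combinations lying in the null space of the two
    second-derivative boundary constraints; outside the boundary knots each
    column is continued linearly from its boundary value and slope.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values passed to natural_cubic_basis")
    a, b = knots.boundary_low, knots.boundary_high
    t = np.concatenate([[a] * 4, knots.interior, [b] * 4])

    # second-derivative constraints at both boundaries; the first B-spline
    # column is dropped (it carries the intercept direction)
    const = _bspline_design(t, np.array([a, b]), nu=2)[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    null_basis = q[:, 2:]  # (K+3, K+1)

    inside = np.clip(x, a, b)
    design = _bspline_design(t, inside)[:, 1:] @ null_basis

    left = x < a
    right = x > b
    if left.any():
        slope = _bspline_design(t, np.array([a]), nu=1)[:, 1:] @ null_basis
        design[left] += np.outer(x[left] - a, slope.ravel())
    if right.any():
        slope = _bspline_design(t, np.array([b]), nu=1)[:, 1:] @ null_basis
        design[right] += np.outer(x[right] - b, slope.ravel())
    return design


def truncated_power_basis(x, knots: KnotSet) -> np.ndarray:
    """Truncated-power natural spline basis (test oracle).

    With all knots ``t_1 < ... < t_m`` (boundary knots included), the columns
    are ``N_1(x) = x`` and ``N_{k+1}(x) = d_k(x) - d_{m-1}(x)`` for
    ``k = 1..m-2``, where ``d_k(x) = [(x - t_k)_+^3 - (x - t_m)_+^3] / (t_m - t_k)``.
    Spans exactly the same function space as :func:`natural_cubic_basis`
    (modulo the intercept), including the linear tails.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values passed to truncated_power_basis")
    t = knots.all_knots
    m = len(t)

    def pos_cube(v):
        return np.maximum(v, 0.0) ** 3

    def d(k):  # 0-based index into t
        return (pos_cube(x - t[k]) - pos_cube(x - t[m - 1])) / (t[m - 1] - t[k])

    cols = [x]
    if m > 2:
        d_last = d(m - 2)
        for k in range(m - 2):
            cols.append(d(k) - d_last)
    return np.column_stack(cols)
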