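"""One-dimensional optical-trap force laws and their linearity diagnostics.

Near the beam focus an optical trap acts as a linear spring, ``F(x) = -k0*x``.
Away from the focus the restoring force saturates and eventually decays, so
the local stiffness seen by a particle that starts its fall far from the
center differs from the equilibrium stiffness.  This module provides three
force laws

* ``linear``            -- ideal spring, exact everywhere;
* ``gaussian_profile``  -- ``F(x) = -k0*x*exp(-x^2/w^2)``, the gradient force
  of a Gaussian intensity profile in the small-particle limit, used as the
  parametric stand-in for full electromagnetic force curves;
* ``tabulated``         -- externally computed force-extension curves read
  from two-column text files,

together with the diagnostics used to decide where calibration is trustworthy:
the relative stiffness profile ``(-F(x)/x)/k0``, the third-to-first derivative
ratio ``F'''(0)/F'(0)`` (how fast the trap departs from harmonic), and the
half-width of the region in which the stiffness stays within a tolerance of
its central value.

All quantities are SI: displacements in metres, forces in newtons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "TrapModel",
    "linear_trap",
    "gaussian_trap",
    "tabulated_trap",
    "load_force_table",
    "force",
    "stiffness_profile",
    "derivative_ratio",
    "linear_region",
    "LinearRegion",
]

_KINDS = ("linear", "gaussian_profile", "tabulated")


@dataclass(frozen=True)
class TrapModel:
    """A 1D restoring force law F(x) with stiffness ``k0`` at the center.

    Parameters
    ----------
    kind
        One of ``linear``, ``gaussian_profile``, ``tabulated``.
    k0
        Stiffness at the trap center, N/m (``-F'(0)``).  For tabulated
        models this is derived from the table.
    w
        Length scale of the nonlinearity, m (``gaussian_profile`` only).
    table
        ``(n, 2)`` array of (displacement_m, force_N) pairs with strictly
        increasing displacements spanning 0 (``tabulated`` only).
    """

    kind: str
    k0: float
    w: Optional[float] = None
    table: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown trap kind {self.kind!r}")
        if not np.isfinite(self.k0) or self.k0 <= 0:
            raise ValueError("k0 must be positive and finite")
        if self.kind == "gaussian_profile":
            if self.w is None or self.w <= 0:
                raise ValueError("gaussian_profile requires a positive w")
        if self.kind == "tabulated":
            t = self.table
            if t is None or t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 5:
                raise ValueError("tabulated requires a (n>=5, 2) table")
            x = t[:, 0]
            if not np.all(np.diff(x) > 0):
                raise ValueError("table displacements must be strictly increasing")
            if x[0] > 0 or x[-1] < 0:
                raise ValueError("table must span displacement 0")
            object.__setattr__(self, "_spline", CubicSpline(t[:, 0], t[:, 1]))

    def force(self, x):
        return force(self, x)


def linear_trap(k0: float) -> TrapModel:
    """Ideal linear spring ``F(x) = -k0*x``."""
    return TrapModel("linear", k0)


def gaussian_trap(k0: float, w: float) -> TrapModel:
    """Gaussian-profile trap ``F(x) = -k0*x*exp(-x^2/w^2)``."""
    return TrapModel("gaussian_profile", k0, w=w)


def tabulated_trap(table: np.ndarray) -> TrapModel:
    """Trap defined by a (displacement, force) table; k0 = -F'(0) by stencil."""
    table = np.asarray(table, dtype=float)
    model = object.__new__(TrapModel)
    object.__setattr__(model, "kind", "tabulated")
    object.__setattr__(model, "k0", 1.0)  # placeholder until derivative known
    object.__setattr__(model, "w", None)
    object.__setattr__(model, "table", table)
    TrapModel.__post_init__(model)
    d1, _ = _tabulated_derivatives(model)
    if d1 >= 0:
        raise ValueError("tabulated force is not restoring at 0 (F'(0) >= 0)")
    object.__setattr__(model, "k0", -d1)
    return model


def load_force_table(path: str | Path) -> TrapModel:
    """Read a 2-column delimited text file (displacement_m, force_N).

    Lines starting with ``#`` are comments; whitespace or comma delimited.
    """
    table = np.loadtxt(path, comments="#", delimiter=None)
    if table.ndim != 2 or table.shape[1] < 2:
        # retry comma-delimited
        table = np.loadtxt(path, comments="#", delimiter=",")
    return tabulated_trap(table[:, :2])


def force(model: TrapModel, x):
    """Evaluate F(x) in newtons for scalar or array displacement (m)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("displacement must be finite")
    if model.kind == "linear":
        out = -model.k0 * x
    elif model.kind == "gaussian_profile":
        out = -model.k0 * x * np.exp(-(x / model.w) ** 2)
    else:
        lo, hi = model.table[0, 0], model.table[-1, 0]
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(
                f"displacement outside tabulated range [{lo:g}, {hi:g}] m"
            )
        out = model._spline(x)
    return out if out.ndim else float(out)


def stiffness_profile(model: TrapModel, x_grid) -> np.ndarray:
    """Local secant stiffness relative to the center value.

    Returns ``(-F(x)/x)/k0`` per grid point; ``x = 0`` entries take the
    limit value 1.
    """
    x = np.atleast_1d(np.asarray(x_grid, dtype=float))
    out = np.ones_like(x)
    nz = x != 0.0
    out[nz] = -force(model, x[nz]) / x[nz] / model.k0
    return out


def _tabulated_derivatives(model: TrapModel) -> tuple[float, float]:
    """First and third derivative of F at 0 via 5-point central differences.

    The table is resampled uniformly with a cubic spline so the stencils are
    exact for cubics; the step is 1/400 of the smaller table half-range,
    small enough that stencil truncation error is <0.1% on smooth tables
    while staying far above floating-point roundoff.
    """
    x = model.table[:, 0]
    h = min(-x[0], x[-1]) / 400.0
    if h <= 0:
        raise ValueError("table does not bracket 0")
    f = model._spline(np.array([-2 * h, -h, 0.0, h, 2 * h]))
    d1 = (f[0] - 8 * f[1] + 8 * f[3] - f[4]) / (12 * h)
    d3 = (-f[0] + 2 * f[1] - 2 * f[3] + f[4]) / (2 * h**3)
    return d1, d3


def derivative_ratio(model: TrapModel) -> float:
    """Ratio F'''(0)/F'(0) in 1/m^2 -- how fast the trap departs from linear.

    Zero for a linear trap; ``-6/w^2`` for the Gaussian profile
    (Taylor: ``F = -k0*(x - x^3/w^2 + ...)``).  Computed analytically for
    parametric models, by central finite differences for tabulated ones.
    """
    if model.kind == "linear":
        return 0.0
    if model.kind == "gaussian_profile":
        return -6.0 / model.w**2
    d1, d3 = _tabulated_derivatives(model)
    if d1 == 0.0:
        raise ZeroDivisionError("degenerate trap: F'(0) = 0")
    return d3 / d1


@dataclass(frozen=True)
class LinearRegion:
    """Half-width of the quasi-linear region plus qualifying flags."""

    half_width: float  # m
    unbounded: bool = False  # tolerance never exceeded within the scan limit
    empty: bool = False  # tolerance violated arbitrarily close to 0


def linear_region(
    model: TrapModel,
    tolerance: float,
    scan_limit: Optional[float] = None,
    n_scan: int = 4096,
) -> LinearRegion:
    """Largest |x| such that the relative stiffness stays within ``tolerance``.

    Scans a symmetric grid out to ``scan_limit`` (default: 5w for the
    Gaussian profile, the table extent for tabulated models, 1 um for linear)
    and refines the first crossing by bisection.  A linear trap never crosses,
    so the scan limit is returned with ``unbounded=True``.
    """
    if not 0.0 < tolerance < 1.0:
        raise ValueError("tolerance must lie in (0, 1)")
    if scan_limit is None:
        if model.kind == "gaussian_profile":
            scan_limit = 5.0 * model.w
        elif model.kind == "tabulated":
            scan_limit = min(-model.table[0, 0], model.table[-1, 0])
        else:
            scan_limit = 1e-6

    def bad(x: float) -> bool:
        s = stiffness_profile(model, np.array([x, -x]))
        return bool(np.any(np.abs(s - 1.0) > tolerance))

    grid = np.linspace(0.0, scan_limit, n_scan + 1)[1:]
    violations = [x for x in grid if bad(x)]
    if not violations:
        return LinearRegion(scan_limit, unbounded=True)
    hi = violations[0]
    lo = hi - scan_limit / n_scan
    if lo <= 0.0:
        return LinearRegion(0.0, empty=True)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if bad(mid):
            hi = mid
        else:
            lo = mid
    return LinearRegion(0.5 * (lo + hi))
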