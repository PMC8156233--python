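"""FORMA trap-frequency estimators with aliasing correction.

FORMA (force reconstruction via maximum-likelihood-estimator analysis)
regresses the finite-difference velocity estimator on position to recover
the linear response ``omega_c`` of the trap (``x_dot = omega_c x``,
``omega_c < 0`` for a stable trap).  With ``y_n = x_{n+1} - x_n`` the
original estimator is

    omega = (1/dt) * sum(x_n y_n) / sum(x_n^2),

which is biased at finite sampling rate because ``y_n/dt`` is not the
instantaneous velocity: on a pure relaxation it returns
``(e^{omega_c dt} - 1)/dt`` instead of ``omega_c``.  Recognising that the
discretely observed linear trap is the AR(1) process
``x_{n+1} = e^{omega_c dt} x_n + xi_n`` gives the aliasing-corrected
estimator

    omega_corr = log( sum(x_n x_{n+1}) / sum(x_n^2) ) / dt,

valid while the lag ratio ``S = sum(x_n x_{n+1})/sum(x_n^2)`` is positive
(deep in the aliased regime S can go negative on short windows, in which
case equipartition calibration should be used instead).  The matching
aliasing-compensated diffusion estimator is

    D_est = (1/(2 dt)) * (2 omega dt / (e^{2 omega dt} - 1)) * mean(xi_n^2),
    xi_n  = x_{n+1} - e^{omega dt} x_n,

exactly unbiased on AR(1) data since E[xi^2] = D (1 - e^{2 omega dt})/|omega|.

Positions passed to these estimators must be referenced to the trap
equilibrium (zero mean position); no internal centering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .langevin import BOLTZMANN, FluidContext

__all__ = [
    "CalibrationError",
    "CalibrationResult",
    "forma_original",
    "forma_corrected",
    "estimate_diffusion",
    "calibrate",
    "stokes_drag",
    "diffusion_coefficient",
    "stiffness_from_omega",
    "brownian_rms",
    "min_diffusion_time",
    "equipartition_stiffness",
]


class CalibrationError(ValueError):
    """Raised when an estimator is degenerate or outside its validity range."""


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a single-window FORMA calibration.

    ``valid`` is equivalent to ``ratio_S > 0``; when invalid the corrected
    frequency and diffusion are NaN and equipartition calibration is the
    recommended fallback.  ``stiffness`` (``gamma * |omega_corrected|``) is
    filled when a fluid context is supplied.
    """

    omega_original: float  # 1/s
    omega_corrected: float  # 1/s
    D_est: float  # m^2/s
    n_points: int
    ratio_S: float
    valid: bool
    stiffness: Optional[float] = None  # N/m


def _validate(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise CalibrationError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise CalibrationError("positions must be finite")
    if not np.any(x[:-1] != 0.0):
        raise CalibrationError("degenerate input: all regressor positions zero")
    return x


def _lag_ratio(x: np.ndarray) -> float:
    a = x[:-1]
    den = float(a @ a)
    if den == 0.0:  # all-zero regressors, or underflow of sub-normal inputs
        raise CalibrationError("degenerate input: sum of squared positions is zero")
    return float(a @ x[1:]) / den


def forma_original(x, dt: float) -> float:
    """Original FORMA estimate ``(1/dt) sum(x_n y_n)/sum(x_n^2)``, 1/s."""
    x = _validate(x)
    return (_lag_ratio(x) - 1.0) / dt


def forma_corrected(x, dt: float) -> float:
    """Aliasing-corrected estimate ``log(sum x_n x_{n+1} / sum x_n^2)/dt``.

    Raises :class:`CalibrationError` when the lag ratio is non-positive
    (the correction would be complex); use :func:`calibrate` for a flagged,
    non-raising variant.
    """
    x = _validate(x)
    S = _lag_ratio(x)
    if S <= 0.0:
        raise CalibrationError(
            f"lag ratio {S:.3g} <= 0: corrected frequency undefined "
            "(too few points or trap too stiff; use equipartition calibration)"
        )
    return float(np.log(S)) / dt


def estimate_diffusion(x, dt: float, omega_corr: float) -> float:
    """Aliasing-compensated diffusion estimate from AR(1) residuals, m^2/s.

    The ``omega -> 0`` limit of the compensation factor
    ``2 omega dt/(e^{2 omega dt} - 1)`` is taken analytically (it tends to
    1, recovering the plain MSD estimator ``mean(dx^2)/(2 dt)``).
    """
    x = _validate(x)
    if not np.isfinite(omega_corr):
        raise CalibrationError("omega_corr must be finite")
    phi = np.exp(omega_corr * dt)
    resid = x[1:] - phi * x[:-1]
    msq = float(np.mean(resid * resid))
    a = 2.0 * omega_corr * dt
    c = a / np.expm1(a) if a != 0.0 else 1.0
    return c * msq / (2.0 * dt)


def calibrate(x, dt: float, fluid: Optional[FluidContext] = None) -> CalibrationResult:
    """Full single-window calibration returning a flagged result.

    Unlike :func:`forma_corrected` this never raises on a non-positive lag
    ratio; it returns ``valid=False`` with NaN corrected values so ensemble
    code can count and exclude invalid windows explicitly.
    """
    x = _validate(x)
    S = _lag_ratio(x)
    omega_orig = (S - 1.0) / dt
    if S > 0.0:
        omega_corr = float(np.log(S)) / dt
        D_est = estimate_diffusion(x, dt, omega_corr)
        valid = True
    else:
        omega_corr = np.nan
        D_est = np.nan
        valid = False
    stiffness = None
    if fluid is not None and valid:
        stiffness = stiffness_from_omega(omega_corr, fluid.gamma)
    return CalibrationResult(
        omega_original=omega_orig,
        omega_corrected=omega_corr,
        D_est=D_est,
        n_points=x.size,
        ratio_S=S,
        valid=valid,
        stiffness=stiffness,
    )


# --- auxiliary physical formulas -------------------------------------------


def stokes_drag(fluid: FluidContext) -> float:
    """Stokes drag gamma = 6*pi*eta*r, kg/s."""
    return fluid.gamma


def diffusion_coefficient(fluid: FluidContext) -> float:
    """Einstein relation D = kB*T/gamma, m^2/s."""
    return fluid.diffusion


def stiffness_from_omega(omega: float, gamma: float) -> float:
    """Trap stiffness k = gamma*|omega|, N/m."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return gamma * abs(omega)


def brownian_rms(D: float, dt: float) -> float:
    """Free-diffusion rms wandering distance sqrt(2 D dt), m."""
    if D < 0 or dt < 0:
        raise ValueError("D and dt must be non-negative")
    return float(np.sqrt(2.0 * D * dt))


def min_diffusion_time(dx: float, D: float) -> float:
    """Mean time to diffuse a cumulative 1D displacement dx: dx^2/(2 D), s."""
    if D <= 0:
        raise ValueError("D must be positive")
    return dx * dx / (2.0 * D)


def equipartition_stiffness(x, temperature: float = 298.0) -> float:
    """Equipartition calibration k = kB*T/var(x) on an equilibrium trace.

    ``var`` is the sample variance about the sample mean; the fallback
    recommended when the corrected estimator's lag ratio is non-positive.
    """
    x = np.asarray(x, dtype=float)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    v = float(np.var(x, ddof=1))
    if v <= 0.0 or np.ptp(x) == 0.0:
        raise CalibrationError("zero position variance: equipartition undefined")
    return BOLTZMANN * temperature / v
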