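"""Overdamped Brownian dynamics in an optical trap, plus the camera model.

The physical model is the overdamped Langevin equation

    dx/dt = F(x)/gamma + sqrt(2 D) xi(t),

with Stokes drag ``gamma = 6 pi eta r`` and diffusion ``D = kB T / gamma``.
Trajectories are integrated with a stochastic second-order Runge-Kutta
(Heun) scheme on a fine time step and then passed through the measurement
chain of a tracking camera:

* snapshot downsampling to the frame rate (this is what aliases the
  spectrum),
* exposure blur (arithmetic mean of the fine trajectory over the exposure
  window -- convolution with a rect function),
* additive position noise: white per-frame tracking noise and, optionally,
  a low-pass-filtered Gaussian drift component.

For a *linear* trap the continuous process is an Ornstein-Uhlenbeck process
whose discrete-time form is an exact AR(1) update; :func:`simulate_ou_exact`
samples it directly and serves as the reference against which the RK2
integrator is validated.

Sign convention: a stable trap has angular trap frequency ``omega_c < 0``
(the relaxation ``x_dot = omega_c x``).  Stiffness is ``k = gamma*|omega_c|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.constants import k as BOLTZMANN
from scipy.signal import lfilter

from .trap_models import TrapModel, force

__all__ = [
    "BOLTZMANN",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_VISCOSITY",
    "DEFAULT_RADIUS",
    "FluidContext",
    "Trace",
    "MeasurementModel",
    "simulate_fine",
    "rk2_paths",
    "simulate_ou_exact",
    "downsample",
    "apply_blur",
    "add_noise",
    "simulate_catch_release",
]

# Water at room temperature around a 2 um diameter polystyrene bead.
DEFAULT_TEMPERATURE = 298.0  # K
DEFAULT_VISCOSITY = 8.9e-4  # Pa s
DEFAULT_RADIUS = 1e-6  # m


@dataclass(frozen=True)
class FluidContext:
    """Thermal bath and particle geometry giving drag and diffusion."""

    temperature: float = DEFAULT_TEMPERATURE  # K
    viscosity: float = DEFAULT_VISCOSITY  # Pa s
    radius: float = DEFAULT_RADIUS  # m

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.viscosity <= 0 or self.radius <= 0:
            raise ValueError("temperature, viscosity and radius must be positive")

    @property
    def gamma(self) -> float:
        """Stokes drag 6*pi*eta*r, kg/s."""
        return 6.0 * np.pi * self.viscosity * self.radius

    @property
    def diffusion(self) -> float:
        """Einstein diffusion coefficient kB*T/gamma, m^2/s."""
        return BOLTZMANN * self.temperature / self.gamma


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled 1D position time series.

    ``annotations`` may carry trap-on intervals as ``[(start, stop), ...]``
    sample-index pairs (half-open) under key ``"trap_on"``, and true
    simulation parameters under ``"truth"`` when synthetic.
    """

    positions: np.ndarray  # m
    dt: float  # s
    t0: float = 0.0
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", p)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if p.ndim != 1 or p.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(p)):
            raise ValueError("positions must be finite")

    @property
    def n(self) -> int:
        return int(self.positions.size)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class MeasurementModel:
    """Camera measurement chain parameters.

    exposure_fraction
        Fraction of the frame period integrated by the sensor (0 = ideal
        snapshot, 1 = full-frame integration).
    noise_sigma
        White per-frame position noise sd, m.
    lowfreq_sigma / lowfreq_cutoff
        Optional low-frequency (drift-like) Gaussian noise: sd in m and
        first-order low-pass cutoff in Hz.
    """

    exposure_fraction: float = 0.0
    noise_sigma: float = 0.0
    lowfreq_sigma: float = 0.0
    lowfreq_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.exposure_fraction <= 1.0:
            raise ValueError("exposure_fraction must lie in [0, 1]")
        if self.noise_sigma < 0 or self.lowfreq_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.lowfreq_sigma > 0 and self.lowfreq_cutoff <= 0:
            raise ValueError("lowfreq_cutoff must be positive")


def rk2_paths(
    model: TrapModel,
    fluid: FluidContext,
    x0,
    dt_fine: float,
    n_steps: int,
    rng: np.random.Generator,
    diffusion: Optional[float] = None,
) -> np.ndarray:
    """Integrate an ensemble of overdamped paths with stochastic Heun RK2.

    Each step uses a single Gaussian increment ``w = sqrt(2 D dt) N(0,1)``
    shared by predictor and corrector:

        x_pred = x + F(x)/gamma dt + w
        x_next = x + (F(x) + F(x_pred)) / (2 gamma) dt + w

    Returns an array of shape ``(n_paths, n_steps + 1)``; ``x0`` may be a
    scalar (one path) or a 1D array of starting positions.  ``diffusion``
    overrides the fluid's thermal value (0 gives the deterministic limit).
    """
    if dt_fine <= 0:
        raise ValueError("dt_fine must be positive")
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    out = np.empty((x.size, n_steps + 1))
    out[:, 0] = x
    g = fluid.gamma
    D = fluid.diffusion if diffusion is None else diffusion
    sq = np.sqrt(2.0 * D * dt_fine)
    for i in range(n_steps):
        w = sq * rng.standard_normal(x.size)
        with np.errstate(over="ignore", invalid="ignore"):
            # overflow here is reported below as an instability error
            f1 = force(model, x) / g
            xp = x + f1 * dt_fine + w
            f2 = force(model, xp) / g
            x = x + 0.5 * (f1 + f2) * dt_fine + w
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise FloatingPointError(
                f"integration became non-finite at step {i + 1} (path {bad})"
            )
        out[:, i + 1] = x
    return out


def simulate_fine(
    model: TrapModel,
    fluid: FluidContext,
    x0: float,
    dt_fine: float,
    n_steps: int,
    seed: int | np.random.Generator,
    diffusion: Optional[float] = None,
) -> Trace:
    """Single fine-step RK2 trajectory starting at ``x0`` (see rk2_paths)."""
    rng = np.random.default_rng(seed)
    path = rk2_paths(model, fluid, float(x0), dt_fine, n_steps, rng, diffusion)[0]
    D = fluid.diffusion if diffusion is None else diffusion
    truth = {"D": D, "gamma": fluid.gamma, "x0": float(x0)}
    if model.kind == "linear":
        truth["omega"] = -model.k0 / fluid.gamma
    return Trace(path, dt_fine, annotations={"truth": truth})


def simulate_ou_exact(
    omega: float,
    D: float,
    x0: float,
    dt: float,
    n_steps: int,
    seed: int | np.random.Generator,
) -> Trace:
    """Sample the exact discrete-time OU (AR(1)) process.

    ``x_{n+1} = e^{omega dt} x_n + xi_n`` with
    ``Var(xi) = D (1 - e^{2 omega dt}) / |omega|``; this is the exact law of
    the linear-trap Langevin equation observed at interval ``dt`` and is the
    oracle for the RK2 integrator.
    """
    if omega >= 0:
        raise ValueError("stable trap requires omega < 0")
    rng = np.random.default_rng(seed)
    phi = np.exp(omega * dt)
    sd = np.sqrt(D * (1.0 - phi * phi) / abs(omega))
    drive = np.empty(n_steps + 1)
    drive[0] = x0
    drive[1:] = sd * rng.standard_normal(n_steps)
    x = lfilter([1.0], [1.0, -phi], drive)
    return Trace(
        x, dt, annotations={"truth": {"omega": omega, "D": D, "x0": float(x0)}}
    )


def _scale_intervals(intervals, num, den):
    return [(start * num // den, stop * num // den) for start, stop in intervals]


def downsample(trace: Trace, factor: int) -> Trace:
    """Keep every ``factor``-th sample (snapshot semantics -> aliasing)."""
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError("factor must be a positive integer")
    ann = dict(trace.annotations)
    if "trap_on" in ann:
        ann["trap_on"] = _scale_intervals(ann["trap_on"], 1, factor)
    return Trace(trace.positions[::factor], trace.dt * factor, trace.t0, ann)


def apply_blur(trace: Trace, frame_period: float, exposure_fraction: float) -> Trace:
    """Camera exposure blur: per-frame mean over the exposure window.

    Each output sample is the arithmetic mean of the fine samples inside the
    exposure window at the start of each frame; the output interval is
    ``frame_period``.  An exposure of one fine step reduces to snapshot
    downsampling.
    """
    m = frame_period / trace.dt
    if abs(m - round(m)) > 1e-9 * m:
        raise ValueError("frame_period must be an integer multiple of the fine dt")
    m = int(round(m))
    e = max(1, int(round(exposure_fraction * m)))
    if e > m:
        raise ValueError("exposure window longer than frame period")
    n_frames = trace.n // m
    if n_frames < 2:
        raise ValueError("trace too short for two frames")
    frames = trace.positions[: n_frames * m].reshape(n_frames, m)
    out = frames[:, :e].mean(axis=1)
    ann = dict(trace.annotations)
    if "trap_on" in ann:
        ann["trap_on"] = _scale_intervals(ann["trap_on"], 1, m)
    return Trace(out, frame_period, trace.t0, ann)


def add_noise(trace: Trace, mm: MeasurementModel, seed: int | np.random.Generator) -> Trace:
    """Add white (and optionally low-frequency) Gaussian position noise.

    The low-frequency component is an AR(1) process ``z_{n+1} = a z_n +
    b g_n`` with ``a = exp(-2 pi f_cut dt)`` and ``b`` chosen so its
    stationary sd equals ``lowfreq_sigma``; it is initialised from its
    stationary law so the noise is statistically homogeneous.
    """
    rng = np.random.default_rng(seed)
    out = trace.positions.copy()
    if mm.noise_sigma > 0:
        out = out + mm.noise_sigma * rng.standard_normal(trace.n)
    if mm.lowfreq_sigma > 0:
        a = np.exp(-2.0 * np.pi * mm.lowfreq_cutoff * trace.dt)
        b = mm.lowfreq_sigma * np.sqrt(1.0 - a * a)
        drive = rng.standard_normal(trace.n)
        drive[0] *= mm.lowfreq_sigma  # stationary start
        drive[1:] *= b
        out = out + lfilter([1.0], [1.0, -a], drive)
    return replace(trace, positions=out)


def simulate_catch_release(
    model: TrapModel,
    fluid: FluidContext,
    mm: MeasurementModel,
    trap_off_duration: float = 0.36,
    trap_on_duration: float = 0.04,
    n_cycles: int = 10,
    dt_fine: float = 1e-5,
    frame_rate: float = 1e4,
    seed: int | np.random.Generator = 0,
    x_start: float = 0.0,
    escape_bound: float = 2e-6,
    diffusion: Optional[float] = None,
) -> Trace:
    """Shutter-controlled catch-and-release protocol.

    Alternates free diffusion (trap off, F = 0) of ``trap_off_duration``
    with trapped relaxation of ``trap_on_duration``, ``n_cycles`` times,
    integrating on the fine step and carrying the position continuously
    across segment boundaries.  The fine trajectory is then passed through
    the camera chain (exposure blur or snapshot downsampling at
    ``frame_rate``, then additive noise).  Trap-on intervals are recorded in
    camera-frame indices under ``annotations["trap_on"]``; paths exceeding
    ``escape_bound`` from the trap center during trap-on are flagged under
    ``annotations["escapes"]`` and the simulation continues.
    """
    if trap_off_duration < 0 or trap_on_duration <= 0:
        raise ValueError("durations must be positive")
    if frame_rate * dt_fine > 1.0 + 1e-12:
        raise ValueError("frame rate cannot exceed the fine sampling rate")
    rng = np.random.default_rng(seed)
    D = fluid.diffusion if diffusion is None else diffusion
    n_off = int(round(trap_off_duration / dt_fine))
    n_on = int(round(trap_on_duration / dt_fine))
    sq = np.sqrt(2.0 * D * dt_fine)

    segments = [np.array([x_start])]
    intervals: list[tuple[int, int]] = []
    escapes: list[int] = []
    x = float(x_start)
    pos = 1  # samples emitted so far
    if n_cycles <= 0:
        # pure free diffusion over one shutter-off interval
        steps = sq * rng.standard_normal(max(n_off, 1))
        segments.append(x + np.cumsum(steps))
    for cyc in range(max(n_cycles, 0)):
        if n_off:
            # free diffusion: exact Gaussian increments, vectorised
            steps = sq * rng.standard_normal(n_off)
            seg = x + np.cumsum(steps)
            segments.append(seg)
            x = float(seg[-1])
            pos += n_off
        on = rk2_paths(model, fluid, x, dt_fine, n_on, rng, diffusion=D)[0, 1:]
        intervals.append((pos, pos + n_on))
        if np.max(np.abs(on)) > escape_bound:
            escapes.append(cyc)
        segments.append(on)
        x = float(on[-1])
        pos += n_on
    fine = Trace(
        np.concatenate(segments),
        dt_fine,
        annotations={
            "trap_on": intervals,
            "escapes": escapes,
            "truth": {
                "D": D,
                "gamma": fluid.gamma,
                "omega": (-model.k0 / fluid.gamma) if model.kind == "linear" else None,
            },
        },
    )
    frame_period = 1.0 / frame_rate
    if frame_period > dt_fine:
        if mm.exposure_fraction > 0:
            cam = apply_blur(fine, frame_period, mm.exposure_fraction)
        else:
            cam = downsample(fine, int(round(frame_period / dt_fine)))
    else:
        cam = fine
    return add_noise(cam, mm, rng)
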