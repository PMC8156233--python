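"""Detection, windowing and calibration of single in-fall trapping events.

A particle diffusing freely that is suddenly captured by the trap executes
a high signal-to-noise exponential approach ``x(t) = x0 e^{-|omega_c| t}``
to the trap center.  This module turns a raw position trace (with or
without a shutter schedule) into accepted :class:`InfallEvent` windows,
calibrates each with the aliasing-corrected FORMA estimator, and provides
the diagnostics used to judge which part of a fall is trustworthy.

Acceptance band: events are kept when the start displacement satisfies
``x0_min < |x0| < x0_max`` (defaults 160-400 nm): far enough out that the
fall dominates measurement noise, not so far that the trap's nonlinear
stiffness contaminates the estimate.  Windows are truncated to samples with
``|x - equilibrium| <= x0_max``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .forma import CalibrationResult, calibrate
from .langevin import FluidContext, Trace

__all__ = [
    "InfallEvent",
    "EventCalibration",
    "estimate_equilibrium",
    "detect_events",
    "align_events",
    "force_position_curve",
    "calibrate_events",
    "stability_surface",
]

X0_MIN_DEFAULT = 160e-9  # m
X0_MAX_DEFAULT = 400e-9  # m
WINDOW_DEFAULT = 20  # samples (2 ms at 10 kHz, ~1-2 trap periods)


@dataclass(frozen=True)
class InfallEvent:
    """A windowed sub-trace starting at a detected trapping onset.

    ``positions`` are raw (not equilibrium-referenced) window samples;
    ``x`` gives the equilibrium-referenced displacements used for
    calibration.  ``x0`` is the signed start displacement.
    """

    start_index: int
    x0: float  # m, equilibrium-referenced
    positions: np.ndarray  # m, raw
    dt: float  # s
    equilibrium: float  # m
    provenance: str = "shutter-annotated"  # or "threshold-detected"
    time_offset: float = 0.0  # s, set by align_events

    @property
    def x(self) -> np.ndarray:
        return self.positions - self.equilibrium

    @property
    def n(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class EventCalibration:
    """Per-event calibrations plus ensemble statistics of omega_corrected."""

    results: tuple[CalibrationResult, ...]
    events: tuple[InfallEvent, ...]
    mean_omega: float  # 1/s, over valid events
    sd_omega: float  # 1/s, NaN when fewer than 2 valid events
    two_sigma: float  # 1/s
    n_valid: int
    n_invalid: int


def estimate_equilibrium(
    trace: Trace,
    trap_on_interval: tuple[int, int],
    tail_fraction: float = 0.5,
    min_samples: int = 4,
) -> float:
    """Trap-center estimate: mean over the settled tail of a trap-on interval.

    Uses the last ``tail_fraction`` of the interval, where the particle has
    relaxed to equilibrium and merely jitters about the trap center.
    """
    start, stop = trap_on_interval
    if not 0 <= start < stop <= trace.n:
        raise ValueError("trap-on interval out of range")
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must lie in (0, 1]")
    n = stop - start
    tail = max(int(round(n * tail_fraction)), 1)
    if n < min_samples:
        raise ValueError(
            f"trap-on interval of {n} samples too short to estimate equilibrium"
        )
    return float(np.mean(trace.positions[stop - tail : stop]))


def _infer_trap_on(
    trace: Trace, window: int, threshold: float
) -> list[tuple[int, int]]:
    """Fallback shutter inference from sliding-window variance collapse.

    Trapped motion has far smaller local variance than free diffusion; the
    rolling variance (about the local mean, so slow drift cancels) is
    compared against its median, taken as the free-diffusion level, and
    samples below ``threshold`` times that level are marked trapped.
    """
    x = trace.positions
    n = trace.n
    if n < 2 * window:
        return []
    csum = np.cumsum(np.insert(x, 0, 0.0))
    csq = np.cumsum(np.insert(x * x, 0, 0.0))
    m = (csum[window:] - csum[:-window]) / window
    v = (csq[window:] - csq[:-window]) / window - m * m
    free_level = float(np.median(v))
    trapped = v < threshold * free_level
    # close gaps shorter than a window so one trap-on period stays one event
    runs: list[list[int]] = []
    i = 0
    while i < trapped.size:
        if trapped[i]:
            j = i
            while j < trapped.size and trapped[j]:
                j += 1
            if runs and i - runs[-1][1] < window:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j
        else:
            i += 1
    intervals: list[tuple[int, int]] = []
    for i, j in runs:
        stop = min(j + window, n)
        # The rolling variance only collapses once the fall itself has left
        # the window, so walk the onset back to the displacement extremum
        # (relative to the settled tail) just before i.
        eq = float(np.mean(x[(i + stop) // 2 : stop]))
        lo = max(0, i - window)
        onset = lo + int(np.argmax(np.abs(x[lo : i + 1] - eq)))
        intervals.append((onset, stop))
    return intervals


def detect_events(
    trace: Trace,
    schedule: Optional[Sequence[tuple[int, int]]] = None,
    x0_min: float = X0_MIN_DEFAULT,
    x0_max: float = X0_MAX_DEFAULT,
    window: int = WINDOW_DEFAULT,
    detect_window: Optional[int] = None,
    variance_threshold: float = 0.2,
) -> list[InfallEvent]:
    """Find accepted in-fall events at trap-on onsets.

    ``schedule`` is a sequence of half-open trap-on sample intervals; when
    absent it is taken from ``trace.annotations["trap_on"]``, and failing
    that inferred from sliding-window variance collapse (window
    ``detect_window`` samples, default the event window; threshold
    ``variance_threshold`` times the free-diffusion variance).

    For each onset, the trap center is estimated from the settled tail of
    the interval; the event is accepted when ``x0_min < |x0| < x0_max`` and
    windowed to at most ``window`` samples, truncated to the contiguous run
    with ``|x - equilibrium| <= x0_max``.  Returns an empty list when no
    onset qualifies.
    """
    if schedule is None:
        schedule = trace.annotations.get("trap_on")
        provenance = "shutter-annotated"
    else:
        provenance = "shutter-annotated"
    if schedule is None:
        dw = detect_window or window
        schedule = _infer_trap_on(trace, dw, variance_threshold)
        provenance = "threshold-detected"

    out: list[InfallEvent] = []
    for start, stop in schedule:
        start, stop = int(start), int(stop)
        if stop - start < 2:
            continue
        try:
            eq = estimate_equilibrium(trace, (start, stop))
        except ValueError:
            continue
        x0 = float(trace.positions[start] - eq)
        if not x0_min < abs(x0) < x0_max:
            continue
        end = min(start + window, stop)
        seg = trace.positions[start:end]
        inside = np.abs(seg - eq) <= x0_max
        n_keep = int(np.argmin(inside)) if not inside.all() else inside.size
        if n_keep < 2:
            continue
        out.append(
            InfallEvent(
                start_index=start,
                x0=x0,
                positions=seg[:n_keep].copy(),
                dt=trace.dt,
                equilibrium=eq,
                provenance=provenance,
            )
        )
    return out


def align_events(
    events: Sequence[InfallEvent], x_ref: float = X0_MAX_DEFAULT
) -> list[InfallEvent]:
    """Time-shift events to a common projected start displacement.

    Each event is assigned ``time_offset = log(|x0|/x_ref)/omega`` (omega
    from a preliminary corrected-FORMA fit of its own window) so that all
    falls overlay as if released from ``x_ref``.  Used for overlay and
    reporting only -- never for estimation.  Events whose preliminary fit is
    invalid are skipped.
    """
    out = []
    for ev in events:
        res = calibrate(ev.x, ev.dt)
        if not res.valid:
            continue
        tau = float(np.log(abs(ev.x0) / x_ref) / res.omega_corrected)
        out.append(
            InfallEvent(
                start_index=ev.start_index,
                x0=ev.x0,
                positions=ev.positions,
                dt=ev.dt,
                equilibrium=ev.equilibrium,
                provenance=ev.provenance,
                time_offset=tau,
            )
        )
    return out


def force_position_curve(
    x, gamma: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Viscous-force estimator paired with position.

    ``f_n = gamma * (x_{n+1} - x_n) / dt`` plotted against ``x_n``
    (equilibrium-referenced).  On a noiseless fall the points lie on the
    straight line ``f = gamma (e^{omega dt} - 1)/dt * x``; during free
    diffusion there is no trend of f against x.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    f = gamma * np.diff(x) / dt
    return x[:-1], f


def calibrate_events(
    events: Sequence[InfallEvent],
    fluid: Optional[FluidContext] = None,
) -> EventCalibration:
    """Corrected-FORMA calibration of each event plus ensemble statistics.

    Statistics (mean, sd, 2*sd of omega_corrected) are computed over valid
    events only; a single valid event reports NaN spread.  Raises when no
    event yields a valid calibration.
    """
    if not events:
        raise ValueError("no events to calibrate")
    results = tuple(calibrate(ev.x, ev.dt, fluid=fluid) for ev in events)
    omegas = np.array([r.omega_corrected for r in results if r.valid])
    if omegas.size == 0:
        raise ValueError("all events invalid: calibration failed")
    sd = float(np.std(omegas, ddof=1)) if omegas.size > 1 else float("nan")
    return EventCalibration(
        results=results,
        events=tuple(events),
        mean_omega=float(np.mean(omegas)),
        sd_omega=sd,
        two_sigma=2.0 * sd,
        n_valid=int(omegas.size),
        n_invalid=int(len(results) - omegas.size),
    )


def stability_surface(
    event: InfallEvent,
    start_offsets: Sequence[int],
    lengths: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected-FORMA estimate as a function of window start and length.

    Returns ``(omega, valid)`` arrays of shape ``(len(start_offsets),
    len(lengths))``; cells whose window leaves the event, has fewer than 2
    samples, or yields a non-positive lag ratio are NaN with
    ``valid=False``.  The cell at (offset 0, full length) reproduces the
    per-event calibration exactly.

    Reliable estimates come from early starts (terminal-velocity part of
    the fall, highest signal-to-noise); windows started near equilibrium or
    extended deep into the settled tail are dominated by Brownian motion,
    measurement noise and blur and underestimate the trap frequency.
    """
    x = event.x
    omega = np.full((len(start_offsets), len(lengths)), np.nan)
    valid = np.zeros_like(omega, dtype=bool)
    for i, s in enumerate(start_offsets):
        for j, L in enumerate(lengths):
            if s < 0 or L < 2 or s + L > x.size:
                continue
            res = calibrate(x[s : s + L], event.dt)
            if res.valid:
                omega[i, j] = res.omega_corrected
                valid[i, j] = True
    return omega, valid
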