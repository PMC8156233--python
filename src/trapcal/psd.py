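"""Equilibrium power-spectrum calibration with aliasing and blur.

The position power spectral density of a bead at equilibrium in a linear
trap is a Lorentzian, one-sided

    L(f) = D / (pi^2 (fc^2 + f^2)),       fc = |omega_c| / (2 pi),

whose integral over (0, inf) is the stationary variance D/|omega_c|.
A tracking camera modifies it twice: exposure over a window ``W`` multiplies
the spectrum by ``sinc^2(pi f W)`` (motion blur), and sampling at ``fs``
folds power from ``f + j fs`` back into the Nyquist band (aliasing).  The
measured spectrum is therefore fitted with the truncated alias sum

    P(f) = sum_{j=-n..n} L(f + j fs) * sinc^2(pi (f + j fs) W).

Fitting is done as least squares of log(model) against the log of a
block-averaged periodogram (periodogram bins are exponentially distributed;
block averaging plus the log transform makes equal-weight least squares
well behaved without full spectral MLE machinery).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import welch

from .langevin import FluidContext, Trace

__all__ = ["SpectrumFit", "periodogram", "model_psd", "fit_psd"]


@dataclass(frozen=True)
class SpectrumFit:
    """Result of an aliased-blurred Lorentzian fit.

    ``omega_c = 2 pi fc`` (reported positive); ``stiffness`` is filled when
    a fluid context is supplied to :func:`fit_psd`.
    """

    fc: float  # Hz
    D: float  # m^2/s
    fs: float  # Hz
    exposure: float  # s
    n_alias: int
    residual_norm: float
    n_iter: int
    converged: bool
    boundary_warning: bool = False
    stiffness: Optional[float] = None  # N/m

    @property
    def omega_c(self) -> float:
        return 2.0 * np.pi * self.fc


def periodogram(trace: Trace, n_blocks: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Block-averaged one-sided periodogram of a position trace.

    The trace is cut into ``n_blocks`` non-overlapping rectangular blocks,
    each demeaned, and the one-sided power densities are averaged (Bartlett
    averaging).  Normalisation satisfies Parseval: ``sum(P) * df`` equals
    the sample variance.  Returns ``(f, P)`` with the zero-frequency bin
    dropped.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if trace.n < 2 * n_blocks:
        raise ValueError("trace too short for the requested number of blocks")
    nperseg = trace.n // n_blocks
    f, p = welch(
        trace.positions,
        fs=trace.fs,
        window="boxcar",
        nperseg=nperseg,
        noverlap=0,
        detrend="constant",
        scaling="density",
        return_onesided=True,
    )
    return f[1:], p[1:]


def model_psd(
    f,
    fc: float,
    D: float,
    fs: float,
    exposure: float = 0.0,
    n_alias: int = 10,
) -> np.ndarray:
    """Aliased, motion-blurred one-sided Lorentzian evaluated at ``f`` (Hz).

    ``exposure`` is the camera integration time in seconds (0 disables the
    blur factor); ``n_alias`` alias terms are included on each side.
    """
    if n_alias < 0:
        raise ValueError("n_alias must be >= 0")
    f = np.atleast_1d(np.asarray(f, dtype=float))
    j = np.arange(-n_alias, n_alias + 1)
    nu = f[:, None] + j[None, :] * fs
    lor = D / (np.pi**2 * (fc * fc + nu * nu))
    if exposure > 0.0:
        arg = np.pi * nu * exposure
        blur = np.sinc(arg / np.pi) ** 2  # np.sinc(x) = sin(pi x)/(pi x)
        lor = lor * blur
    return lor.sum(axis=1)


def _alias_sum_converged(f, fc, D, fs, exposure, n_alias, rtol=1e-6):
    """Double the truncation until the model stops changing."""
    cur = model_psd(f, fc, D, fs, exposure, n_alias)
    while True:
        n_alias *= 2
        nxt = model_psd(f, fc, D, fs, exposure, n_alias)
        if np.max(np.abs(nxt - cur) / nxt) < rtol or n_alias > 4096:
            return nxt, n_alias
        cur = nxt


def fit_psd(
    psd: tuple[np.ndarray, np.ndarray],
    fs: float,
    exposure: Optional[float] = None,
    init: Optional[tuple[float, float]] = None,
    band: Optional[tuple[float, float]] = None,
    n_alias: int = 10,
    fluid: Optional[FluidContext] = None,
) -> SpectrumFit:
    """Fit the aliased-blurred Lorentzian to a measured periodogram.

    Parameters
    ----------
    psd
        ``(f, P)`` as returned by :func:`periodogram` (positive powers).
    fs
        Sampling (frame) rate, Hz.
    exposure
        Camera integration time, s.  Defaults to the full frame period
        ``1/fs`` (streaming camera); pass 0 for snapshot data.
    init
        Optional ``(fc, D)`` starting point; otherwise fc starts at fs/8
        and D from the low-frequency plateau.
    band
        Fit band in Hz; defaults to (50, fs/2) -- the low-frequency drift
        band is excluded because slow setup noise contaminates the plateau.
    n_alias
        Initial alias truncation; doubled until the model is converged to
        1e-6 relative before fitting.
    """
    f, p = np.asarray(psd[0], dtype=float), np.asarray(psd[1], dtype=float)
    if exposure is None:
        exposure = 1.0 / fs
    if band is None:
        band = (50.0, fs / 2.0)
    keep = (f >= band[0]) & (f <= band[1]) & (p > 0)
    f, p = f[keep], p[keep]
    if f.size < 10:
        raise ValueError("need at least 10 positive periodogram bins in band")

    if init is None:
        fc0 = fs / 8.0
        plateau = float(np.median(p[f < np.quantile(f, 0.2)]))
        D0 = max(plateau, 1e-300) * np.pi**2 * fc0**2
    else:
        fc0, D0 = init

    # converge the alias truncation once at the starting point
    _, n_alias = _alias_sum_converged(f, fc0, D0, fs, exposure, n_alias)
    logp = np.log(p)

    def resid(theta):
        fc, D = np.exp(theta)
        return np.log(model_psd(f, fc, D, fs, exposure, n_alias)) - logp

    sol = least_squares(resid, np.log([fc0, D0]), method="lm", max_nfev=2000)
    fc, D = np.exp(sol.x)
    boundary = bool(fc <= 1.05 * band[0] or fc >= 0.95 * band[1])
    stiffness = None
    if fluid is not None:
        stiffness = fluid.gamma * 2.0 * np.pi * fc
    return SpectrumFit(
        fc=float(fc),
        D=float(D),
        fs=fs,
        exposure=exposure,
        n_alias=n_alias,
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_iter=int(sol.nfev),
        converged=bool(sol.success),
        boundary_warning=boundary,
        stiffness=stiffness,
    )
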