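# Methods

## Physical model

A micron-scale bead held by optical tweezers near the focus behaves as an
overdamped particle in a (nearly) linear trap:

    dx/dt = F(x)/γ + √(2D) ξ(t),        F(x) ≈ −k x near the center,

with Stokes drag γ = 6πηr, thermal diffusion D = k_B T/γ, and white noise
ξ. For the linear trap this is an Ornstein–Uhlenbeck (OU) process with
angular trap frequency ω_c = −k/γ (negative for a stable trap; user-facing
reports quote |ω_c| and the stiffness k = γ|ω_c|). Default physical
constants are T = 298 K, η = 8.9×10⁻⁴ Pa·s, r = 1 μm, giving
γ = 1.678×10⁻⁸ kg/s and D = 2.45×10⁻¹³ m²/s — a free-diffusion rms
wander of 7.0 nm per 100 μs sample.

## The estimators

FORMA regresses the finite-difference velocity estimator
y_n/Δt = (x_{n+1}−x_n)/Δt on position:

    ω̂ = (1/Δt) Σ x_n y_n / Σ x_n².

At finite sampling rate this is biased: on a noiseless relaxation it
returns (e^{ω_c Δt}−1)/Δt, a 26% magnitude underestimate at
|ω_c|Δt = 0.628 (the operating point: |ω_c|Δt/2π = 0.1 at 10 kHz). The
discretely observed OU process is exactly AR(1),
x_{n+1} = e^{ω_c Δt} x_n + ξ_n, which gives the aliasing-corrected
estimator implemented here:

    ω̂_corr = log(Σ x_n x_{n+1} / Σ x_n²) / Δt,

valid while the lag ratio S = Σ x_n x_{n+1}/Σ x_n² is positive. Invalid
windows (S ≤ 0, increasingly likely for very stiff traps and short
windows) are returned as structured flags, never as NaN surprises or
complex numbers, with equipartition calibration (k = k_B T/var(x)) as the
recommended fallback. The matching diffusion estimator

    D̂ = (1/2Δt) · (2ω̂Δt/(e^{2ω̂Δt}−1)) · mean((x_{n+1}−e^{ω̂Δt}x_n)²)

is exactly unbiased on AR(1) data (E[ξ²] = D(1−e^{2ωΔt})/|ω|); the ω → 0
prefactor limit is taken analytically, recovering the plain MSD estimator.

No internal mean subtraction is performed: the estimators assume
equilibrium-referenced positions, and the event pipeline does the
referencing explicitly (centering choices materially affect 20-sample
windows).

Exposure blur (a moving average over the camera integration window) maps a
pure exponential onto another exponential with the *same* rate, so
ω̂_corr on a high signal-to-noise fall is blur-invariant; diffusion
estimates are not, and no such claim is made or tested for blurred data.

## Simulation and the camera chain

Trajectories are integrated with stochastic Heun (RK2) steps at
Δt_fine = 10⁻⁵ s: a single Gaussian increment per step shared by predictor
and corrector, drift evaluated at both. Against an exact-OU sampler driven
by the same noise stream, the integrator's stationary variance and lag-1
autocorrelation agree to well under 1% at the default step. The camera
chain applies, in order: exposure blur (mean over the exposure window at
the start of each frame), snapshot downsampling to the frame rate (the
operation that aliases), additive white tracking noise, and optionally a
low-frequency noise component modelled as a first-order low-passed
Gaussian process (variance-normalised, default 10 Hz cutoff). Blur and
snapshot sampling are deliberately separate operations so the two camera
artefacts can be tested independently.

The catch-and-release protocol alternates shutter-off free diffusion
(default 360 ms, the mean time to diffuse Δx ≈ 420 nm via Δt = Δx²/2D)
with trapped relaxation (default 40 ms ≈ 40 trap periods, enough to
settle); position is continuous across shutter edges and trap-on intervals
are recorded as annotations.

## Event pipeline

Events are accepted when the start displacement satisfies
160 nm < |x₀| < 400 nm — far enough out that the fall dominates the ~10 nm
measurement noise, close enough in that nonlinear stiffness does not
contaminate the estimate — and windowed to 2 ms (20 samples ≈ 1–2 trap
periods) truncated to |x − equilibrium| ≤ 400 nm. The trap center is the
mean over the settled tail (last 50%) of each trap-on interval; x₀ is the
first trap-on sample, signed, and sub-frame onset jitter is ignored. When
no shutter schedule exists, onsets are inferred from sliding-window
variance collapse (window = one event window, threshold 0.2× the median
rolling variance, which free diffusion dominates); because the rolling
variance only collapses after the fall leaves the window, the onset is
walked back to the preceding displacement extremum. Threshold detection is
a fallback: its parameters are explicit configuration, and every
accept/reject decision is logged.

The stability surface recomputes ω̂_corr over a grid of window starts and
lengths. Early starts at terminal velocity give stable estimates; windows
started near equilibrium, or extended deep into the settled tail, are
dominated by Brownian motion, blur and correlated noise and underestimate
|ω_c|. Note the direction of that trend depends on the noise character:
*white* noise inflates the denominator Σx² and biases |ω̂_corr| up, while
blur and low-frequency (drift-like) noise raise the lag-1 correlation and
bias it toward zero. The synthetic experiment preset therefore uses
full-frame exposure, 1 nm white tracking noise and 8 nm low-frequency
noise, which reproduces the late-start underestimation seen in real
camera data.

## Power-spectrum baseline

The equilibrium reference calibration fits the one-sided Lorentzian
L(f) = D/(π²(f_c²+f²)), multiplied by the blur factor sinc²(πfW) and
folded over ±n alias terms, to a Bartlett (block-averaged, ≥16 blocks)
periodogram in log-log space with equal bin weights. The alias truncation
starts at n = 10 and doubles until the model changes by <10⁻⁶ relative;
the snapshot-sampled (W = 0) alias sum reproduces the closed-form AR(1)
spectrum to ~10⁻⁴, which serves as an independent oracle in the tests.
Frequencies below 50 Hz are excluded by default because slow setup noise
contaminates the plateau. Fitting blurred data with the blur factor
disabled biases f_c low by tens of percent — the reason the blur-aware
model is the default for streaming-camera data (exposure = frame period).

## Monte-Carlo campaign

The replication preset simulates 1000 falls: linear trap at
ω_act = −2π·1000 s⁻¹ (|ω|Δt/2π = 0.1 at f_s = 10 kHz), RK2 at 10⁻⁵ s,
snapshot downsampling, start displacement 400 nm, 10 nm additive white
position noise, both estimators evaluated on growing windows (3–40
samples) with the headline statistics read at the 2 ms window. Campaigns
are vectorised across runs and fully determined by one seed; stored
per-run traces let every summary number be reproduced externally with the
single-window estimators.

Under this preset the corrected estimator's ensemble mean ratio
ω̂_corr/ω_act lands ~1–2% above unity with a relative spread of ~6%, and
the uncorrected estimator shows the analytic ~26% aliasing bias — a
≈23-percentage-point accuracy gap. The mean sits *above* one because
white measurement noise can only attenuate the lag ratio; a mean slightly
below one, and spreads near 4%, arise instead when the measurement error
is dominated by low-frequency (correlated) noise, as in the experimental
characterization. The noise composition at fixed total amplitude is thus
the single most influential nuisance parameter of this calibration, which
is why the measurement model keeps the white and low-frequency amplitudes
independently configurable.

## What the synthetic data does and does not emulate

The generator reproduces overdamped 1D motion, trap nonlinearity (via the
Gaussian-profile force law F = −k₀x·e^{−x²/w²} or tabulated
force-extension curves), discrete snapshot sampling, exposure blur,
white and low-frequency position noise, and the shutter protocol. It does
not model inertia, hydrodynamic memory, 3D motion, camera image formation
(tracking noise is injected directly as position noise), or
electromagnetic force computation — the Gaussian-profile trap stands in
for full force curves and preserves the two properties the diagnostics
rely on: a near-linear core and stiffness decay with displacement
(derivative ratio F‴(0)/F′(0) = −6/w²). Passing tests therefore validate
the estimators and pipeline against the stated stochastic model, not
against unmodelled camera or beam-pointing pathologies.

## Numerical choices and degenerate inputs

* Trap-frequency sign convention: ω_c < 0 internally; stiffness always
  positive.
* Tabulated derivatives: 5-point central differences on a cubic-spline
  resample with step = half-range/400 (<0.1% truncation error on smooth
  tables; well above roundoff).
* Linear-region search: grid scan plus bisection; a tolerance never
  exceeded within the scan limit returns the limit with an `unbounded`
  flag, a tolerance violated arbitrarily close to zero returns 0 with an
  `empty` flag.
* Zero-variance traces, all-zero regressors (including underflowing
  sub-normal inputs), non-positive lag ratios, and out-of-range tabulated
  evaluations raise typed, message-bearing errors.
* All randomness flows through `numpy.random.Generator` seeds; every
  simulation is bit-reproducible for a fixed seed.

## Problem sizes

Default test and reproduction sizes are desk-scale: 1000-run campaigns of
40 camera samples each, 5 s equilibrium traces at 10 kHz, 12-cycle
(≈4.8 s) catch-and-release records, and 100-seed diffusion ensembles of
10⁵ samples; the full suite runs in about a minute on one core.
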