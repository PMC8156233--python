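import numpy as np
import pytest

import trapcal as tc
from trapcal.langevin import rk2_paths

from conftest import DT_FINE, OMEGA_ACT


class _ReplayRNG:
    """Feed a pre-drawn standard-normal table to rk2_paths."""

    def __init__(self, draws):
        self._rows = iter(draws)

    def standard_normal(self, size):
        row = next(self._rows)
        assert row.size == size
        return row


class TestRK2:
    def test_deterministic_limit_matches_exponential(self, fluid, linear_model):
        # zero diffusion: x(t) = x0 exp(-(k0/gamma) t), RK2 error O(dt^2)
        k_over_g = linear_model.k0 / fluid.gamma
        dt = 1e-2 / k_over_g
        tr = tc.simulate_fine(
            linear_model, fluid, 400e-9, dt, 200, seed=0, diffusion=0.0
        )
        expect = 400e-9 * np.exp(-k_over_g * tr.times)
        assert np.max(np.abs(tr.positions / expect - 1.0)) < 1e-4

    def test_free_diffusion_msd(self, fluid):
        free = tc.linear_trap(1e-20)  # negligible restoring force
        rng = np.random.default_rng(1)
        paths = rk2_paths(free, fluid, np.zeros(2000), DT_FINE, 100, rng)
        msd = np.mean(paths[:, -1] ** 2)
        expect = 2.0 * fluid.diffusion * (100 * DT_FINE)
        assert msd == pytest.approx(expect, rel=0.1)

    def test_stationary_variance(self, fluid, linear_model):
        # OU stationary variance D/|omega_c| from a long equilibrated ensemble
        rng = np.random.default_rng(2)
        omega = -linear_model.k0 / fluid.gamma
        paths = rk2_paths(linear_model, fluid, np.zeros(500), DT_FINE, 4000, rng)
        var = np.var(paths[:, 2000:])
        assert var == pytest.approx(fluid.diffusion / abs(omega), rel=0.05)

    def test_matches_exact_ou_sampler(self, fluid):
        # RK2-then-downsample vs the exact AR(1) sampler driven by the SAME
        # Gaussian increments: stationary variance and lag-1 autocorrelation
        # agree to <1% at omega*dt_fine = -0.0063 (common random numbers
        # isolate the discretisation bias from Monte-Carlo noise)
        omega = -0.0063 / DT_FINE
        model = tc.linear_trap(fluid.gamma * abs(omega))
        n_paths, n_steps = 200, 3000
        draws = np.random.default_rng(3).standard_normal((n_steps, n_paths))

        rk2 = rk2_paths(
            model, fluid, np.zeros(n_paths), DT_FINE, n_steps,
            _ReplayRNG(draws),
        )
        phi = np.exp(omega * DT_FINE)
        sd = np.sqrt(fluid.diffusion * (1 - phi * phi) / abs(omega))
        exact = np.zeros((n_paths, n_steps + 1))
        for i in range(n_steps):
            exact[:, i + 1] = phi * exact[:, i] + sd * draws[i]

        rk2 = rk2[:, 1000::10]  # discard transient, downsample to 10 kHz
        exact = exact[:, 1000::10]

        def lag1(a):
            return np.mean(a[:, :-1] * a[:, 1:]) / np.mean(a[:, :-1] ** 2)

        assert np.var(rk2) == pytest.approx(np.var(exact), rel=0.01)
        assert lag1(rk2) == pytest.approx(lag1(exact), rel=0.01)

    def test_instability_reported_with_step_index(self, fluid):
        stiff = tc.linear_trap(1.0)  # absurd stiffness -> overflow
        with pytest.raises(FloatingPointError, match="step"):
            tc.simulate_fine(stiff, fluid, 1e-7, 1.0, 50, seed=0)


class TestDownsample:
    def test_identity(self, noiseless_fall):
        out = tc.downsample(noiseless_fall, 1)
        assert np.array_equal(out.positions, noiseless_fall.positions)
        assert out.dt == noiseless_fall.dt

    def test_snapshot_semantics(self, fluid, linear_model):
        tr = tc.simulate_fine(linear_model, fluid, 4e-7, DT_FINE, 1000, seed=5)
        out = tc.downsample(tr, 10)
        assert out.dt == pytest.approx(1e-4)
        assert out.n == 101
        assert np.array_equal(out.positions, tr.positions[::10])

    def test_composition(self, fluid, linear_model):
        tr = tc.simulate_fine(linear_model, fluid, 4e-7, DT_FINE, 1000, seed=5)
        a = tc.downsample(tc.downsample(tr, 2), 5)
        b = tc.downsample(tr, 10)
        assert np.array_equal(a.positions, b.positions) and a.dt == b.dt

    def test_bad_factor(self, noiseless_fall):
        with pytest.raises(ValueError):
            tc.downsample(noiseless_fall, 0)


class TestBlur:
    def test_one_step_exposure_equals_downsample(self, fluid, linear_model):
        tr = tc.simulate_fine(linear_model, fluid, 4e-7, DT_FINE, 1000, seed=6)
        blur = tc.apply_blur(tr, 1e-4, 0.0)  # rounds up to 1 fine step
        snap = tc.downsample(tr, 10)
        assert np.allclose(blur.positions, snap.positions[: blur.n])

    def test_preserves_exponential_rate(self):
        # window-mean of e^{omega t} is a constant times e^{omega t}
        fine = tc.Trace(4e-7 * np.exp(OMEGA_ACT * DT_FINE * np.arange(3000)), DT_FINE)
        blurred = tc.apply_blur(fine, 1e-4, 1.0)
        rate = tc.forma_corrected(blurred.positions, blurred.dt)
        assert rate == pytest.approx(OMEGA_ACT, rel=1e-12)
        assert blurred.positions[0] < fine.positions[0]  # amplitude rescaled

    def test_constant_input_invariant(self):
        tr = tc.Trace(np.full(1000, 2.5e-7), DT_FINE)
        out = tc.apply_blur(tr, 1e-4, 1.0)
        assert np.allclose(out.positions, 2.5e-7)

    def test_exposure_longer_than_frame_rejected(self, noiseless_fall):
        with pytest.raises(ValueError):
            tc.apply_blur(noiseless_fall, 2 * noiseless_fall.dt, 1.5)


class TestNoise:
    def test_zero_noise_identity(self, noiseless_fall):
        mm = tc.MeasurementModel()
        out = tc.add_noise(noiseless_fall, mm, seed=0)
        assert np.array_equal(out.positions, noiseless_fall.positions)

    def test_white_noise_sd(self):
        tr = tc.Trace(np.zeros(100_000), DT_FINE)
        out = tc.add_noise(tr, tc.MeasurementModel(noise_sigma=10e-9), seed=1)
        assert np.std(out.positions) == pytest.approx(10e-9, rel=0.01)

    def test_lowfreq_noise_variance_normalised(self):
        tr = tc.Trace(np.zeros(200_000), 1e-4)
        mm = tc.MeasurementModel(lowfreq_sigma=8e-9, lowfreq_cutoff=10.0)
        out = tc.add_noise(tr, mm, seed=2)
        # correlated process: generous Monte-Carlo tolerance
        assert np.std(out.positions) == pytest.approx(8e-9, rel=0.15)

    def test_seeded_repeatability(self, noiseless_fall):
        mm = tc.MeasurementModel(noise_sigma=1e-9, lowfreq_sigma=8e-9)
        a = tc.add_noise(noiseless_fall, mm, seed=3)
        b = tc.add_noise(noiseless_fall, mm, seed=3)
        assert np.array_equal(a.positions, b.positions)


class TestCatchRelease:
    def test_intervals_annotated(self, catch_release_trace):
        iv = catch_release_trace.annotations["trap_on"]
        assert len(iv) == 12
        # camera frames: 0.36 s off then 0.04 s on, at 10 kHz
        assert iv[0] == (3600, 4000)
        assert all(b - a == 400 for a, b in iv)

    def test_n_cycles_zero_is_free_diffusion(self, fluid, linear_model):
        mm = tc.MeasurementModel()
        tr = tc.simulate_catch_release(
            linear_model, fluid, mm, n_cycles=0, seed=4
        )
        assert tr.annotations["trap_on"] == []
        msd = np.mean(np.diff(tr.positions) ** 2)
        assert msd == pytest.approx(2 * fluid.diffusion * tr.dt, rel=0.05)

    def test_deterministic_limit_pure_decay(self, fluid, linear_model):
        mm = tc.MeasurementModel()
        tr = tc.simulate_catch_release(
            linear_model, fluid, mm,
            trap_off_duration=0.0, trap_on_duration=0.004,
            n_cycles=2, seed=0, x_start=400e-9, diffusion=0.0,
        )
        start, stop = tr.annotations["trap_on"][0]
        seg = tr.positions[start:stop][:20]
        # geometric to machine precision (RK2 is deterministic here) ...
        ratios = seg[1:] / seg[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)
        # ... at a rate matching omega to the RK2 discretisation error
        assert tc.forma_corrected(seg, tr.dt) == pytest.approx(OMEGA_ACT, rel=1e-3)

    def test_off_interval_rms_follows_diffusion_law(self, fluid, linear_model):
        mm = tc.MeasurementModel()
        tr = tc.simulate_catch_release(
            linear_model, fluid, mm, n_cycles=40, seed=11
        )
        iv = tr.annotations["trap_on"]
        # displacement accrued over each 360 ms off interval
        d = [
            tr.positions[iv[k][0]] - tr.positions[iv[k - 1][1] - 1]
            for k in range(1, len(iv))
        ]
        rms = np.sqrt(np.mean(np.square(d)))
        assert rms == pytest.approx(np.sqrt(2 * fluid.diffusion * 0.36), rel=0.25)

    def test_position_continuous_across_boundaries(self, catch_release_trace):
        # no teleportation: steps at segment boundaries comparable to others
        steps = np.abs(np.diff(catch_release_trace.positions))
        assert steps.max() < 500e-9
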