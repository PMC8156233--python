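import numpy as np
import pytest

import trapcal as tc

OMEGA_ACT = -2.0 * np.pi * 1000.0  # 1/s, |omega| dt / 2pi = 0.1 at 10 kHz
DT_CAMERA = 1e-4  # s
DT_FINE = 1e-5  # s


@pytest.fixture(scope="session")
def fluid():
    return tc.FluidContext()


@pytest.fixture(scope="session")
def linear_model(fluid):
    return tc.linear_trap(fluid.gamma * abs(OMEGA_ACT))


@pytest.fixture
def noiseless_fall():
    """Pure exponential relaxation from 400 nm at the operating point."""
    x = 400e-9 * np.exp(OMEGA_ACT * DT_CAMERA * np.arange(20))
    return tc.Trace(x, DT_CAMERA)


@pytest.fixture(scope="session")
def catch_release_trace(fluid, linear_model):
    """Shutter-cycled synthetic experiment through the camera chain.

    Full-frame exposure blur, 1 nm white tracking noise and 8 nm
    low-frequency noise; 12 cycles of 360 ms free diffusion + 40 ms trapped.
    """
    mm = tc.MeasurementModel(
        exposure_fraction=1.0, noise_sigma=1e-9, lowfreq_sigma=8e-9
    )
    return tc.simulate_catch_release(
        linear_model, fluid, mm, n_cycles=12, seed=7
    )
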