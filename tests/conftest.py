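import numpy as np
import pytest

from drawcog import DeviceProfile, PenStream, make_session_plan, simulate_session


@pytest.fixture(scope="session")
def device():
    return DeviceProfile()


def random_generating_params(rng):
    """Plausible per-session kinematic generating parameters."""
    return {
        "speed_mean": rng.uniform(25.0, 80.0),
        "speed_cv": rng.uniform(0.25, 0.8),
        "pressure_mad": rng.uniform(0.02, 0.12),
        "incl_h_sd": rng.uniform(2.0, 15.0),
        "incl_v_sd": rng.uniform(2.0, 12.0),
        "pause_ratio": rng.uniform(0.15, 0.9),
    }


@pytest.fixture(scope="session")
def session_factory(device):
    """Short random synthetic sessions (few targets, a few seconds long)."""

    def make(seed, n_targets=6):
        rng = np.random.default_rng(seed)
        plan = make_session_plan(random_generating_params(rng), device, rng,
                                 n_targets=n_targets)
        return simulate_session(plan, device, rng)

    return make


@pytest.fixture(scope="session")
def walk_stream_factory(device):
    """Random-walk pen streams with optional pen-up gaps, for pause tests."""

    def make(seed, n=300, step_mm=0.05, n_gaps=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / device.sampling_rate_hz
        x = 100.0 + np.cumsum(rng.normal(0.0, step_mm, size=n))
        y = 90.0 + np.cumsum(rng.normal(0.0, step_mm, size=n))
        pressure = rng.uniform(0.2, 0.9, size=n)
        hover = np.zeros(n)
        for _ in range(n_gaps):
            lo = int(rng.integers(1, n - 10))
            hi = lo + int(rng.integers(2, 8))
            pressure[lo:hi] = 0.0
            hover[lo:hi] = 2.0
        return PenStream(t=t, x=x, y=y, pressure=pressure,
                         incl_h=60 + np.cumsum(rng.normal(0, 0.2, n)),
                         incl_v=55 + np.cumsum(rng.normal(0, 0.2, n)),
                         hover=hover, device=device)

    return make
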