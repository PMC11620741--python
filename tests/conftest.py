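import numpy as np
import pytest

from mcellmsi import SimParams, Trace
from mcellmsi.protocols import build_auditory_pip, build_tectal_train


@pytest.fixture(scope="session")
def params() -> SimParams:
    return SimParams.default()


@pytest.fixture(scope="session")
def nf_params(params) -> SimParams:
    """Noise-free parameter set (no recording noise, no trial jitter)."""
    return params.noise_free()


@pytest.fixture
def pip():
    return build_auditory_pip(0.0)


@pytest.fixture
def train_60hz_100ms():
    return build_tectal_train(60.0, 100.0)


def make_trace(values, fs_hz=25000.0, t0_ms=-50.0) -> Trace:
    return Trace(np.asarray(values, dtype=float), fs_hz, t0_ms)


@pytest.fixture
def flat_trace():
    """200 ms of flat -80 mV starting 50 ms before the stimulus."""
    n = int(0.2 * 25000)
    return make_trace(np.full(n, -80.0))
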