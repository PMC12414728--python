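import numpy as np
import pytest

from bagmove.telemetry import Telemetry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_telemetry():
    """Noiseless straight-line movement: x = 2t, y = -t at unit spacing."""
    t = np.arange(50, dtype=float)
    return Telemetry(t, 2.0 * t, -1.0 * t)


@pytest.fixture
def constant_telemetry():
    """An animal parked at (12, -7), recorded 40 times."""
    t = np.linspace(0.0, 100.0, 40)
    return Telemetry(t, np.full(40, 12.0), np.full(40, -7.0))


@pytest.fixture
def noisy_telemetry(rng):
    """Smooth sinusoidal path sampled irregularly with iid location noise."""
    t = np.sort(rng.uniform(0, 500, 120))
    x = 80 * np.sin(2 * np.pi * t / 200) + rng.normal(0, 5, t.size)
    y = 40 * np.cos(2 * np.pi * t / 150) + rng.normal(0, 5, t.size)
    return Telemetry(t, x, y)
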