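import numpy as np
import pytest

from gaborclean.recording import Recording
from gaborclean.simulate import SimulationSpec, simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One small default-condition simulation shared across read-only tests."""
    spec = SimulationSpec(n_events=10, seed=7)
    rec, truth = simulate(spec)
    return spec, rec, truth


@pytest.fixture()
def flat_recording():
    """Three constant channels, handy for arithmetic checks."""
    samples = np.vstack([
        np.full(4000, 2.0),
        np.full(4000, 0.5),
        np.zeros(4000),
    ])
    return Recording(samples=samples, fs=2000.0,
                     channel_labels=["A1", "A2", "A3"])
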