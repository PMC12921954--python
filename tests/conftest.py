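import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spikegaze as sg

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_stream(rng, n=200, width=32, height=32, t_max=50_000):
    """Random valid event stream used across modules."""
    return sg.EventStream.from_arrays(
        rng.integers(0, width, n), rng.integers(0, height, n),
        np.sort(rng.integers(0, t_max, n)),
        rng.choice((-1, 1), n), width, height, 0, t_max)


@pytest.fixture
def stream(rng):
    return make_stream(rng)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small simulated dataset shared by tests that need real segments.

    48x48 sensor, 6 segments per class; the same code path as the full
    generator, kept small for speed.
    """
    scene = sg.default_scene(48, 48)
    kin = sg.default_kinematics(48, 48)
    emu = sg.EmulatorParams(seed=0)
    return sg.generate_dataset(scene, kin, emu, n_per_class=6, seed=99)
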