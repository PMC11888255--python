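import numpy as np
import pytest

from tbslice import protocol as proto
from tbslice import synthetic_data as synth


@pytest.fixture(scope="session")
def default_train():
    return proto.generate_pulse_train()


@pytest.fixture(scope="session")
def spine_set_control():
    p = synth.SpineSimParams(n_segments=20, seed=42)
    return synth.simulate_spine_trajectory_set(p, condition="control")


@pytest.fixture(scope="session")
def mepsc_fixture():
    p = synth.MepscSimParams(duration=60.0, seed=5)
    trace, truth = synth.simulate_mepsc_trace(p)
    return p, trace, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
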