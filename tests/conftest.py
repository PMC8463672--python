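import numpy as np
import pytest
from hypothesis import settings

import spikewac as sw

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_locomotion():
    """8-neuron, 60 s rate-coded locomotion recording shared across tests."""
    spec = sw.SimulationSpec(n_neurons=8, duration_s=60.0, seed=7, mode="locomotion")
    raster, kin = sw.simulate(spec)
    return raster, kin


@pytest.fixture(scope="session")
def small_center_out():
    spec = sw.SimulationSpec(n_neurons=8, duration_s=60.0, seed=7, mode="center_out")
    raster, kin = sw.simulate(spec)
    return raster, kin
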