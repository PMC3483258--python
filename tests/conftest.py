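import numpy as np
import pytest

from crossmeth.simulate import SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest two-species simulation shared across read-only tests."""
    return simulate(SimulationConfig(n_regions=40, seed=7, dmr_fraction=0.25))
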