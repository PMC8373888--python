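import numpy as np
import pytest

from glioconn import SimulationConfig, make_atlas, simulate_cohort


@pytest.fixture(scope="session")
def toy_atlas():
    """8-region odd/even atlas for hand-checkable compartment arithmetic."""
    return make_atlas(8)


@pytest.fixture(scope="session")
def reduced_cohort():
    """One reduced-size cohort shared by structural tests."""
    return simulate_cohort(SimulationConfig.reduced(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
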