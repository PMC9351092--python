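import numpy as np
import pytest
from hypothesis import settings

from gdnacontam import SimulationConfig, simulate_experiment

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_experiment():
    """One multinomial-noise experiment under the study conditions."""
    return simulate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noisefree_experiment():
    """Same design with exact expected counts (noise='none')."""
    return simulate_experiment(SimulationConfig(seed=11, noise="none"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
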