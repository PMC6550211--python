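import numpy as np
import pytest

from phenostress.config import SimConfig
from phenostress.simulate import simulate_subject
from phenostress.types import Phenotype


@pytest.fixture(scope="session")
def sim_config_1day() -> SimConfig:
    return SimConfig(days=1)


@pytest.fixture(scope="session")
def responsive_subject(sim_config_1day):
    """One responsive subject, one simulated day (shared across tests)."""
    return simulate_subject("R000", Phenotype.RESPONSIVE, 12345, sim_config_1day)


@pytest.fixture(scope="session")
def blunted_subject(sim_config_1day):
    return simulate_subject("B000", Phenotype.BLUNTED, 54321, sim_config_1day)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
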