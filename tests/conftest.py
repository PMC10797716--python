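import numpy as np
import pytest
from hypothesis import settings

from asthma_cua import ScenarioSpec, synthetic_life_table, table1_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """The packaged base-case parameter set."""
    return table1_fixture()


@pytest.fixture(scope="session")
def life_table():
    return synthetic_life_table()


@pytest.fixture(scope="session")
def scenario():
    return ScenarioSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20240118)


@pytest.fixture
def short_scenario():
    """A 60-cycle horizon for cheap engine runs."""
    return ScenarioSpec(horizon=60)
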