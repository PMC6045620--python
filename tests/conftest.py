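import numpy as np
import pytest

from pyrocast import SyntheticScenario, generate_ba, generate_climate, seasonal_to_monthly
from pyrocast.preprocess import SeasonSpec


@pytest.fixture(scope="session")
def small_scenario():
    return SyntheticScenario(n_lat=2, n_lon=3, seed=11)


@pytest.fixture(scope="session")
def small_climate(small_scenario):
    return generate_climate(small_scenario)


@pytest.fixture(scope="session")
def jja():
    return SeasonSpec("JJA")


@pytest.fixture(scope="session")
def small_pipeline(small_scenario, small_climate, jja):
    """Scenario, monthly climate, seasonal BA and the monthly BA field."""
    precip, temp = small_climate
    ba = generate_ba(small_scenario, precip, jja)
    monthly = seasonal_to_monthly(ba, jja, precip["time"].dt)
    return small_scenario, precip, temp, ba, monthly


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
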