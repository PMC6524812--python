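import numpy as np
import pytest

from leksim.demographic_core import RealizedRates, SiteState, default_vital_rates


@pytest.fixture(scope="session")
def table_rates():
    return default_vital_rates()


@pytest.fixture(scope="session")
def mean_rates(table_rates):
    return RealizedRates.from_means(table_rates)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture()
def start_state():
    """Default site initialization: 50 F + 50 M at 60:40 ASY:SY."""
    return SiteState(female_sy=20, female_asy=30, male_sy=20, male_asy=30)
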