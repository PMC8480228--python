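import numpy as np
import pytest

from herdclim import (
    EmulatorParams,
    ScenarioConfig,
    make_bau_livestock_ch4,
    make_mitigation_scenario,
)


@pytest.fixture(scope="session")
def params():
    return EmulatorParams()


@pytest.fixture(scope="session")
def scenario():
    """(co2, ch4_mitigation, ch4_bau) under the default configuration."""
    config = ScenarioConfig()
    co2, ch4 = make_mitigation_scenario(config)
    bau = make_bau_livestock_ch4(config)
    return co2, ch4, bau


@pytest.fixture
def rng():
    return np.random.default_rng(20211115)
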