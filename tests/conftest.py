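import numpy as np
import pytest

import phenomass as pm


@pytest.fixture(scope="session")
def small_config():
    return pm.SimConfig(n_hybrids=60, n_markers=300, n_cal_hybrids=20, seed=1)


@pytest.fixture(scope="session")
def markers(small_config):
    return pm.simulate_markers(small_config)


@pytest.fixture(scope="session")
def weather(small_config):
    return pm.simulate_weather(small_config, year="2019")


@pytest.fixture(scope="session")
def trial(small_config, markers, weather):
    return pm.simulate_trial(small_config, markers, weather,
                             trial_id="Tc", year="2019")


@pytest.fixture(scope="session")
def catalog():
    return pm.default_catalog()


@pytest.fixture(scope="session")
def tensor(trial, weather, catalog):
    return pm.extract_trial_features(trial, weather, catalog)
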