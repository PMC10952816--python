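import numpy as np
import pytest

from msam import CommunityAbundanceModel, McmcConfig
from msam.experiments import calibration_scenario
from msam.simulate import simulate_dataset
from msam.survey import table1_fixture


@pytest.fixture(scope="session")
def fixture_table():
    return table1_fixture()


@pytest.fixture(scope="session")
def small_sim():
    """Study-scale simulated community (4 species, 30 sites, 3 surveys)."""
    from dataclasses import replace
    return simulate_dataset(replace(calibration_scenario(), seed=5))


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A short 2-chain fit of the generating model, shared across tests."""
    model = CommunityAbundanceModel.from_simulation(small_sim)
    return model.fit(McmcConfig(n_chains=2, n_iter=12_000, n_burnin=4_000,
                                thin=10, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
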