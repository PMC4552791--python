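import numpy as np
import pytest

from alderhydro.synthetic_data import SyntheticConfig, simulate_site


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    """The study-condition defaults (three-lake setting, 1900-2013)."""
    return SyntheticConfig()


@pytest.fixture(scope="session")
def default_site(default_config):
    """One fully simulated site under the default study conditions."""
    return simulate_site(default_config, site_index=0)


@pytest.fixture(scope="session")
def century_climate_balance():
    """Monthly water balance D = P - PET for a 100-year synthetic climate."""
    from alderhydro.climate_spei import thornthwaite_pet, water_balance
    from alderhydro.synthetic_data import generate_monthly_climate

    cfg = SyntheticConfig(start_year=1914, end_year=2013, seed=7)
    climate = generate_monthly_climate(cfg)
    pet = thornthwaite_pet(climate, cfg.latitude_deg)
    return water_balance(climate, pet)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
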