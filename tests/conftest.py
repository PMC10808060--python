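import numpy as np
import pytest

import natcapclim as nc


@pytest.fixture(scope="session")
def small_config():
    return nc.WorldConfig(n_lat=12, n_lon=24, n_countries=4, n_biomes=3, seed=7)


@pytest.fixture(scope="session")
def small_world(small_config):
    return nc.make_world(small_config)


@pytest.fixture(scope="session")
def small_accounts(small_world):
    return nc.make_accounts(small_world)


@pytest.fixture(scope="session")
def small_vegs(small_world):
    return nc.make_vegs_table(small_world, n_obs=300, seed=11)


@pytest.fixture(scope="session")
def base_areas(small_world):
    from natcapclim import biome_accounting

    return biome_accounting.aggregate_to_country(
        small_world.cover0, small_world.carbon0, small_world.mask)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
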