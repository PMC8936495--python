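import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lakefi as lf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_config():
    """Reduced landscape: quick to generate and analyse end to end."""
    return lf.SyntheticConfig(
        n_stations_north=8,
        n_stations_south=12,
        year_start=1996,
        year_end=2001,
        n_taxa=30,
        n_common_taxa=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return lf.generate_landscape(small_config)


@pytest.fixture(scope="session")
def default_landscape():
    """One full-size landscape at the default study conditions."""
    return lf.generate_landscape(lf.SyntheticConfig(seed=11))
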