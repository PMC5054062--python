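import numpy as np
import pytest

from aqoi import ErrorStatistics, SyntheticConfig, simulate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact synthetic scene shared by pipeline-level tests."""
    cfg = SyntheticConfig(n_lat=25, n_lon=25, n_stations=60, n_hours=4,
                          seed=42)
    return simulate_scene(cfg)


@pytest.fixture(scope="session")
def pm25_stats():
    """True-parameter error statistics matching the default scene generator
    (sigma_b2 = 25, Lc = 60 km, rural sigma_o2 = 8 at dx = 10 km)."""
    return ErrorStatistics(
        pollutant="PM2.5", sigma_b2=25.0, lc_km=60.0,
        sigma_o2_by_land_use={"rural": 8.0, "suburban": 14.0, "urban": 24.0},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
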