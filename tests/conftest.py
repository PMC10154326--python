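import dataclasses

import pytest

from thermorange import synthetic_data as sd
from thermorange.microclimate import MicroclimateHour


@pytest.fixture(scope="session")
def finch():
    return sd.generate_species("small_finch", seed=1)


@pytest.fixture(scope="session")
def parakeet():
    return sd.generate_species("medium_parakeet", seed=1)


@pytest.fixture(scope="session")
def small_landscape():
    cfg = sd.SyntheticConfig(grid_rows=25, grid_cols=25, seed=11)
    return sd.generate_landscape(cfg)


@pytest.fixture(scope="session")
def controlled_config():
    """Isothermal-day, overcast, flat, noise-free world: the analytic regime."""
    return sd.SyntheticConfig(
        grid_rows=30, grid_cols=30, seed=7,
        diurnal_range_c=0.0, cloud_mean_frac=1.0, cloud_noise_frac=0.0,
        wind_noise_ms=0.0, flat_terrain=True,
        landcover_mix={"forest": 0.0, "shrub_herb": 0.0, "urban": 0.0, "other": 1.0},
    )


@pytest.fixture(scope="session")
def controlled_landscape(controlled_config):
    return sd.generate_landscape(controlled_config)


@pytest.fixture(scope="session")
def controlled_finch(finch):
    """Finch without work export: survival maps reduce to the conductance form."""
    return dataclasses.replace(finch, muscle_efficiency=0.0)


def make_hour(
    air=10.0, wind=2.0, rh=60.0, solar=0.0, sky=None, ground=None, hour=12, daylight=None
) -> MicroclimateHour:
    return MicroclimateHour(
        hour=hour,
        air_temp_c=air,
        wind_ms=wind,
        rh_pct=rh,
        solar_wm2=solar,
        sky_temp_c=air if sky is None else sky,
        ground_temp_c=air if ground is None else ground,
        is_daylight=(solar > 0) if daylight is None else daylight,
        is_active_window=(solar > 0) if daylight is None else daylight,
    )


@pytest.fixture
def hour_factory():
    return make_hour
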