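import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from plantainforage import (
    ManagementEvent,
    SimulationParams,
    WeatherDay,
    compute_drivers,
    synth_weather,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

LATITUDE = -43.6


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(latitude=LATITUDE)


@pytest.fixture(scope="session")
def two_year_weather():
    """Two synthetic Canterbury-like years with drivers attached."""
    days = synth_weather(LATITUDE, 2, seed=11, start_year=2000)
    return compute_drivers(days, LATITUDE)


def constant_weather(n_days, radn=18.0, maxt=22.0, mint=12.0, rain=3.0,
                     start=dt.date(2000, 9, 1)):
    """Benign constant weather: mild, moist, bright."""
    return [
        WeatherDay(date=start + dt.timedelta(days=i), radn=radn, maxt=maxt,
                   mint=mint, rain=rain)
        for i in range(n_days)
    ]


def sow_event(date=dt.date(2000, 9, 1), depth=5.0, density=200.0):
    return ManagementEvent(date=date, kind="sow", sowing_depth_mm=depth,
                           plant_density=density)
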