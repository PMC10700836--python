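import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import acclimate.synthetic_data as sd
from acclimate.weather import interpolate_county_daily

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_single_series(seed=0, **climate_kw):
    """One station and one county at the same point: the county series is
    exactly the station series (IDW snap), handy for deterministic checks."""
    st = pd.DataFrame({"station_id": [0], "x": [500.0], "y": [500.0], "region_id": [0]})
    co = pd.DataFrame({"county_id": [0], "x": [500.0], "y": [500.0], "region_id": [0]})
    wx = sd.simulate_station_weather(st, sd.ClimateParams(**climate_kw), seed=seed)
    return interpolate_county_daily(wx, st, co, variables=("temp",))[0]


FLAT = dict(seasonal_amplitude=0.0, warming_trend=0.0, daily_noise_sd=0.0,
            annual_noise_sd=0.0, station_noise_sd=0.0)


@pytest.fixture(scope="session")
def flat_series():
    """Constant 16 degC every day, 1951-2018."""
    return make_single_series(regional_base_temp=(16.0,), **FLAT)


@pytest.fixture(scope="session")
def trend_series():
    """Pure 0.02 degC/yr warming steps, no seasonality or noise."""
    kw = dict(FLAT, warming_trend=0.02)
    return make_single_series(regional_base_temp=(16.0,), **kw)


@pytest.fixture(scope="session")
def noisy_series():
    """Default climate at a single station/county."""
    return make_single_series(seed=5)


@pytest.fixture(scope="session")
def small_world():
    """6 stations, 8 counties, 2 regions with default climate; returns
    (stations, counties, series_map)."""
    st, co = sd.generate_geography(6, 8, 2, seed=42)
    wx = sd.simulate_station_weather(st, sd.ClimateParams(), seed=7)
    return st, co, interpolate_county_daily(wx, st, co)


@pytest.fixture(scope="session")
def flat_world():
    """3 stations, 4 counties with a constant climate (no trend, no noise)."""
    st, co = sd.generate_geography(3, 4, 1, seed=9)
    wx = sd.simulate_station_weather(
        st, sd.ClimateParams(regional_base_temp=(16.0,), **FLAT), seed=7)
    return st, co, interpolate_county_daily(wx, st, co)


@pytest.fixture(scope="session")
def small_panel(small_world):
    """60 respondents with interviews packed into early August so every
    interview date carries several observations (exact-date fixed effects
    stay identified at this scale)."""
    _, co, _ = small_world
    return sd.simulate_panel(co, n_individuals=60, seed=3,
                             interview_window=((8, 1), (8, 21)))


@pytest.fixture(scope="session")
def study_world():
    """The standard study geography: 10 stations, 30 counties, 4 regions,
    default climate 1951-2018. Session-scoped because interpolation is the
    expensive step shared by the recovery experiments."""
    st, co = sd.generate_geography(10, 30, 4, seed=11)
    wx = sd.simulate_station_weather(st, sd.ClimateParams(), seed=12)
    return st, co, interpolate_county_daily(wx, st, co)
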