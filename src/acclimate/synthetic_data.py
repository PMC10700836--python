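"""Synthetic inputs for the anomaly–well-being pipeline.

Everything the downstream stages consume is generated here with known ground
truth: a planar station/county geography, daily station weather with a
seasonal cycle plus a secular warming trend, a three-wave panel of
non-migrating survey respondents, a 1-5 subjective well-being (SWB) outcome
generated from the linear fixed-effects data-generating process, ensemble
temperature trajectories to 2100 under three emissions archetypes, and an
average-age path for the projection's representative agent.

All generators are deterministic given their ``seed`` argument; every stream
of randomness flows through a single ``numpy.random.Generator`` per call.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError

__all__ = [
    "ClimateParams",
    "DGPParams",
    "generate_geography",
    "simulate_station_weather",
    "simulate_panel",
    "simulate_swb",
    "generate_projection_scenarios",
    "generate_age_trajectory",
]

DAYS_PER_YEAR = 365.25


@dataclass
class ClimateParams:
    """Parameters of the station weather generator.

    The defaults emulate a temperate monsoon record: a mid-July seasonal
    peak, ~0.2 degC/decade secular warming (the rate global temperature has
    risen over recent decades), day-to-day synoptic noise of 2 degC and a
    fixed per-station microclimate offset.
    """

    regional_base_temp: tuple[float, ...] = (14.0, 16.0, 18.0, 20.0)  # degC per region
    seasonal_amplitude: float = 11.0  # degC, half peak-to-trough
    seasonal_peak_day: int = 197  # day of year (mid July)
    warming_trend: float = 0.02  # degC per year
    daily_noise_sd: float = 2.0  # degC
    annual_noise_sd: float = 0.8  # degC, station-by-year anomaly (interannual variability)
    station_noise_sd: float = 0.5  # degC, per-station offset
    start_year: int = 1951
    end_year: int = 2018

    def __post_init__(self):
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if self.daily_noise_sd < 0 or self.station_noise_sd < 0 or self.annual_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")

    def base_for_region(self, region_id: int) -> float:
        return self.regional_base_temp[region_id % len(self.regional_base_temp)]


@dataclass
class DGPParams:
    """Generative twin of the estimated fixed-effects model.

    ``beta_true`` is the marginal SWB effect of a 1 degC anomaly; the default
    -0.023 is the effect size the package's recovery experiments target.
    Individual and date intercepts are drawn once per person / interview
    date; ``cluster_shock_sd`` adds a county-by-date shock so that clustered
    inference has genuine within-cluster error correlation to absorb.
    """

    beta_true: float = -0.023
    control_coeffs: dict[str, float] = field(
        default_factory=lambda: {
            "log_income": 0.016,
            "age": 0.020,
            "married": 0.165,
            "education": 0.009,
            "employed": 0.020,
            "discomfort": -0.092,
        }
    )
    alpha: float = 3.0
    fe_sd_individual: float = 0.5
    fe_sd_date: float = 0.1
    cluster_shock_sd: float = 0.1
    noise_sd: float = 1.0
    discretize: bool = False

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_geography(n_stations: int, n_counties: int, n_regions: int, seed: int):
    """Draw stations and counties uniformly on a bounded plane.

    Coordinates are planar kilometres on a 1000 km x 1000 km domain split
    into ``n_regions`` vertical bands; each unit is assigned the region its
    x-coordinate falls in, so every county has a region and regions with at
    least one station are guaranteed when ``n_stations >= n_regions`` (the
    generator retries station draws until each band holds one).

    Returns ``(stations, counties)`` DataFrames with columns
    ``station_id|county_id, x, y, region_id``.
    """
    if n_stations < 1 or n_counties < 1 or n_regions < 1:
        raise ValueError("n_stations, n_counties and n_regions must all be >= 1")
    rng = _rng(seed)
    width = 1000.0
    band = width / n_regions

    def _draw(n, prefix):
        xy = rng.uniform(0.0, width, size=(n, 2))
        region = np.minimum((xy[:, 0] // band).astype(int), n_regions - 1)
        return pd.DataFrame(
            {
                f"{prefix}_id": np.arange(n),
                "x": xy[:, 0],
                "y": xy[:, 1],
                "region_id": region,
            }
        )

    stations = _draw(n_stations, "station")
    if n_stations >= n_regions:
        # ensure every region holds at least one station: move one spare
        # station into each empty band, deterministically
        present = set(stations["region_id"])
        missing = [r for r in range(n_regions) if r not in present]
        if missing:
            counts = stations["region_id"].value_counts()
            for r in missing:
                donor_region = counts.idxmax()
                idx = stations.index[stations["region_id"] == donor_region][0]
                stations.loc[idx, "x"] = (r + 0.5) * band
                stations.loc[idx, "region_id"] = r
                counts = stations["region_id"].value_counts()
    counties = _draw(n_counties, "county")
    return stations, counties


def _season(day_of_year: np.ndarray, amplitude: float, peak_day: int) -> np.ndarray:
    return amplitude * np.cos(2.0 * np.pi * (day_of_year - peak_day) / DAYS_PER_YEAR)


def simulate_station_weather(stations: pd.DataFrame, params: ClimateParams, seed: int) -> pd.DataFrame:
    """Daily station weather over ``[start_year, end_year]``.

    temp = regional base + seasonal cosine + warming trend x (year - start)
    + per-station offset + station-by-year anomaly + daily noise. The
    station-by-year term carries the interannual variability that real
    records show (one August warmer than the next) and is what gives
    temperature anomalies cross-sectional variation downstream. Auxiliary
    variables (wind, humidity, precipitation, sunlight hours) are mildly
    correlated with temperature; they exist so the estimation stage has
    weather controls, not to be physical. Leap days are present.
    """
    rng = _rng(seed)
    dates = pd.date_range(
        dt.date(params.start_year, 1, 1), dt.date(params.end_year, 12, 31), freq="D"
    )
    doy = dates.day_of_year.to_numpy()
    years = dates.year.to_numpy()
    season = _season(doy, params.seasonal_amplitude, params.seasonal_peak_day)
    trend = params.warming_trend * (years - params.start_year)
    n_days = len(dates)

    frames = []
    year_index = years - params.start_year
    n_years = params.end_year - params.start_year + 1
    for row in stations.itertuples(index=False):
        offset = rng.normal(0.0, params.station_noise_sd)
        noise = rng.normal(0.0, params.daily_noise_sd, size=n_days) if params.daily_noise_sd > 0 else 0.0
        yearly = (
            rng.normal(0.0, params.annual_noise_sd, size=n_years)[year_index]
            if params.annual_noise_sd > 0 else 0.0
        )
        temp = params.base_for_region(int(row.region_id)) + season + trend + offset + yearly + noise
        dev = temp - np.mean(temp)
        wind = np.clip(3.0 + 0.03 * dev + rng.normal(0.0, 0.8, n_days), 0.0, None)
        humidity = np.clip(70.0 - 0.6 * dev + rng.normal(0.0, 6.0, n_days), 5.0, 100.0)
        precip = np.clip(rng.exponential(2.0, n_days) * (1.0 + 0.02 * dev), 0.0, None)
        sun = np.clip(6.5 + 0.08 * dev + rng.normal(0.0, 1.5, n_days), 0.0, 14.0)
        frames.append(
            pd.DataFrame(
                {
                    "station_id": row.station_id,
                    "date": dates,
                    "temp": temp,
                    "wind": wind,
                    "humidity": humidity,
                    "precip": precip,
                    "sun_hours": sun,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_panel(
    counties: pd.DataFrame,
    waves=(2010, 2014, 2018),
    n_individuals: int = 3000,
    birth_year_range=(1955, 1990),
    interview_window=((5, 1), (10, 31)),
    seed: int = 0,
) -> pd.DataFrame:
    """A balanced panel of non-migrating respondents.

    One row per person-wave. Each person keeps a single county for life;
    interview dates are drawn uniformly inside ``interview_window`` (default
    May 1 - Oct 31, the summer/autumn fieldwork season) of each wave year.
    Controls: log household income (drifts across waves), marital status,
    education level (1-8, fixed), employment, a two-week discomfort
    indicator, and a positive survey weight.
    """
    if len(counties) == 0:
        raise ValueError("county catalog is empty")
    waves = list(waves)
    if birth_year_range[1] > min(waves):
        raise ValueError("latest birth year must not exceed the first wave year")
    rng = _rng(seed)
    n = n_individuals
    county_ids = counties["county_id"].to_numpy()
    person_county = rng.choice(county_ids, size=n)
    birth_year = rng.integers(birth_year_range[0], birth_year_range[1] + 1, size=n)
    weight = np.exp(rng.normal(0.0, 0.4, size=n))
    education = rng.integers(1, 9, size=n)
    base_income = rng.normal(9.2, 0.8, size=n)

    (m0, d0), (m1, d1) = interview_window
    rows = []
    for w_idx, wave in enumerate(waves):
        start = dt.date(wave, m0, d0).toordinal()
        end = dt.date(wave, m1, d1).toordinal()
        ords = rng.integers(start, end + 1, size=n)
        dates = [dt.date.fromordinal(int(o)) for o in ords]
        rows.append(
            pd.DataFrame(
                {
                    "person_id": np.arange(n),
                    "county_id": person_county,
                    "birth_year": birth_year,
                    "wave": wave,
                    "interview_date": pd.to_datetime(dates),
                    "age": wave - birth_year,
                    "log_income": base_income + 0.06 * w_idx * 4 + rng.normal(0.0, 0.3, n),
                    "married": (rng.uniform(size=n) < 0.55 + 0.08 * w_idx).astype(int),
                    "education": education,
                    "employed": (rng.uniform(size=n) < 0.7).astype(int),
                    "discomfort": (rng.uniform(size=n) < 0.25).astype(int),
                    "weight": weight,
                }
            )
        )
    panel = pd.concat(rows, ignore_index=True)
    return panel.sort_values(["person_id", "wave"], ignore_index=True)


def simulate_swb(panel: pd.DataFrame, true_anomalies, dgp: DGPParams, seed: int) -> pd.DataFrame:
    """Generate the well-being outcome from the linear fixed-effects DGP.

    y = alpha + beta_true * anomaly + controls . coeffs + gamma_i + theta_date
        + county-by-date shock + eps

    ``true_anomalies`` must align row-for-row with ``panel`` (same length and
    order). Returns a copy of the panel with ``swb_latent`` and, if
    ``dgp.discretize``, an ordinal ``swb`` clipped/rounded to 1-5 (rounding
    compresses the tails, so recovered slopes are attenuated relative to the
    latent outcome); otherwise ``swb`` equals the latent value.
    """
    anomalies = np.asarray(true_anomalies, dtype=float)
    if len(anomalies) != len(panel):
        raise AlignmentError(
            f"anomaly vector has {len(anomalies)} rows but panel has {len(panel)}"
        )
    rng = _rng(seed)
    out = panel.copy()

    y = dgp.alpha + dgp.beta_true * anomalies
    for col, coef in dgp.control_coeffs.items():
        if col in out.columns and coef != 0.0:
            y = y + coef * out[col].to_numpy(dtype=float)

    persons, person_idx = np.unique(out["person_id"].to_numpy(), return_inverse=True)
    gamma = rng.normal(0.0, dgp.fe_sd_individual, size=len(persons))
    dates, date_idx = np.unique(out["interview_date"].to_numpy(), return_inverse=True)
    theta = rng.normal(0.0, dgp.fe_sd_date, size=len(dates))
    cd = pd.factorize(
        out["county_id"].astype(str) + "|" + out["interview_date"].astype(str)
    )[0]
    shock = rng.normal(0.0, dgp.cluster_shock_sd, size=cd.max() + 1)
    eps = rng.normal(0.0, dgp.noise_sd, size=len(out))

    y = y + gamma[person_idx] + theta[date_idx] + shock[cd] + eps
    out["swb_latent"] = y
    out["swb"] = np.clip(np.round(y), 1, 5) if dgp.discretize else y
    return out


SCENARIOS = ("netzero", "middle", "high")


def generate_projection_scenarios(
    regions,
    scenarios=SCENARIOS,
    n_models: int = 20,
    years=range(2015, 2101),
    seed: int = 0,
    history_start: int = 1950,
    base_temps: tuple[float, ...] = (14.0, 16.0, 18.0, 20.0),
    history_trend: float = 0.02,
    model_offset_sd: float = 0.3,
    model_slope_sd: float = 0.10,
) -> pd.DataFrame:
    """Annual regional mean-temperature paths per scenario and climate model.

    Each (scenario, model, region) series spans ``history_start`` through the
    last projection year: a shared warming history to 2014, then
    scenario-specific annual increments -- "netzero" increments shrink
    linearly to zero by 2045 and stay there (a plateau, emulating a
    net-zero/SSP1-2.6 archetype), "middle" warms at a steady 0.03 degC/yr,
    "high" accelerates from 0.03 toward ~0.08 degC/yr. Inter-model spread
    enters through a per-model level offset and increment multiplier; the
    paths themselves are smooth.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    unknown = set(scenarios) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenario labels: {sorted(unknown)}; known: {SCENARIOS}")
    years = list(years)
    proj_start, proj_end = years[0], years[-1]
    rng = _rng(seed)
    offsets = rng.normal(0.0, model_offset_sd, size=n_models)
    slopes = 1.0 + rng.normal(0.0, model_slope_sd, size=n_models)

    all_years = np.arange(history_start, proj_end + 1)
    hist_mask = all_years < proj_start
    records = []
    for m in range(n_models):
        # increments per scenario, degC/yr, applied from proj_start onward
        yrs_p = all_years[~hist_mask]
        t_rel = yrs_p - proj_start
        inc = {
            "netzero": np.clip(0.025 * (1.0 - t_rel / 30.0), 0.0, None),
            "middle": np.full_like(t_rel, 0.03, dtype=float),
            "high": 0.03 + 0.0006 * t_rel,
        }
        for scen in scenarios:
            increments = np.concatenate(
                [np.full(hist_mask.sum(), history_trend), inc[scen] * slopes[m]]
            )
            # temperature path: cumulative increments anchored at the base
            path = np.cumsum(increments) - increments[0]
            for r_idx, region in enumerate(regions):
                base = base_temps[int(region) % len(base_temps)]
                records.append(
                    pd.DataFrame(
                        {
                            "scenario": scen,
                            "model": m,
                            "region": region,
                            "year": all_years,
                            "temp": base + offsets[m] + path,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


def generate_age_trajectory(years=range(2020, 2101), start_age: float = 38.0, drift: float = 0.15) -> pd.DataFrame:
    """Average-age path for the projection's representative citizen.

    Linear: age(year) = start_age + drift * (year - first year). ``drift=0``
    gives the constant-age path used by the analytic closed-form checks.
    """
    if start_age <= 0:
        raise ValueError("start_age must be > 0")
    years = np.asarray(list(years))
    ages = start_age + drift * (years - years[0])
    if (ages <= 0).any():
        raise ValueError("age trajectory must stay strictly positive")
    return pd.DataFrame({"year": years, "avg_age": ages})
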