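"""Station-to-county weather and exposure-window statistics.

Station records are turned into county-level daily series with
inverse-distance weighting (IDW); county series expose 30-day window means,
3 degC temperature-bin day counts, and per-year transpositions of a calendar
window back through the historical record -- the raw material for the
reference-temperature schemes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, ExposureMissingError, MissingDataError

__all__ = [
    "BinSpec",
    "CountyDailySeries",
    "idw_to_county",
    "idw_weights",
    "interpolate_county_daily",
    "window_stats",
    "bin_day_counts",
    "calendar_window_history",
]

SNAP_DISTANCE_KM = 0.001  # a county point within 1 m of a station takes its value


@dataclass(frozen=True)
class BinSpec:
    """Temperature-bin layout for day-count exposures.

    Half-open bins [a, a+width) anchored at ``lower_consolidation``; all
    days below it pool into one sub-freezing bin and days at/above
    ``upper_consolidation`` pool into one hot bin. ``omitted_bin`` marks the
    comfortable reference interval excluded from estimation (coefficients
    are effects of moving a day out of it).
    """

    bin_width: float = 3.0
    lower_consolidation: float = 0.0
    upper_consolidation: float = 30.0
    omitted_bin: tuple[float, float] = (18.0, 21.0)

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        lo, hi = self.omitted_bin
        rel = (lo - self.lower_consolidation) / self.bin_width
        if abs(rel - round(rel)) > 1e-9 or abs(hi - lo - self.bin_width) > 1e-9:
            raise ValueError("omitted_bin must be one bin on the grid")

    def edges(self) -> np.ndarray:
        return np.arange(self.lower_consolidation, self.upper_consolidation + 1e-9, self.bin_width)

    def labels(self) -> list[str]:
        e = self.edges()
        labels = [f"lt_{e[0]:g}"]
        labels += [f"{a:g}_{b:g}" for a, b in zip(e[:-1], e[1:])]
        labels.append(f"ge_{e[-1]:g}")
        return labels

    def omitted_label(self) -> str:
        lo, hi = self.omitted_bin
        return f"{lo:g}_{hi:g}"


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


def _safe_date(year: int, month: int, day: int) -> dt.date:
    """Feb 29 collapses to Feb 28 in non-leap years."""
    try:
        return dt.date(year, month, day)
    except ValueError:
        if month == 2 and day == 29:
            return dt.date(year, 2, 28)
        raise


class CountyDailySeries:
    """Contiguous daily series for one county, with O(1) window sums.

    Built from a date-indexed frame; missing calendar days inside the span
    are kept as NaN and recorded in ``gap_dates`` -- windows touching a gap
    raise rather than silently impute. Prefix sums over values and over
    NaN indicators make any window mean a constant-time lookup, and per-year
    calendar-window means are cached, which is what keeps lifetime-reference
    construction cheap at panel scale.
    """

    def __init__(self, county_id, dates, values: dict[str, np.ndarray]):
        dates = pd.DatetimeIndex(dates)
        if dates.has_duplicates:
            raise ValueError(f"county {county_id}: duplicate dates in series")
        order = np.argsort(dates.values)
        dates = dates[order]
        self.county_id = county_id
        self.start = dates[0].date()
        self.end = dates[-1].date()
        self._start_ord = self.start.toordinal()
        n = self.end.toordinal() - self._start_ord + 1
        idx = np.array([d.toordinal() for d in dates.date]) - self._start_ord
        self._values: dict[str, np.ndarray] = {}
        self._csum: dict[str, np.ndarray] = {}
        for var, arr in values.items():
            full = np.full(n, np.nan)
            full[idx] = np.asarray(arr, dtype=float)[order]
            self._values[var] = full
            filled = np.where(np.isnan(full), 0.0, full)
            self._csum[var] = np.concatenate([[0.0], np.cumsum(filled)])
        nan_any = np.isnan(self._values[next(iter(values))])
        self._nan_csum = np.concatenate([[0], np.cumsum(nan_any.astype(np.int64))])
        self.gap_dates = [
            dt.date.fromordinal(self._start_ord + int(i)) for i in np.nonzero(nan_any)[0]
        ]
        self._hist_cache: dict = {}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, county_id=None, date_col="date",
                   variables=("temp",)) -> "CountyDailySeries":
        if county_id is None:
            county_id = df["county_id"].iloc[0]
        return cls(county_id, pd.to_datetime(df[date_col]),
                   {v: df[v].to_numpy() for v in variables})

    @property
    def variables(self):
        return list(self._values)

    def _index(self, date: dt.date) -> int:
        return date.toordinal() - self._start_ord

    def value_on(self, date, variable="temp") -> float:
        i = self._index(_as_date(date))
        if not 0 <= i < len(self._values[variable]):
            raise ExposureMissingError(
                f"county {self.county_id}: {date} outside record "
                f"[{self.start}..{self.end}]")
        return float(self._values[variable][i])

    def window_values(self, end_date, window_days: int, variable="temp") -> np.ndarray:
        end = _as_date(end_date)
        i1 = self._index(end)
        i0 = i1 - window_days + 1
        self._check_window(i0, i1, end)
        return self._values[variable][i0:i1 + 1]

    def _check_window(self, i0: int, i1: int, end) -> None:
        n = len(self._nan_csum) - 1
        if i0 < 0 or i1 >= n:
            raise ExposureMissingError(
                f"county {self.county_id}: window ending {end} not covered by "
                f"record [{self.start}..{self.end}]")
        if self._nan_csum[i1 + 1] - self._nan_csum[i0] > 0:
            raise ExposureMissingError(
                f"county {self.county_id}: window ending {end} contains gap days")

    def window_mean(self, end_date, window_days: int, variable="temp") -> float:
        end = _as_date(end_date)
        i1 = self._index(end)
        i0 = i1 - window_days + 1
        self._check_window(i0, i1, end)
        c = self._csum[variable]
        return float((c[i1 + 1] - c[i0]) / window_days)

    # -- per-year calendar-window machinery -------------------------------

    def _window_bounds(self, end_date, window_days):
        end = _as_date(end_date)
        start = end - dt.timedelta(days=window_days - 1)
        return start, end

    def year_window_table(self, end_date, window_days: int, variable="temp"):
        """Cached (first_year, means, prefix) of the transposed window.

        ``means[k]`` is the mean over the same month-day window placed in
        year ``first_year + k``, for every year the record fully covers;
        ``prefix`` is the running sum of means so any consecutive-year
        average is O(1).
        """
        start, end = self._window_bounds(end_date, window_days)
        key = (start.month, start.day, end.month, end.day,
               end.year - start.year, variable)
        hit = self._hist_cache.get(key)
        if hit is not None:
            return hit
        span = end.year - start.year
        first = self.start.year + span
        # first year whose transposed window starts on/after record start
        while _safe_date(first - span, start.month, start.day) < self.start:
            first += 1
        last = self.end.year
        while last >= first and _safe_date(last, end.month, end.day) > self.end:
            last -= 1
        if last < first:
            raise CoverageError(
                f"county {self.county_id}: record [{self.start}..{self.end}] "
                f"covers no full {window_days}-day window ending {end.month:02d}-{end.day:02d}")
        years = np.arange(first, last + 1)
        means = np.empty(len(years))
        c = self._csum[variable]
        for k, y in enumerate(years):
            s = _safe_date(y - span, start.month, start.day)
            e = _safe_date(y, end.month, end.day)
            i0, i1 = self._index(s), self._index(e)
            self._check_window(i0, i1, e)
            means[k] = (c[i1 + 1] - c[i0]) / (i1 - i0 + 1)
        prefix = np.concatenate([[0.0], np.cumsum(means)])
        entry = (first, means, prefix)
        self._hist_cache[key] = entry
        return entry

    def year_range_mean(self, end_date, window_days: int, from_year: int, to_year: int,
                        variable="temp") -> float:
        """Mean of per-year transposed-window means over [from_year, to_year]."""
        first, means, prefix = self.year_window_table(end_date, window_days, variable)
        last = first + len(means) - 1
        if from_year < first or to_year > last:
            missing = from_year if from_year < first else to_year
            raise CoverageError(
                f"county {self.county_id}: year {missing} not covered "
                f"(windows available {first}..{last})")
        if from_year > to_year:
            raise ValueError("from_year must be <= to_year")
        a, b = from_year - first, to_year - first
        return float((prefix[b + 1] - prefix[a]) / (b - a + 1))


def idw_weights(stations: pd.DataFrame, point_xy, power: float = 2.0) -> np.ndarray:
    """Normalized inverse-distance weights of every station for one point.

    Weights are proportional to distance^(-power); a station within
    ``SNAP_DISTANCE_KM`` of the point gets all the mass (exact snap).
    """
    sx = stations["x"].to_numpy(dtype=float)
    sy = stations["y"].to_numpy(dtype=float)
    d = np.hypot(sx - point_xy[0], sy - point_xy[1])
    w = np.zeros_like(d)
    snap = d < SNAP_DISTANCE_KM
    if snap.any():
        w[np.argmin(d)] = 1.0
        return w
    w = d ** (-power)
    return w / w.sum()


def idw_to_county(station_values, stations: pd.DataFrame, county, power: float = 2.0) -> float:
    """IDW-interpolate one value at a county point.

    ``station_values`` aligns with ``stations`` rows; NaNs are excluded and
    the remaining weights renormalized. Raises ``MissingDataError`` when no
    station reports a value.
    """
    vals = np.asarray(station_values, dtype=float)
    ok = ~np.isnan(vals)
    if not ok.any():
        raise MissingDataError(f"no station data for county {county!r}")
    try:
        xy = (float(county["x"]), float(county["y"]))
    except (TypeError, IndexError, KeyError):
        xy = (float(county[0]), float(county[1]))
    w = idw_weights(stations.iloc[np.flatnonzero(ok)], xy, power=power)
    return float(np.dot(w, vals[ok]))


def interpolate_county_daily(
    weather: pd.DataFrame,
    stations: pd.DataFrame,
    counties: pd.DataFrame,
    power: float = 2.0,
    variables=("temp", "wind", "humidity", "precip", "sun_hours"),
) -> dict:
    """Build a ``CountyDailySeries`` per county from station records.

    Vectorized: one (counties x stations) weight matrix, then a matrix
    product per variable over the (days x stations) pivot. Days where a
    station is missing are renormalized over the reporting stations; a day
    with no reporting station at all becomes a gap (NaN) in every county.
    """
    variables = [v for v in variables if v in weather.columns]
    stations = stations.sort_values("station_id").reset_index(drop=True)
    W = np.vstack([
        idw_weights(stations, (c.x, c.y), power=power)
        for c in counties.itertuples(index=False)
    ])  # (n_counties, n_stations)
    pivots = {
        v: weather.pivot_table(index="date", columns="station_id", values=v, aggfunc="first")
        .reindex(columns=stations["station_id"])
        for v in variables
    }
    dates = pivots[variables[0]].index
    out = {}
    series_values: dict[str, np.ndarray] = {}
    for v in variables:
        M = pivots[v].to_numpy()
        mask = ~np.isnan(M)
        M0 = np.where(mask, M, 0.0)
        num = M0 @ W.T          # (days, counties)
        den = mask.astype(float) @ W.T
        with np.errstate(invalid="ignore", divide="ignore"):
            series_values[v] = np.where(den > 0, num / den, np.nan)
    for j, c in enumerate(counties.itertuples(index=False)):
        out[c.county_id] = CountyDailySeries(
            c.county_id, dates, {v: series_values[v][:, j] for v in variables}
        )
    return out


def window_stats(series: CountyDailySeries, end_date, window_days: int = 30,
                 variable: str = "temp") -> float:
    """Arithmetic mean over the ``window_days`` days ending on ``end_date``."""
    return series.window_mean(end_date, window_days, variable)


def bin_day_counts(series: CountyDailySeries, end_date, window_days: int = 30,
                   spec: BinSpec = BinSpec()) -> pd.Series:
    """Days of the exposure window falling in each temperature bin.

    Returns counts indexed by bin label (sub-freezing pool, the 3 degC
    ladder, the hot pool); the omitted bin stays in the output -- exclusion
    is the estimator's job. Counts always sum to ``window_days``.
    """
    vals = series.window_values(end_date, window_days, "temp")
    edges = spec.edges()
    idx = np.digitize(vals, edges)  # 0 => below lower pool, len(edges) => hot pool
    counts = np.bincount(idx, minlength=len(edges) + 1)
    return pd.Series(counts, index=spec.labels(), name="days")


def build_exposures(
    panel: pd.DataFrame,
    series_map: dict,
    window_days: int = 30,
    variables=("wind", "humidity", "precip", "sun_hours"),
    bin_spec: BinSpec | None = None,
) -> pd.DataFrame:
    """Person-wave exposure covariates: auxiliary-weather window means and,
    when ``bin_spec`` is given, temperature-bin day counts (``bin_<label>``
    columns). Row order follows ``panel``."""
    county = panel["county_id"].to_numpy()
    dates = [d.date() for d in pd.to_datetime(panel["interview_date"])]
    cols: dict[str, np.ndarray] = {
        f"{v}_mean": np.empty(len(panel)) for v in variables
    }
    bins = None
    if bin_spec is not None:
        labels = bin_spec.labels()
        bins = np.zeros((len(panel), len(labels)), dtype=int)
    for i in range(len(panel)):
        s = series_map[county[i]]
        for v in variables:
            cols[f"{v}_mean"][i] = s.window_mean(dates[i], window_days, v)
        if bins is not None:
            bins[i] = bin_day_counts(s, dates[i], window_days, bin_spec).to_numpy()
    out = pd.DataFrame(cols, index=panel.index)
    if bins is not None:
        for j, lab in enumerate(labels):
            out[f"bin_{lab}"] = bins[:, j]
    return out


def calendar_window_history(series: CountyDailySeries, end_date, window_days: int,
                            from_year: int, to_year: int, variable="temp") -> pd.Series:
    """Per-year means of the same calendar window transposed to each year.

    The window keeps its month-day boundaries; Feb 29 inside a transposed
    window simply does not exist in non-leap years, so those means use the
    days actually present.
    """
    if from_year > to_year:
        raise ValueError("from_year must be <= to_year")
    first, means, _ = series.year_window_table(end_date, window_days, variable)
    last = first + len(means) - 1
    if from_year < first or to_year > last:
        missing = from_year if from_year < first else to_year
        raise CoverageError(
            f"county {series.county_id}: year {missing} not covered "
            f"(windows available {first}..{last})")
    years = np.arange(from_year, to_year + 1)
    return pd.Series(means[from_year - first:to_year - first + 1], index=years, name=variable)
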