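"""Reference temperatures and person-specific temperature anomalies.

An anomaly is the current exposure-window mean temperature minus a
historical reference temperature for the same calendar window. The schemes:

``lifetime``
    The individualized reference: the same month-day window averaged over
    every year from the respondent's birth year through the year
    immediately preceding the interview. A 25-year-old interviewed in late
    August 2014 is referenced against Augusts 1989-2013.
``fixed_period(a, b)``
    The window averaged over a fixed span of calendar years (e.g.
    1980-2000), identical for everyone in a county interviewed on the same
    date. Spans reaching into the interview year are truncated to the year
    before it, with a warning.
``preceding_years(n)``
    The window averaged over the n years immediately before the interview
    year; coincides with ``lifetime`` exactly when n equals the
    respondent's age.
``cumulative_age(max_age)``
    Years from birth up to at most ``max_age`` years of life (and never
    past the year before the interview); saturates to ``lifetime`` once
    ``max_age`` reaches the respondent's age.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError
from .weather import CountyDailySeries, _as_date, _safe_date

__all__ = [
    "ReferenceSpec",
    "lifetime_reference",
    "fixed_period_reference",
    "preceding_years_reference",
    "cumulative_age_reference",
    "reference_year_span",
    "split_sign",
    "day_count_anomaly",
    "years_missed_rate",
    "build_anomaly_set",
]


@dataclass(frozen=True)
class ReferenceSpec:
    """Which historical reference scheme to use, and the window length."""

    scheme: str = "lifetime"  # lifetime | fixed_period | preceding_years | cumulative_age
    fixed_period: tuple[int, int] = (1980, 2000)
    preceding_years: int = 25
    cumulative_max_age: int = 40
    window_days: int = 30

    def __post_init__(self):
        if self.scheme not in {"lifetime", "fixed_period", "preceding_years", "cumulative_age"}:
            raise ValueError(f"unknown reference scheme {self.scheme!r}")
        a, b = self.fixed_period
        if a > b:
            raise ValueError("fixed_period requires a <= b")
        if self.preceding_years < 1 or self.cumulative_max_age < 1:
            raise ValueError("preceding_years and cumulative_max_age must be >= 1")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")

    def label(self) -> str:
        if self.scheme == "fixed_period":
            return f"fixed_{self.fixed_period[0]}_{self.fixed_period[1]}"
        if self.scheme == "preceding_years":
            return f"preceding_{self.preceding_years}"
        if self.scheme == "cumulative_age":
            return f"cumulative_age_{self.cumulative_max_age}"
        return "lifetime"


def reference_year_span(spec: ReferenceSpec, birth_year: int, interview_year: int) -> tuple[int, int]:
    """Inclusive [first, last] calendar years a scheme averages over.

    Every scheme stops at the year immediately preceding the interview.
    """
    last_allowed = interview_year - 1
    if spec.scheme == "lifetime":
        first, last = birth_year, last_allowed
    elif spec.scheme == "fixed_period":
        a, b = spec.fixed_period
        first = a
        last = min(b, last_allowed)
        if b > last_allowed:
            warnings.warn(
                f"fixed_period ({a},{b}) truncated at {last_allowed} "
                f"(year before the {interview_year} interview)", stacklevel=2)
    elif spec.scheme == "preceding_years":
        first, last = interview_year - spec.preceding_years, last_allowed
    elif spec.scheme == "cumulative_age":
        first = birth_year
        last = min(birth_year + spec.cumulative_max_age - 1, last_allowed)
    if first > last:
        raise ValueError(
            f"empty reference span for scheme {spec.scheme} "
            f"(birth {birth_year}, interview {interview_year})")
    return first, last


def _ref_mean(series: CountyDailySeries, interview_date, spec: ReferenceSpec,
              birth_year: int | None) -> tuple[float, int]:
    iv = _as_date(interview_date)
    first, last = reference_year_span(spec, birth_year if birth_year is not None else 0, iv.year)
    return (
        series.year_range_mean(iv, spec.window_days, first, last),
        last - first + 1,
    )


def lifetime_reference(series: CountyDailySeries, birth_year: int, interview_date,
                       window_days: int = 30) -> float:
    """Individualized reference: window means averaged birth..interview-1."""
    iv = _as_date(interview_date)
    if birth_year >= iv.year:
        raise ValueError("birth_year must precede the interview year")
    spec = ReferenceSpec("lifetime", window_days=window_days)
    return _ref_mean(series, iv, spec, birth_year)[0]


def fixed_period_reference(series: CountyDailySeries, interview_date, a: int, b: int,
                           window_days: int = 30) -> float:
    spec = ReferenceSpec("fixed_period", fixed_period=(a, b), window_days=window_days)
    return _ref_mean(series, interview_date, spec, None)[0]


def preceding_years_reference(series: CountyDailySeries, interview_date, n: int,
                              window_days: int = 30) -> float:
    spec = ReferenceSpec("preceding_years", preceding_years=n, window_days=window_days)
    return _ref_mean(series, interview_date, spec, None)[0]


def cumulative_age_reference(series: CountyDailySeries, birth_year: int, interview_date,
                             max_age: int, window_days: int = 30) -> float:
    spec = ReferenceSpec("cumulative_age", cumulative_max_age=max_age, window_days=window_days)
    return _ref_mean(series, interview_date, spec, birth_year)[0]


def split_sign(anomaly):
    """Decompose an anomaly into its positive and negative parts.

    positive_part = max(a, 0) ("hotter-than-expected"), negative_part =
    min(a, 0) ("colder-than-expected"); the parts sum back to the anomaly.
    Works elementwise on arrays.
    """
    a = np.asarray(anomaly, dtype=float)
    pos, neg = np.maximum(a, 0.0), np.minimum(a, 0.0)
    if np.isscalar(anomaly) or a.ndim == 0:
        return float(pos), float(neg)
    return pos, neg


def day_count_anomaly(series: CountyDailySeries, interview_date, window_days: int,
                      history_from: int, history_to: int) -> int:
    """Days in the window whose temperature exceeds that calendar day's
    historical average over [history_from, history_to]."""
    if history_from > history_to:
        raise ValueError("history_from must be <= history_to")
    iv = _as_date(interview_date)
    count = 0
    for k in range(window_days):
        day = iv - dt.timedelta(days=window_days - 1 - k)
        temps = []
        for y in range(history_from, history_to + 1):
            if day.month == 2 and day.day == 29:
                d = _safe_date(y, 2, 29)
                if d.day != 29:  # skip non-leap years entirely
                    continue
            else:
                d = dt.date(y, day.month, day.day)
            temps.append(series.value_on(d))
        if not temps:
            raise CoverageError(f"no historical days for {day.month:02d}-{day.day:02d}")
        if series.value_on(day) > float(np.mean(temps)):
            count += 1
    return count


def years_missed_rate(age: int, n: int) -> float:
    """Mismatch between an n-year reference window and an age-year lifetime.

    |age - n| / max(age, n): the share of lifetime years missed when
    n < age, or of reference years that over-reach the lifetime when
    n > age. 0 iff the window length matches the age exactly.
    """
    if age < 1 or n < 1:
        raise ValueError("age and n must both be >= 1")
    return abs(age - n) / max(age, n)


def build_anomaly_set(
    panel: pd.DataFrame,
    series_map: dict,
    spec: ReferenceSpec = ReferenceSpec(),
    include_day_count: bool = False,
    day_count_history: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-observation anomaly table (one row per panel row, same order).

    Columns: current_mean, reference_mean, anomaly, positive_part,
    negative_part, reference_years_used (+ day_count_above on request,
    against ``day_count_history`` or the scheme's own span). The heavy
    lifting is the per-year window tables cached on each county series.
    """
    w = spec.window_days
    n = len(panel)
    current = np.empty(n)
    reference = np.empty(n)
    years_used = np.empty(n, dtype=int)
    day_counts = np.full(n, -1, dtype=int)

    county = panel["county_id"].to_numpy()
    birth = panel["birth_year"].to_numpy()
    dates = [
        d.date() if hasattr(d, "date") else d
        for d in pd.to_datetime(panel["interview_date"])
    ]
    for i in range(n):
        series = series_map[county[i]]
        iv = dates[i]
        current[i] = series.window_mean(iv, w)
        first, last = reference_year_span(spec, int(birth[i]), iv.year)
        reference[i] = series.year_range_mean(iv, w, first, last)
        years_used[i] = last - first + 1
        if include_day_count:
            hist = day_count_history or (first, last)
            day_counts[i] = day_count_anomaly(series, iv, w, hist[0], hist[1])

    anomaly = current - reference
    pos, neg = split_sign(anomaly)
    out = pd.DataFrame(
        {
            "person_id": panel["person_id"].to_numpy(),
            "wave": panel["wave"].to_numpy(),
            "scheme": spec.label(),
            "current_mean": current,
            "reference_mean": reference,
            "anomaly": anomaly,
            "positive_part": pos,
            "negative_part": neg,
            "reference_years_used": years_used,
        },
        index=panel.index,
    )
    if include_day_count:
        out["day_count_above"] = day_counts
    return out
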