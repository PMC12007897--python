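"""Monitor completeness QC and annual exposure metrics.

Raw regulatory monitoring data arrive hourly for the gaseous pollutants
(NO2, SO2, CO, O3) and daily for particulate matter (PM2.5, PM10).  This
module reduces one site-pollutant-year series to a single annual observation,
applying the completeness criteria used for national land-use-regression
modelling:

* a day is valid when it has at least 18 hourly measurements (hourly series);
  a reported daily PM value counts as a valid day by presence;
* a site-year is included when it has at least 244 valid days (everyday
  schedule), 61 (1-in-3 sampling) or 41 (1-in-6 sampling), i.e. at least 75%
  of intended measurements;
* no stretch of more than 45 consecutive days without any measurement;
* for O3 the annual metric is instead the May-September mean of the daily
  highest 8-hour average, included when at least 75% of the season's days are
  valid.

Annual averages are square-root transformed downstream so the kriging model's
normality assumption is reasonable; the forward/backward transform pair lives
here because QC emits observations on both scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

GAS_POLLUTANTS = frozenset({"CO", "NO2", "SO2", "O3"})
PM_POLLUTANTS = frozenset({"PM25", "PM10"})
POLLUTANTS = GAS_POLLUTANTS | PM_POLLUTANTS

#: minimum hourly measurements for a valid day
MIN_VALID_HOURS = 18
#: valid-day completeness thresholds per reporting schedule
VALID_DAY_THRESHOLDS = {"everyday": 244, "one_in_three": 61, "one_in_six": 41}
#: longest tolerated run of days with no measurement at all
MAX_GAP_DAYS = 45
#: O3 season (inclusive): May 1 - Sep 30, 153 days in any year
O3_SEASON = ((5, 1), (9, 30))
O3_SEASON_DAYS = 153
O3_MIN_VALID_FRACTION = 0.75
#: minimum present hours for an 8-h rolling window to contribute (EPA convention)
MIN_WINDOW_HOURS = 6

Schedule = Literal["everyday", "one_in_three", "one_in_six"]


@dataclass(frozen=True)
class MonitorSeries:
    """One site-pollutant-year time series.

    ``records`` is a float Series indexed by timestamps (hourly, at hour
    start) for gases or by dates (daily) for PM; missing measurements are
    simply absent from the index.
    """

    site_id: str
    lon: float
    lat: float
    pollutant: str
    cadence: Literal["hourly", "daily"]
    year: int
    records: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.pollutant not in POLLUTANTS:
            raise ValueError(f"unknown pollutant {self.pollutant!r}")
        expected = "hourly" if self.pollutant in GAS_POLLUTANTS else "daily"
        if self.cadence != expected:
            raise ValueError(
                f"{self.pollutant} series must be {expected}, got {self.cadence}"
            )
        idx = self.records.index
        if len(idx) and not idx.is_monotonic_increasing:
            raise ValueError("record timestamps must be increasing")
        if not np.all(np.isfinite(self.records.to_numpy(dtype=float))):
            raise ValueError("record values must be finite")


@dataclass(frozen=True)
class AnnualObservation:
    """QC-passing annual metric at one site, on native and sqrt scales."""

    site_id: str
    lon: float
    lat: float
    pollutant: str
    year: int
    value_native: float
    value_sqrt: float
    n_valid_days: int
    schedule: Schedule


@dataclass(frozen=True)
class Rejection:
    """Typed QC failure; ``rule`` names the criterion that failed."""

    site_id: str
    pollutant: str
    year: int
    rule: Literal["too_few_records", "completeness", "gap"]
    detail: str


def sqrt_transform(value_native: float | np.ndarray) -> float | np.ndarray:
    """Forward square-root transform; rejects negative concentrations."""
    v = np.asarray(value_native, dtype=float)
    if np.any(v < 0):
        raise ValueError("concentrations must be non-negative")
    out = np.sqrt(v)
    return float(out) if np.isscalar(value_native) else out


def back_transform(value_sqrt: float | np.ndarray) -> float | np.ndarray:
    """Back-transform from sqrt scale: clamp negatives to zero, then square."""
    v = np.asarray(value_sqrt, dtype=float)
    out = np.square(np.maximum(v, 0.0))
    return float(out) if np.isscalar(value_sqrt) else out


def daily_validity(hourly_values: np.ndarray | pd.Series) -> tuple[bool, float]:
    """Validity flag and daily average for one calendar day of hourly data.

    ``hourly_values`` holds at most 24 entries; missing hours may be absent
    or NaN.  Valid iff at least ``MIN_VALID_HOURS`` non-missing hours; the
    average is computed over present hours only and is NaN for invalid days.
    """
    v = np.asarray(hourly_values, dtype=float)
    if v.size > 24:
        raise ValueError("a calendar day has at most 24 hourly records")
    present = v[np.isfinite(v)]
    if present.size >= MIN_VALID_HOURS:
        return True, float(present.mean())
    return False, float("nan")


def daily_max_8h(hour_of_day: np.ndarray, values: np.ndarray) -> float:
    """Daily maximum 8-hour rolling mean (window start hours 0-16).

    A window contributes when at least ``MIN_WINDOW_HOURS`` of its 8 hours
    are present; the mean is over present hours.  NaN when no window
    qualifies.
    """
    slots = np.full(24, np.nan)
    slots[np.asarray(hour_of_day, dtype=int)] = np.asarray(values, dtype=float)
    best = float("nan")
    for start in range(17):
        window = slots[start : start + 8]
        present = window[np.isfinite(window)]
        if present.size >= MIN_WINDOW_HOURS:
            m = float(present.mean())
            if not np.isfinite(best) or m > best:
                best = m
    return best


def classify_schedule(series: MonitorSeries) -> Schedule:
    """Classify the reporting schedule by the modal gap between reported days.

    Modal gap 1 -> everyday, 3 -> 1-in-3, 6 -> 1-in-6; other modal gaps map
    to the nearest of those three (ties towards the denser schedule).
    """
    days = reported_days(series)
    if len(days) < 2:
        raise ValueError("need at least 2 reported days to classify a schedule")
    gaps = np.diff(days.astype("datetime64[D]")).astype(int)
    values, counts = np.unique(gaps, return_counts=True)
    modal = int(values[np.argmax(counts)])
    candidates = np.array([1, 3, 6])
    labels = ("everyday", "one_in_three", "one_in_six")
    return labels[int(np.argmin(np.abs(candidates - modal)))]


def reported_days(series: MonitorSeries) -> np.ndarray:
    """Sorted unique calendar days carrying at least one measurement."""
    idx = pd.DatetimeIndex(series.records.index)
    return np.unique(idx.normalize().values.astype("datetime64[D]"))


def longest_gap_days(series: MonitorSeries) -> int:
    """Longest run of consecutive days without any measurement.

    Measured on reported (not valid) days, including the stretches between
    January 1 / December 31 and the first / last reported day.
    """
    days = reported_days(series)
    if days.size == 0:
        return 366
    start = np.datetime64(f"{series.year}-01-01", "D")
    end = np.datetime64(f"{series.year}-12-31", "D")
    bounded = np.concatenate(([start - 1], days, [end + 1]))
    return int((np.diff(bounded).astype(int) - 1).max())


def _daily_summaries(series: MonitorSeries) -> pd.DataFrame:
    """Per-day validity and daily average (mean of present hours)."""
    if series.cadence == "daily":
        idx = pd.DatetimeIndex(series.records.index).normalize()
        return pd.DataFrame(
            {"valid": True, "value": series.records.to_numpy(dtype=float)}, index=idx
        )
    idx = pd.DatetimeIndex(series.records.index)
    rows = {}
    for day, group in series.records.groupby(idx.normalize()):
        rows[day] = daily_validity(group.to_numpy(dtype=float))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["valid", "value"])
    return df.sort_index()


def annual_average(series: MonitorSeries) -> AnnualObservation | Rejection:
    """Annual mean of valid-day values, gated by completeness and gap rules.

    Not defined for O3 (use :func:`o3_season_metric`).  The completeness
    threshold depends on the schedule inferred from the data itself, so a
    nominally-everyday monitor that reported sparsely is held to the everyday
    threshold only if its modal gap still looks everyday.
    """
    if series.pollutant == "O3":
        raise ValueError("use o3_season_metric for O3 series")
    if len(reported_days(series)) < 2:
        return Rejection(series.site_id, series.pollutant, series.year,
                         "too_few_records", "fewer than 2 reported days")
    schedule = classify_schedule(series)
    daily = _daily_summaries(series)
    n_valid = int(daily["valid"].sum())
    threshold = VALID_DAY_THRESHOLDS[schedule]
    if n_valid < threshold:
        return Rejection(
            series.site_id, series.pollutant, series.year, "completeness",
            f"{n_valid} valid days < {threshold} required for {schedule}",
        )
    gap = longest_gap_days(series)
    if gap > MAX_GAP_DAYS:
        return Rejection(
            series.site_id, series.pollutant, series.year, "gap",
            f"longest measurement-free run {gap} days > {MAX_GAP_DAYS}",
        )
    value = float(daily.loc[daily["valid"], "value"].mean())
    return AnnualObservation(
        site_id=series.site_id, lon=series.lon, lat=series.lat,
        pollutant=series.pollutant, year=series.year,
        value_native=value, value_sqrt=sqrt_transform(value),
        n_valid_days=n_valid, schedule=schedule,
    )


def o3_season_days(year: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{year}-{O3_SEASON[0][0]:02d}-{O3_SEASON[0][1]:02d}",
                         f"{year}-{O3_SEASON[1][0]:02d}-{O3_SEASON[1][1]:02d}", freq="D")


def o3_season_metric(series: MonitorSeries) -> AnnualObservation | Rejection:
    """May-September mean of the daily highest 8-h average for O3.

    A season day is valid when it has >= 18 present hours; the site-year is
    included when valid days cover at least 75% of the 153-day season
    (ceiling: >= 115 days).
    """
    if series.pollutant != "O3":
        raise ValueError("o3_season_metric is defined for O3 only")
    if series.cadence != "hourly":
        raise ValueError("O3 series must be hourly")
    idx = pd.DatetimeIndex(series.records.index)
    season = o3_season_days(series.year)
    in_season = idx.normalize().isin(season)
    records = series.records[in_season]
    idx = idx[in_season]

    daily_values = []
    for day, group in records.groupby(idx.normalize()):
        hours = pd.DatetimeIndex(group.index).hour.to_numpy()
        if len(hours) >= MIN_VALID_HOURS:
            daily_values.append(daily_max_8h(hours, group.to_numpy(dtype=float)))
    n_valid = len(daily_values)
    required = math.ceil(O3_MIN_VALID_FRACTION * O3_SEASON_DAYS)
    if n_valid < required:
        return Rejection(
            series.site_id, series.pollutant, series.year, "completeness",
            f"{n_valid} valid season days < {required} (75% of {O3_SEASON_DAYS})",
        )
    value = float(np.mean(daily_values))
    if len(reported_days(series)) < 2:
        return Rejection(series.site_id, series.pollutant, series.year,
                         "too_few_records", "fewer than 2 reported days")
    schedule = classify_schedule(series)
    return AnnualObservation(
        site_id=series.site_id, lon=series.lon, lat=series.lat,
        pollutant=series.pollutant, year=series.year,
        value_native=value, value_sqrt=sqrt_transform(value),
        n_valid_days=n_valid, schedule=schedule,
    )


def qc_series(series: MonitorSeries) -> AnnualObservation | Rejection:
    """Dispatch to the pollutant-appropriate annual metric."""
    if series.pollutant == "O3":
        return o3_season_metric(series)
    return annual_average(series)


# ---------------------------------------------------------------------------
# CSV interfaces


def read_monitor_csv(path) -> list[MonitorSeries]:
    """Read a monitor table (site_id, lon, lat, datetime|date, pollutant, value)."""
    df = pd.read_csv(path)
    time_col = "datetime" if "datetime" in df.columns else "date"
    df[time_col] = pd.to_datetime(df[time_col])
    out: list[MonitorSeries] = []
    for (site, pollutant, year), g in df.groupby(
        ["site_id", "pollutant", df[time_col].dt.year], sort=True
    ):
        g = g.sort_values(time_col)
        cadence = "hourly" if pollutant in GAS_POLLUTANTS else "daily"
        out.append(
            MonitorSeries(
                site_id=str(site), lon=float(g["lon"].iloc[0]), lat=float(g["lat"].iloc[0]),
                pollutant=str(pollutant), cadence=cadence, year=int(year),
                records=pd.Series(g["value"].to_numpy(dtype=float),
                                  index=pd.DatetimeIndex(g[time_col])),
            )
        )
    return out


def qc_to_dataframe(series_list: list[MonitorSeries]) -> pd.DataFrame:
    """Apply QC to every series; one row per series with status and reason."""
    rows = []
    for s in series_list:
        result = qc_series(s)
        if isinstance(result, AnnualObservation):
            rows.append({
                "site_id": result.site_id, "lon": result.lon, "lat": result.lat,
                "pollutant": result.pollutant, "year": result.year,
                "value_native": result.value_native, "value_sqrt": result.value_sqrt,
                "n_valid_days": result.n_valid_days, "schedule": result.schedule,
                "qc_status": "included", "qc_reason": "",
            })
        else:
            rows.append({
                "site_id": result.site_id, "lon": s.lon, "lat": s.lat,
                "pollutant": result.pollutant, "year": result.year,
                "value_native": np.nan, "value_sqrt": np.nan,
                "n_valid_days": pd.NA, "schedule": "",
                "qc_status": "rejected", "qc_reason": f"{result.rule}: {result.detail}",
            })
    return pd.DataFrame(rows)
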