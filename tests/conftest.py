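"""Shared fixtures: a small landscape, a truth field, and series builders."""

import numpy as np
import pandas as pd
import pytest

from airlur import generate_landscape, generate_truth_field
from airlur.qc import MonitorSeries


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(seed=7, n_roads=24, n_sources=12, domain_km=60.0)


@pytest.fixture(scope="session")
def truth(landscape):
    return generate_truth_field(landscape, partial_sill=0.05, range_km=15.0,
                                nugget=0.01, seed=11)


def make_daily_series(year=2016, days=None, values=None, pollutant="PM25",
                      site_id="S0"):
    """PM-style daily series from day-of-year indices (0-based)."""
    index = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")[list(days)]
    if values is None:
        values = np.full(len(index), 10.0)
    return MonitorSeries(site_id=site_id, lon=-98.0, lat=39.0, pollutant=pollutant,
                         cadence="daily", year=year,
                         records=pd.Series(np.asarray(values, float), index=index))


def make_hourly_series(year=2016, day_hours=None, value=10.0, pollutant="NO2",
                       values_by_day=None, site_id="S0"):
    """Gas-style hourly series; ``day_hours`` maps day-of-year (0-based) to an
    iterable of hours present that day.  ``values_by_day`` optionally maps the
    same keys to per-hour value arrays."""
    base = pd.Timestamp(f"{year}-01-01")
    stamps, vals = [], []
    for day, hours in sorted(day_hours.items()):
        hours = sorted(hours)
        day_ts = base + pd.Timedelta(days=day)
        for i, h in enumerate(hours):
            stamps.append(day_ts + pd.Timedelta(hours=int(h)))
            if values_by_day is not None:
                vals.append(values_by_day[day][i])
            else:
                vals.append(value)
    return MonitorSeries(site_id=site_id, lon=-98.0, lat=39.0, pollutant=pollutant,
                         cadence="hourly", year=year,
                         records=pd.Series(np.asarray(vals, float),
                                           index=pd.DatetimeIndex(stamps)))
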