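"""Uniform weekly time axis on a 364-day model calendar.

The simulator runs on years of exactly 52 weeks (364 days) so that weekly
sampling divides every year evenly and bandpass windows never straddle a
leap-week.  Months follow the usual civil lengths (Jan=31, Feb=28, ...);
day 363 therefore falls on 30 December and the nominal 31 December never
occurs.  Real-data ingestion converts true calendars through
:func:`axis_from_datetimes` instead.

"IOD years" span June 1 - May 31 (the Indian Ocean Dipole peaks in fall),
so a timestep is assigned to the IOD year that started on the most recent
June 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 364
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_EDGES = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])  # 0..365
JUNE1_DOY = int(_MONTH_EDGES[5])  # day-of-year index (0-based) of June 1


def month_of_day(day_of_year):
    """Calendar month (1-12) for a 0-based day-of-year in [0, 364)."""
    d = np.asarray(day_of_year)
    if np.any((d < 0) | (d >= DAYS_PER_YEAR)):
        raise ValueError("day_of_year must lie in [0, 364)")
    return np.searchsorted(_MONTH_EDGES, d, side="right").astype(int)


def weekly_axis(start_year: int, n_steps: int, dt_days: float = 7.0) -> pd.DataFrame:
    """Build the model time axis as a DataFrame.

    Columns: ``day`` (absolute model day since Jan 1 of start_year),
    ``year``, ``day_of_year`` (0-based), ``month`` (1-12) and ``iod_year``
    (the calendar year whose June 1 opened the current IOD window).
    """
    if dt_days <= 0:
        raise ValueError("dt_days must be positive")
    day = np.arange(n_steps) * float(dt_days)
    year = start_year + (day // DAYS_PER_YEAR).astype(int)
    doy = (day % DAYS_PER_YEAR).astype(int)
    month = month_of_day(doy)
    iod_year = np.where(doy >= JUNE1_DOY, year, year - 1)
    return pd.DataFrame(
        {"day": day, "year": year, "day_of_year": doy, "month": month,
         "iod_year": iod_year}
    )


def axis_from_datetimes(times) -> pd.DataFrame:
    """Same columns as :func:`weekly_axis` but from real calendar dates."""
    idx = pd.DatetimeIndex(times)
    year = idx.year.to_numpy()
    month = idx.month.to_numpy()
    iod_year = np.where(month >= 6, year, year - 1)
    day = (idx - idx[0]) / pd.Timedelta(days=1)
    doy = (idx.dayofyear - 1).to_numpy()
    return pd.DataFrame(
        {"day": np.asarray(day), "year": year, "day_of_year": doy,
         "month": month, "iod_year": iod_year}
    )
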