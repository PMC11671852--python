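"""Time-axis helpers for the 16-day composite and monthly calendars.

The composite calendar mimics the MODIS vegetation-index products: 23 fixed
16-day composites per year whose start days-of-year are 1, 17, ..., 353.
The last composite of each year absorbs the remaining 13 (or 14) days, so
leap days never shift composite starts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COMPOSITES_PER_YEAR = 23
COMPOSITE_DOYS = np.arange(1, 1 + 16 * COMPOSITES_PER_YEAR, 16)  # 1..353


def composite_dates(start_year: int, end_year: int) -> pd.DatetimeIndex:
    """Start dates of every 16-day composite in [start_year, end_year]."""
    dates = [
        pd.Timestamp(year=y, month=1, day=1) + pd.Timedelta(days=int(d) - 1)
        for y in range(start_year, end_year + 1)
        for d in COMPOSITE_DOYS
    ]
    return pd.DatetimeIndex(dates)


def month_dates(start_year: int, end_year: int) -> pd.DatetimeIndex:
    """First-of-month dates for every calendar month in the record."""
    return pd.date_range(
        start=f"{start_year}-01-01", end=f"{end_year}-12-01", freq="MS"
    )


def month_index(dates: pd.DatetimeIndex, start_year: int) -> np.ndarray:
    """Months elapsed since January of ``start_year`` (0-based)."""
    return ((dates.year - start_year) * 12 + dates.month - 1).to_numpy()


_NOMINAL_MONTH_END_DOY = np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def nominal_month(dates: pd.DatetimeIndex) -> np.ndarray:
    """Calendar month (0-based) of each date's day-of-year in the nominal
    365-day composite calendar.

    Composites keep fixed start days-of-year across years, so binning them
    by nominal month makes month membership identical in leap and regular
    years (the leap day is absorbed by the calendar's last composite).
    """
    return np.searchsorted(_NOMINAL_MONTH_END_DOY,
                           np.minimum(dates.dayofyear, 365), side="left")


def nominal_month_index(dates: pd.DatetimeIndex, start_year: int) -> np.ndarray:
    """Nominal months elapsed since January of ``start_year`` (0-based)."""
    return (dates.year.to_numpy() - start_year) * 12 + nominal_month(dates)


def n_months(start_year: int, end_year: int) -> int:
    return 12 * (end_year - start_year + 1)
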