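"""Per-pixel fire histories: burn-map decoding, quality and fire-season
filters, fire frequency, and selection of the twice-burned pixel set.

Events are carried as a tidy DataFrame with one row per (pixel, event):
``pixel_id, row, col, fire_month_idx, fire_date, burn_doy,
uncertainty_days, in_season``.  The event date used for time arithmetic is
the first day of the burn month; the burn day-of-year is kept for
reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import DataError
from .timeaxis import month_index

EVENT_COLUMNS = [
    "pixel_id", "row", "col", "fire_month_idx", "fire_date",
    "burn_doy", "uncertainty_days",
]


@dataclass(frozen=True)
class RegionSeason:
    """A region's extended fire season as an ordered tuple of months.

    Seasons may wrap the year boundary (e.g. October-February for
    Australia); membership is tested on the calendar month.
    """

    name: str
    months: tuple[int, ...]
    hemisphere: str = "north"

    def __post_init__(self):
        if not self.months:
            raise DataError(f"season '{self.name}' has no months")
        if any(m < 1 or m > 12 for m in self.months):
            raise DataError(f"season '{self.name}' has invalid month codes")

    def contains(self, month: int) -> bool:
        return month in self.months


def _span(start: int, end: int) -> tuple[int, ...]:
    """Inclusive month span, wrapping December to January."""
    months = [start]
    while months[-1] != end:
        months.append(months[-1] % 12 + 1)
    return tuple(months)


#: typical extended fire seasons of the five Mediterranean-climate regions
REGION_SEASONS = {
    "mediterranean": RegionSeason("mediterranean", _span(6, 10), "north"),
    "california": RegionSeason("california", _span(6, 10), "north"),
    "australia": RegionSeason("australia", _span(10, 2), "south"),
    "south_africa": RegionSeason("south_africa", _span(12, 4), "south"),
    "chile": RegionSeason("chile", _span(12, 4), "south"),
}


def events_from_burn_maps(burns: xr.Dataset, start_year: int) -> pd.DataFrame:
    """Decode monthly burn maps into the per-event table.

    A pixel burns in a month when ``burn_doy > 0`` there; the companion
    ``uncertainty_days`` band supplies the burn-date uncertainty.
    """
    doy = burns["burn_doy"].values
    unc = burns["uncertainty_days"].values
    time = burns["time"].to_index()
    midx = month_index(time, start_year)
    t, r, c = np.nonzero(doy > 0)
    ncols = burns.sizes["col"]
    df = pd.DataFrame(
        {
            "pixel_id": r * ncols + c,
            "row": r,
            "col": c,
            "fire_month_idx": midx[t],
            "fire_date": time[t],
            "burn_doy": doy[t, r, c].astype(int),
            "uncertainty_days": unc[t, r, c].astype(int),
        }
    )
    return df.sort_values(["pixel_id", "fire_month_idx"]).reset_index(drop=True)


def filter_burn_uncertainty(events: pd.DataFrame, max_days: float = 7) -> pd.DataFrame:
    """Drop events whose burn-date uncertainty exceeds ``max_days``.

    The boundary value is kept: only strictly larger uncertainties go.
    """
    if len(events) and (events["uncertainty_days"] < 0).any():
        raise DataError("negative burn-date uncertainty encountered")
    return events[events["uncertainty_days"] <= max_days].reset_index(drop=True)


def flag_in_season(events: pd.DataFrame, season: RegionSeason) -> pd.DataFrame:
    """Mark events falling inside the region's fire season."""
    out = events.copy()
    if len(out):
        months = pd.DatetimeIndex(out["fire_date"]).month
        out["in_season"] = [season.contains(int(m)) for m in months]
    else:
        out["in_season"] = pd.Series(dtype=bool)
    return out


def fire_frequency(events: pd.DataFrame, shape: tuple[int, int]):
    """Per-pixel count of in-season events and the relative-frequency table.

    Returns ``(count_map, table)`` where the table gives the share of
    burned pixels that burned once, twice, and three or more times.
    """
    nr, nc = shape
    counts = np.zeros((nr, nc), dtype=int)
    ev = events[events["in_season"]] if "in_season" in events else events
    if len(ev):
        np.add.at(counts, (ev["row"].to_numpy(), ev["col"].to_numpy()), 1)
    burned = counts[counts > 0]
    if burned.size == 0:
        table = pd.DataFrame(columns=["fire_count", "n_pixels", "relative_frequency"])
    else:
        rows = []
        for label, sel in (("1", burned == 1), ("2", burned == 2), (">=3", burned >= 3)):
            n = int(sel.sum())
            if n:
                rows.append(
                    {"fire_count": label, "n_pixels": n,
                     "relative_frequency": n / burned.size}
                )
        table = pd.DataFrame(rows)
    return counts, table


def select_twice_burned(
    events: pd.DataFrame,
    n_record_months: int,
    min_gap_months: int = 48,
    min_tail_months: int = 24,
    recurrence_rule: str = "exactly_two",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select pixels with two in-season fires at least ``min_gap_months``
    apart, leaving ``min_tail_months`` of record after the second fire.

    ``recurrence_rule`` is ``"exactly_two"`` (pixels with 3+ in-season
    fires are excluded) or ``"first_last"`` (take the first and last of
    2+ fires).  Returns ``(pairs, exclusions)``: one pair row per selected
    pixel with E1/E2 columns, and one exclusion row per rejected pixel
    naming the single rule that rejected it (``season``, ``count``,
    ``gap`` or ``tail``).
    """
    if recurrence_rule not in ("exactly_two", "first_last"):
        raise DataError(f"unknown recurrence rule '{recurrence_rule}'")
    if "in_season" not in events.columns:
        raise DataError("events must be season-flagged before pairing")
    pairs, exclusions = [], []
    for pid, grp in events.groupby("pixel_id"):
        ins = grp[grp["in_season"]].sort_values("fire_month_idx")
        if len(ins) == 0:
            exclusions.append({"pixel_id": pid, "rule": "season"})
            continue
        if len(ins) == 1:
            exclusions.append({"pixel_id": pid, "rule": "count"})
            continue
        if len(ins) > 2 and recurrence_rule == "exactly_two":
            exclusions.append({"pixel_id": pid, "rule": "count"})
            continue
        e1, e2 = ins.iloc[0], ins.iloc[-1]
        gap = int(e2["fire_month_idx"] - e1["fire_month_idx"])
        if gap < min_gap_months:
            exclusions.append({"pixel_id": pid, "rule": "gap"})
            continue
        if n_record_months - 1 - int(e2["fire_month_idx"]) < min_tail_months:
            exclusions.append({"pixel_id": pid, "rule": "tail"})
            continue
        pairs.append(
            {
                "pixel_id": pid,
                "row": int(e1["row"]),
                "col": int(e1["col"]),
                "e1_month_idx": int(e1["fire_month_idx"]),
                "e2_month_idx": int(e2["fire_month_idx"]),
                "gap_months": gap,
            }
        )
    pairs_df = pd.DataFrame(
        pairs, columns=["pixel_id", "row", "col", "e1_month_idx",
                        "e2_month_idx", "gap_months"],
    )
    excl_df = pd.DataFrame(exclusions, columns=["pixel_id", "rule"])
    return pairs_df, excl_df
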