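"""Seasonal standardized climate anomalies and post-fire anomaly profiles.

Anomalies are computed per 3-month calendar season (DJF, MAM, JJA, SON) on
seasonal aggregates — precipitation summed, temperature averaged within
each season instance — by removing the record-long climatological seasonal
mean and dividing by the seasonal standard deviation (sample sd over the
season instances).  Hemisphere only changes the local *name* of a season
(DJF is winter in the north, summer in the south); the arithmetic is
identical.

Each post-fire month inherits the z-score of the season instance that
contains it; quarters Q1-Q4 after a fire are the means over post-fire
months 1-3, 4-6, 7-9 and 10-12.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .errors import DataError
from .timeaxis import month_index

SEASONS = ("DJF", "MAM", "JJA", "SON")
_SEASON_OF_MONTH = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}
_LOCAL_NAMES = {
    "north": {"DJF": "winter", "MAM": "spring", "JJA": "summer", "SON": "autumn"},
    "south": {"DJF": "summer", "MAM": "autumn", "JJA": "winter", "SON": "spring"},
}

#: seasonal aggregate per variable: precipitation totals, temperature means
AGGREGATES = {"precipitation": "sum", "temperature": "mean"}


def season_local_name(season: str, hemisphere: str) -> str:
    return _LOCAL_NAMES[hemisphere][season]


def _instance_labels(time: pd.DatetimeIndex):
    """(season, instance_year) per month; DJF belongs to its January's year."""
    months = time.month
    years = time.year
    season = np.array([_SEASON_OF_MONTH[m] for m in months])
    inst_year = np.where(months == 12, years + 1, years)
    return season, inst_year


def _season_instances(series: xr.Dataset):
    """Aggregate each complete 3-month season instance.

    Yields ``(season, instance_year, month_positions, {var: aggregate})``
    for instances with all three months present.
    """
    time = series["time"].to_index()
    season, inst_year = _instance_labels(time)
    order = np.arange(len(time))
    for key in np.unique(inst_year * 10 + np.array([SEASONS.index(s) for s in season])):
        iy, si = divmod(int(key), 10)
        sel = order[(inst_year == iy) & (season == SEASONS[si])]
        if len(sel) != 3:
            continue  # incomplete instance at a record boundary
        aggs = {}
        for var, how in AGGREGATES.items():
            if var not in series:
                continue
            vals = series[var].values[sel]
            aggs[var] = vals.sum(axis=0) if how == "sum" else vals.mean(axis=0)
        yield SEASONS[si], iy, sel, aggs


def seasonal_climatology(series: xr.Dataset) -> xr.Dataset:
    """Per-season climatological mean and sd of the seasonal aggregates.

    Returns a Dataset on (season, crow, ccol) with ``<var>_mean``,
    ``<var>_sd`` (sample sd, n-1) and ``<var>_degenerate`` flags for cells
    whose seasonal sd is zero.
    """
    per_season: dict[str, dict[str, list]] = {s: {} for s in SEASONS}
    for season, _iy, _sel, aggs in _season_instances(series):
        for var, agg in aggs.items():
            per_season[season].setdefault(var, []).append(agg)
    spatial = {d: series[d] for d in ("crow", "ccol") if d in series.coords}
    data = {}
    for var in AGGREGATES:
        if var not in series:
            continue
        means, sds = [], []
        for s in SEASONS:
            stack = np.stack(per_season[s][var])
            if stack.shape[0] < 2:
                raise DataError(f"season {s} has fewer than 2 complete instances")
            means.append(stack.mean(axis=0))
            sds.append(stack.std(axis=0, ddof=1))
        dims = ("season",) + tuple(spatial)
        data[f"{var}_mean"] = (dims, np.stack(means))
        data[f"{var}_sd"] = (dims, np.stack(sds))
        data[f"{var}_degenerate"] = (dims, np.stack(sds) == 0)
        if (np.stack(sds) == 0).any():
            warnings.warn(f"degenerate seasonal sd for {var}: z undefined there")
    return xr.Dataset(data, coords={"season": list(SEASONS), **spatial},
                      attrs=dict(series.attrs))


def standardized_anomaly(aggregate, mean, sd):
    """z = (seasonal aggregate - climatological mean) / climatological sd."""
    sd = np.asarray(sd, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.asarray(aggregate, float) - np.asarray(mean, float)) / sd
    return np.where(sd > 0, z, np.nan)


def seasonal_z(series: xr.Dataset, climatology: xr.Dataset) -> xr.Dataset:
    """Monthly z-score fields: each month carries its season instance's z.

    Months in incomplete season instances (record boundaries) are NaN, as
    are cells with degenerate (zero-sd) climatology.
    """
    time = series["time"].to_index()
    out = {}
    for var in AGGREGATES:
        if var not in series:
            continue
        z = np.full(series[var].shape, np.nan)
        for season, _iy, sel, aggs in _season_instances(series):
            mean = climatology[f"{var}_mean"].sel(season=season).values
            sd = climatology[f"{var}_sd"].sel(season=season).values
            zval = standardized_anomaly(aggs[var], mean, sd)
            z[sel] = zval[None, ...]
        out[f"{var}_z"] = (series[var].dims, z)
    return xr.Dataset(out, coords=series.coords, attrs=dict(series.attrs))


def _nearest_cell(coord_values: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Index of the nearest cell centre for each pixel position."""
    return np.abs(positions[:, None] - coord_values[None, :]).argmin(axis=1)


def postfire_profile(
    zmonthly: xr.Dataset,
    events: pd.DataFrame,
    start_year: int,
) -> pd.DataFrame:
    """Quarterly post-fire anomaly profile per pixel and event.

    ``events`` needs columns ``pixel_id, event, row, col, fire_month_idx``.
    Each pixel reads the climate cell nearest to it; quarters with no
    months inside the record are NaN.  Returns tidy rows
    ``(pixel_id, event, variable, quarter, z)``.
    """
    time = zmonthly["time"].to_index()
    midx = month_index(time, start_year)
    pos = {int(m): i for i, m in enumerate(midx)}
    crow = zmonthly["crow"].values
    ccol = zmonthly["ccol"].values
    cell_r = _nearest_cell(crow, events["row"].to_numpy(float))
    cell_c = _nearest_cell(ccol, events["col"].to_numpy(float))
    rows = []
    for k, rec in enumerate(events.itertuples(index=False)):
        for var in AGGREGATES:
            zvar = f"{var}_z"
            if zvar not in zmonthly:
                continue
            series = zmonthly[zvar].values[:, cell_r[k], cell_c[k]]
            for q in range(4):
                months = [rec.fire_month_idx + 1 + 3 * q + j for j in range(3)]
                vals = [series[pos[m]] for m in months if m in pos]
                z = float(np.nanmean(vals)) if vals else np.nan
                rows.append(
                    {
                        "pixel_id": rec.pixel_id,
                        "event": rec.event,
                        "variable": var,
                        "quarter": f"Q{q + 1}",
                        "z": z,
                    }
                )
    return pd.DataFrame(rows)


def group_anomalies(profiles: pd.DataFrame, grouped_pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean post-fire z per (variable, quarter, event, group, land cover).

    ``grouped_pairs`` supplies the pixel group labels (and optionally the
    land-cover category); cells with no members are simply absent.
    """
    keys = ["pixel_id", "group"] + (
        ["landcover"] if "landcover" in grouped_pairs.columns else []
    )
    merged = profiles.merge(grouped_pairs[keys], on="pixel_id", how="inner")
    if merged.empty:
        warnings.warn("no overlap between profiles and grouped pairs")
    by = ["variable", "quarter", "event", "group"] + (
        ["landcover"] if "landcover" in merged.columns else []
    )
    out = (
        merged.groupby(by, observed=True)["z"]
        .agg(mean_z="mean", n="count")
        .reset_index()
    )
    return out
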