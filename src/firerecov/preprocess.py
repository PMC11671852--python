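"""EVI-cube preprocessing: gap filling, spectral smoothing, detrending and
monthly aggregation, plus land-cover class aggregation.

The chain is fixed — ``fill_low_quality -> fft_smooth -> loess_detrend ->
monthly_aggregate`` — and each step checks the cube's processing state, so
steps cannot be reordered or repeated.  Smoothing and detrending operate
strictly per pixel; the only spatial operation is the neighbour fill.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import CubicSpline

from .containers import EviCube, LandCoverMap, QUALITY_GOOD, code_to_category
from .errors import ConfigError, DataError, StateError
from .timeaxis import nominal_month

_DAYS_PER_MONTH = 365.25 / 12.0
_NOMINAL_SPACING_DAYS = 365.25 / 23.0  # mean composite spacing


def fill_low_quality(cube: EviCube) -> EviCube:
    """Replace low-quality observations.

    A low-quality observation is first replaced by the mean of good-quality
    values among its 8 spatial neighbours in the same composite, provided at
    least 3 good neighbours exist.  Remaining gaps are filled per pixel by a
    piecewise-cubic (spline) interpolation over time; gaps before the first
    or after the last valid observation take the nearest valid value.  Good
    observations are never altered.  Pixels with fewer than 4 good
    observations over the whole record cannot anchor an interpolation; they
    are masked and listed in the returned cube's ``mask``.
    """
    cube.require_state("raw", "fill_low_quality")
    if cube.quality is None:
        raise DataError("fill_low_quality needs per-observation quality flags")
    vals = cube.data.values.astype(float).copy()
    good = cube.quality.values == QUALITY_GOOD
    n_t, nr, nc = vals.shape

    # pixels too poor to fill
    good_counts = good.sum(axis=0)
    bad_pixels = good_counts < 4
    report = [
        {"row": int(r), "col": int(c), "n_good": int(good_counts[r, c])}
        for r, c in zip(*np.nonzero(bad_pixels))
    ]

    filled = vals.copy()
    valid = good.copy()

    if not good.all():
        # spatial step: 8-neighbour mean of good values, per composite
        gv = np.where(good, vals, 0.0)
        gc = good.astype(float)
        nsum = np.zeros_like(vals)
        ncnt = np.zeros_like(vals)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                shifted_v = np.zeros_like(vals)
                shifted_c = np.zeros_like(vals)
                rs = slice(max(dr, 0), nr + min(dr, 0))
                cs = slice(max(dc, 0), nc + min(dc, 0))
                rd = slice(max(-dr, 0), nr + min(-dr, 0))
                cd = slice(max(-dc, 0), nc + min(-dc, 0))
                shifted_v[:, rd, cd] = gv[:, rs, cs]
                shifted_c[:, rd, cd] = gc[:, rs, cs]
                nsum += shifted_v
                ncnt += shifted_c
        can_fill = (~good) & (ncnt >= 3)
        with np.errstate(invalid="ignore", divide="ignore"):
            filled = np.where(can_fill, nsum / np.maximum(ncnt, 1), filled)
        valid = good | can_fill

        # temporal step: cubic interpolation through valid points
        t = np.arange(n_t, dtype=float)
        flat_v = filled.reshape(n_t, -1)
        flat_ok = valid.reshape(n_t, -1)
        flat_bad_pix = bad_pixels.reshape(-1)
        for p in range(flat_v.shape[1]):
            if flat_bad_pix[p]:
                flat_v[:, p] = np.nan
                continue
            ok = flat_ok[:, p]
            if ok.all():
                continue
            ti, yi = t[ok], flat_v[ok, p]
            gaps = ~ok
            inner = gaps & (t > ti[0]) & (t < ti[-1])
            if inner.any():
                spline = CubicSpline(ti, yi)
                flat_v[inner, p] = spline(t[inner])
            before = gaps & (t < ti[0])
            after = gaps & (t > ti[-1])
            flat_v[before, p] = yi[0]
            flat_v[after, p] = yi[-1]
        filled = flat_v.reshape(n_t, nr, nc)
    elif bad_pixels.any():  # pragma: no cover - all good implies none bad
        pass

    out = cube.replace(
        xr.DataArray(filled, coords=cube.data.coords, dims=cube.data.dims, name="evi"),
        state="gapfilled",
    )
    out.mask = bad_pixels
    out.fill_report = report
    return out


def fft_smooth(cube: EviCube, keep_period_months: float = 3.0) -> EviCube:
    """Low-pass the series per pixel in the Fourier domain.

    All Fourier components with period shorter than ``keep_period_months``
    are zeroed; the DC component (the series mean) is always retained, so
    each pixel's mean is preserved to machine precision.  The composite
    spacing is treated as uniform at its nominal value (365.25/23 days).
    """
    cube.require_state("gapfilled", "fft_smooth")
    min_period = 2 * _NOMINAL_SPACING_DAYS / _DAYS_PER_MONTH
    if keep_period_months < min_period:
        raise ConfigError(
            "keep_period_months",
            f"must be at least two composite intervals (~{min_period:.2f} months)",
        )
    vals = cube.data.values
    n_t = vals.shape[0]
    flat = vals.reshape(n_t, -1)
    pix_ok = ~np.isnan(flat).any(axis=0)
    out = np.full_like(flat, np.nan)
    if pix_ok.any():
        spec = np.fft.rfft(flat[:, pix_ok], axis=0)
        freq = np.fft.rfftfreq(n_t, d=_NOMINAL_SPACING_DAYS)  # cycles/day
        cutoff = 1.0 / (keep_period_months * _DAYS_PER_MONTH)
        spec[freq > cutoff, :] = 0.0
        out[:, pix_ok] = np.fft.irfft(spec, n=n_t, axis=0)
    return cube.replace(
        xr.DataArray(out.reshape(vals.shape), coords=cube.data.coords,
                     dims=cube.data.dims, name="evi"),
        state="smoothed",
    )


def loess_detrend(
    cube: EviCube, span_fraction: float = 0.5, robust_iterations: int = 2
) -> EviCube:
    """Remove each pixel's long-term trend with a robust LOESS fit.

    A locally weighted linear regression (tricube weights) with span
    ``span_fraction`` of the record is estimated per pixel and subtracted;
    the pixel's overall mean is added back, so only shape, not level, is
    changed.  The wide default span removes decadal greening trends while
    leaving 2-5-year recovery segments in place, and the robustifying
    iterations down-weight the fire excursions themselves so the trend is
    not dragged into the disturbance it must preserve.
    """
    cube.require_state("smoothed", "loess_detrend")
    if not (0.1 < span_fraction <= 1):
        raise ConfigError("span_fraction", "must lie in (0.1, 1]")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    vals = cube.data.values
    n_t = vals.shape[0]
    flat = vals.reshape(n_t, -1)
    out = np.full_like(flat, np.nan)
    t = np.arange(n_t, dtype=float)
    for p in range(flat.shape[1]):
        y = flat[:, p]
        if np.isnan(y).any():
            continue
        trend = lowess(y, t, frac=span_fraction, it=robust_iterations,
                       return_sorted=False)
        # subtract the mean-centred trend: the pixel mean is restored exactly
        out[:, p] = y - trend + trend.mean()
    return cube.replace(
        xr.DataArray(out.reshape(vals.shape), coords=cube.data.coords,
                     dims=cube.data.dims, name="evi"),
        state="detrended",
    )


def monthly_aggregate(cube: EviCube) -> EviCube:
    """Average the composites of each calendar month into a monthly series.

    Month membership follows the composite's day-of-year in the nominal
    365-day composite calendar (leap days are absorbed by the calendar's
    last composite), so every calendar month contains the same composites
    in every year.
    """
    cube.require_state("detrended", "monthly_aggregate")
    time = cube.time
    keys = time.year * 12 + nominal_month(time)
    uniq, inv = np.unique(keys, return_inverse=True)
    expected = np.arange(keys.min(), keys.max() + 1)
    if not np.array_equal(uniq, expected):  # pragma: no cover - 23/yr calendar
        raise DataError("internal error: a calendar month has no composites")
    vals = cube.data.values
    n_t = vals.shape[0]
    flat = vals.reshape(n_t, -1)
    sums = np.zeros((len(uniq), flat.shape[1]))
    np.add.at(sums, inv, flat)
    counts = np.bincount(inv, minlength=len(uniq)).astype(float)
    monthly = sums / counts[:, None]
    mdates = pd.DatetimeIndex(
        [pd.Timestamp(year=k // 12, month=k % 12 + 1, day=1) for k in uniq]
    )
    coords = {"time": mdates, "row": cube.data.coords["row"],
              "col": cube.data.coords["col"]}
    return cube.replace(
        xr.DataArray(monthly.reshape(len(uniq), *vals.shape[1:]),
                     coords=coords, dims=("time", "row", "col"), name="evi"),
        state="monthly",
    )


def advance_state(cube: EviCube, to_state: str) -> EviCube:
    """Mark a disabled stage as passed without transforming the data.

    Used by the pipeline when smoothing or detrending is switched off: the
    state tag still advances so downstream state checks hold, but values are
    untouched.  Only single-step forward moves are allowed.
    """
    order = ("raw", "gapfilled", "smoothed", "detrended", "monthly")
    i, j = order.index(cube.state), order.index(to_state)
    if j != i + 1:
        raise StateError(f"cannot advance state from '{cube.state}' to '{to_state}'")
    return cube.replace(cube.data, state=to_state, quality=cube.quality)


def aggregate_landcover(lc: LandCoverMap) -> LandCoverMap:
    """Aggregate UN-LCCS 37-class codes into the eight analysis categories.

    Forests split by leaf type (BL/NL/MF), shrubland, transitional
    woodland, grassland and cropland keep their own categories; sparse,
    bare, urban and water classes (codes 150-220) fall into "Oth".
    Unknown codes raise, listing the offending values.
    """
    codes = lc.codes.values
    uniq = np.unique(codes)
    mapping = {}
    unknown = []
    for code in uniq:
        try:
            mapping[int(code)] = code_to_category(int(code))
        except DataError:
            unknown.append(int(code))
    if unknown:
        raise DataError(f"unmapped land-cover class codes: {sorted(unknown)}")
    cats = np.vectorize(mapping.get)(codes)
    return LandCoverMap(
        codes=lc.codes,
        categories=xr.DataArray(cats, dims=lc.codes.dims, coords=lc.codes.coords),
    )
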