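"""The recovery model: ideal seasonal cycle, loss-of-greenness series,
fire-severity location, and exponential recovery-rate fitting.

Model
-----
The *Gorgeous Year* ``GY(m)`` is the per-pixel maximum monthly EVI for each
calendar month over the record — the pixel's ideal annual cycle.  The loss
of greenness ``y(t) = EVI(t) - GY(month(t))`` lies in [-1, 0].  Assuming
the recovery rate of greenness is proportional to the remaining loss,
``dy/dt = -b y``, the post-fire loss decays as ``y(t) = a e^{-b t}`` where
``a`` (the minimum of y at/after the fire) measures fire severity and
``b`` (month^-1) the recovery rate.  ``b`` is estimated as minus the slope
of an ordinary linear regression of ``ln(-y)`` on months-since-minimum,
iterating over candidate window lengths of 2-5 years and keeping the
window with the best adjusted r^2.  The characteristic recovery time is
``1/b``, the time to reach about half the relative recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .containers import EviCube
from .errors import ConsistencyError, DataError

DEFAULT_WINDOWS = (24, 36, 48, 60)

_LOSS_ROUNDOFF = 1e-9


@dataclass
class GorgeousYear:
    """Per-pixel 12-month ideal cycle and its mean."""

    gy: xr.DataArray       # (month: 1..12, row, col)
    gy_mean: xr.DataArray  # (row, col)
    valid: np.ndarray      # (row, col) bool


@dataclass
class LossSeries:
    """Monthly loss of greenness y(t) on (time, row, col); values in [-1, 0]."""

    data: xr.DataArray

    @property
    def time(self) -> pd.DatetimeIndex:
        return self.data.coords["time"].to_index()


@dataclass
class RecoveryFit:
    """Fit result for one pixel-event."""

    a: float
    t0: int                 # month index of the minimum of y
    b: float
    se: float
    adj_r2: float
    window_months: int
    ci_low: float
    ci_high: float
    a_rel: float
    t_char: float
    n_points: int
    valid: bool
    reason: str = ""


def compute_gorgeous_year(cube: EviCube) -> GorgeousYear:
    """GY(m) = max over years of monthly EVI at calendar month m, per pixel."""
    cube.require_state("monthly", "compute_gorgeous_year")
    vals = cube.data.values
    n_t, nr, nc = vals.shape
    if n_t % 12:
        raise DataError("monthly cube must cover whole calendar years")
    by_year = vals.reshape(n_t // 12, 12, nr, nc)
    with np.errstate(invalid="ignore"):
        gy = np.nanmax(by_year, axis=0)
    valid = ~np.isnan(gy).any(axis=0)
    gy_mean = gy.mean(axis=0)
    coords = {"month": np.arange(1, 13), "row": cube.data.coords["row"],
              "col": cube.data.coords["col"]}
    return GorgeousYear(
        gy=xr.DataArray(gy, coords=coords, dims=("month", "row", "col")),
        gy_mean=xr.DataArray(gy_mean, coords={"row": coords["row"],
                                              "col": coords["col"]},
                             dims=("row", "col")),
        valid=valid,
    )


def loss_series(cube: EviCube, gy: GorgeousYear) -> LossSeries:
    """y(t) = EVI(t) - GY(month(t)); requires GY from the same cube."""
    cube.require_state("monthly", "loss_series")
    months = cube.time.month
    y = cube.data.values - gy.gy.values[months - 1]
    if np.nanmax(y) > _LOSS_ROUNDOFF:
        raise ConsistencyError(
            "positive loss of greenness: the Gorgeous Year does not bound this "
            "cube (was it computed from a different cube?)"
        )
    y = np.minimum(y, 0.0)  # absorb float roundoff at the attained maxima
    return LossSeries(
        data=xr.DataArray(y, coords=cube.data.coords, dims=cube.data.dims,
                          name="loss")
    )


def locate_severity(
    y: np.ndarray, fire_month: int, search_months: int = 3
) -> tuple[float, int]:
    """Minimum of y between the fire month and ``search_months`` after it.

    Returns ``(a, t0)``; ties go to the earliest month.  Raises if the
    search window holds no finite value.
    """
    if not (0 <= fire_month < len(y)):
        raise DataError("fire month outside the record")
    window = y[fire_month: fire_month + search_months + 1]
    if np.isnan(window).all():
        raise DataError("severity search window entirely masked")
    i = int(np.nanargmin(window))
    return float(window[i]), fire_month + i


def relative_severity(a: float, gy_mean: float) -> float:
    """a_REL = |a| / GY_MEAN; 0 means no severity, unbounded above."""
    if not gy_mean > 0:
        raise DataError("GY_MEAN must be positive (bare pixel)")
    return abs(a) / gy_mean


def prefire_state(y: np.ndarray, fire_month: int) -> float:
    """Median loss over the 3 months before the fire (fire month excluded)."""
    if fire_month < 3:
        raise DataError("fewer than 3 months of record before the fire")
    return float(np.median(y[fire_month - 3: fire_month]))


def fit_recovery(
    y: np.ndarray,
    a: float,
    t0: int,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    r2_min: float = 0.25,
    truncate_before: int | None = None,
    fit_intercept: bool = True,
    se_method: str = "hc3",
    gy_mean: float | None = None,
) -> RecoveryFit:
    """Fit ln(-y) ~ t over candidate windows after the minimum at ``t0``.

    For each window length L the regression uses months t0..t0+L, dropping
    months where y >= 0 (the log is undefined once the loss closes) and
    months at or beyond ``truncate_before`` (the next fire).  At least 12
    usable points are required.  The window with the highest adjusted r^2
    wins; exact ties go to the shortest window.  The 95% CI comes from the
    slope's standard error with a Student-t quantile (n-2 df); by default
    the standard error is heteroscedasticity-robust (HC3), since the log
    transform inflates the error variance as the loss approaches zero.
    """
    limit = len(y) if truncate_before is None else min(len(y), truncate_before)
    best = None
    any_points = False
    for L in windows:
        end = min(t0 + L + 1, limit)
        seg = y[t0:end]
        t = np.arange(len(seg), dtype=float)
        use = np.isfinite(seg) & (seg < 0)
        n = int(use.sum())
        if n < 12:
            continue
        any_points = True
        tt, ly = t[use], np.log(-seg[use])
        if fit_intercept:
            tbar = tt.mean()
            xc = tt - tbar
            sxx = float(xc @ xc)
            if sxx == 0:
                continue
            slope = float(xc @ ly) / sxx
            intercept = ly.mean() - slope * tbar
            resid = ly - (intercept + slope * tt)
            dof = n - 2
            lev = 1.0 / n + xc ** 2 / sxx
        else:
            # through-origin variant: ln(y/a) = -b t fixes the intercept
            # at ln(-a), so the response is shifted before the origin fit
            ly = ly - np.log(-a)
            sxx = float(tt @ tt)
            if sxx == 0:
                continue
            slope = float(tt @ ly) / sxx
            resid = ly - slope * tt
            dof = n - 1
            xc = tt
            lev = tt ** 2 / sxx
        if dof < 1:
            continue
        ss_res = float(resid @ resid)
        ss_tot = float(((ly - ly.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / dof
        if se_method == "hc3":
            u = resid / np.maximum(1.0 - lev, 1e-8)
            se = float(np.sqrt(((xc * u) ** 2).sum())) / sxx
        else:
            se = float(np.sqrt(ss_res / dof / sxx))
        if best is None or adj > best[0]:
            best = (adj, slope, se, n, L, dof)

    if best is None:
        reason = "insufficient_points" if not any_points else "degenerate_window"
        if not any_points and np.all(y[t0:limit] >= 0):
            reason = "no_loss"
        return RecoveryFit(a=a, t0=t0, b=np.nan, se=np.nan, adj_r2=np.nan,
                           window_months=0, ci_low=np.nan, ci_high=np.nan,
                           a_rel=np.nan, t_char=np.nan, n_points=0,
                           valid=False, reason=reason)

    adj, slope, se, n, L, dof = best
    b = -slope
    tq = float(stats.t.ppf(0.975, dof))
    ci_low, ci_high = b - tq * se, b + tq * se
    a_rel = relative_severity(a, gy_mean) if gy_mean is not None else np.nan
    t_char = 1.0 / b if b > 0 else np.nan
    valid = bool(adj >= r2_min and b > 0)
    reason = "" if valid else ("nonpositive_b" if b <= 0 else "poor_fit")
    return RecoveryFit(a=a, t0=t0, b=b, se=se, adj_r2=adj, window_months=L,
                       ci_low=ci_low, ci_high=ci_high, a_rel=a_rel,
                       t_char=t_char, n_points=n, valid=valid, reason=reason)


def fit_events(
    loss: LossSeries,
    gy: GorgeousYear,
    pairs: pd.DataFrame,
    landcover: pd.Series | None = None,
    search_months: int = 3,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    r2_min: float = 0.25,
    fit_intercept: bool = True,
    se_method: str = "hc3",
) -> pd.DataFrame:
    """Fit both events of every twice-burned pixel.

    The E1 fit window stops the month before E2 so the second disturbance
    cannot contaminate it.  Returns one row per pixel x event with the fit
    parameters, the pre-fire state, and the land-cover category.
    """
    yv = loss.data.values
    gym = gy.gy_mean.values
    rows = []
    for rec in pairs.itertuples(index=False):
        ypix = yv[:, rec.row, rec.col]
        for event, fire_month, trunc in (
            (1, rec.e1_month_idx, rec.e2_month_idx),
            (2, rec.e2_month_idx, None),
        ):
            base = {
                "pixel_id": rec.pixel_id, "row": rec.row, "col": rec.col,
                "event": event, "fire_month_idx": fire_month,
            }
            if landcover is not None:
                base["landcover"] = landcover.loc[rec.pixel_id]
            gy_mean = float(gym[rec.row, rec.col])
            try:
                a, t0 = locate_severity(ypix, fire_month, search_months)
                fit = fit_recovery(
                    ypix, a, t0, windows=windows, r2_min=r2_min,
                    truncate_before=trunc, fit_intercept=fit_intercept,
                    se_method=se_method, gy_mean=gy_mean,
                )
            except DataError as exc:
                rows.append({**base, "valid": False, "reason": str(exc)})
                continue
            try:
                y_pre = prefire_state(ypix, fire_month)
            except DataError:
                y_pre = np.nan
            rows.append({**base, **asdict(fit), "y_pre": y_pre})
    return pd.DataFrame(rows)


def fit_cohort(
    y_matrix: np.ndarray,
    search_months: int = 3,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    r2_min: float = 0.25,
    fit_intercept: bool = True,
    se_method: str = "hc3",
) -> pd.DataFrame:
    """Fit every row of an (n_events, n_months) loss matrix.

    Rows are event-aligned (the fire is at month 0); used for Monte-Carlo
    cohorts from :func:`firerecov.synthgen.simulate_loss_cohort`.
    """
    rows = []
    for i in range(y_matrix.shape[0]):
        ypix = y_matrix[i]
        a, t0 = locate_severity(ypix, 0, search_months)
        fit = fit_recovery(ypix, a, t0, windows=windows, r2_min=r2_min,
                           fit_intercept=fit_intercept, se_method=se_method)
        rows.append({"pixel_id": i, **asdict(fit)})
    return pd.DataFrame(rows)
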