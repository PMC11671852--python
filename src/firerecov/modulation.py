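"""Event-contrast and modulation analyses.

Given per-event recovery fits for twice-burned pixels, this module builds
the paired table (b_DIFF = b2 - b1), tests the paired differences with a
Wilcoxon signed-rank test, selects the pixels with the most relevant
differences (outside the 25th-75th interquartile range, per land-cover
category), and quantifies how recovery rate depends on relative fire
severity through bivariate kernel densities and quantile regression at
the conditional envelopes (tau = 0.01 and 0.99).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

from .errors import DataError

GROUP_FASTER_E2 = "b1_lt_b2"
GROUP_FASTER_E1 = "b1_gt_b2"
GROUP_MIDDLE = "middle"


@dataclass
class WilcoxonResult:
    statistic: float       # W = min(W+, W-)
    p_value: float         # two-sided
    n_nonzero: int
    method: str            # "exact" or "normal"
    degenerate: bool = False


@dataclass
class QuantileFit:
    tau: float
    slope: float
    intercept: float
    pinball_loss: float
    n: int


def pair_events(fits: pd.DataFrame, validity_rule: str = "both_valid") -> pd.DataFrame:
    """One row per pixel whose two events are usable, with b_DIFF = b2 - b1.

    ``validity_rule`` controls the exclusion of poorly fitted pixels:
    ``"both_valid"`` (default) keeps a pixel only when both event fits pass
    the adjusted-r^2 screen, while ``"literal_both_fail"`` drops a pixel
    only when *both* fits fail it.
    """
    if validity_rule not in ("both_valid", "literal_both_fail"):
        raise DataError(f"unknown validity rule '{validity_rule}'")
    dup = fits.duplicated(subset=["pixel_id", "event"])
    if dup.any():
        raise DataError("duplicate pixel-event rows in the fits table")
    e1 = fits[fits["event"] == 1].set_index("pixel_id")
    e2 = fits[fits["event"] == 2].set_index("pixel_id")
    common = e1.index.intersection(e2.index)
    e1, e2 = e1.loc[common], e2.loc[common]
    v1 = e1["valid"].fillna(False).astype(bool)
    v2 = e2["valid"].fillna(False).astype(bool)
    keep = (v1 & v2) if validity_rule == "both_valid" else (v1 | v2)
    # even under the literal rule a b_DIFF needs two finite rates
    keep &= e1["b"].notna() & e2["b"].notna()
    e1, e2 = e1[keep], e2[keep]
    out = pd.DataFrame(
        {
            "pixel_id": e1.index,
            "b1": e1["b"].to_numpy(),
            "b2": e2["b"].to_numpy(),
            "a_rel1": e1["a_rel"].to_numpy(),
            "a_rel2": e2["a_rel"].to_numpy(),
            "y_pre1": e1.get("y_pre", pd.Series(np.nan, index=e1.index)).to_numpy(),
            "y_pre2": e2.get("y_pre", pd.Series(np.nan, index=e2.index)).to_numpy(),
        }
    )
    out["b_diff"] = out["b2"] - out["b1"]
    if "landcover" in fits.columns:
        out["landcover"] = e1["landcover"].to_numpy()
    # carry pixel coordinates and fire months when present, so the climate
    # stage can be fed directly from this table
    for col in ("row", "col"):
        if col in fits.columns:
            out[col] = e1[col].to_numpy()
    if "fire_month_idx" in fits.columns:
        out["e1_month_idx"] = e1["fire_month_idx"].to_numpy()
        out["e2_month_idx"] = e2["fire_month_idx"].to_numpy()
    return out.reset_index(drop=True)


# ---------------------------------------------------------------- Wilcoxon

def _signed_rank_stats(diffs: np.ndarray):
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]  # drop-zeros convention
    n = len(d)
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return d, n, ranks, w_plus, w_minus


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p over all sign assignments of the (mid)ranks.

    Midranks are half-integers at worst, so doubling them gives integers
    and the null distribution of 2*W+ follows from the characteristic
    polynomial product -- identical to full 2^n enumeration.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(np.rint(2 * w_obs))
    lo = min(w2, total - w2)
    p = dist[: lo + 1].sum() + dist[total - lo:].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(diffs: np.ndarray, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of median difference zero.

    Zero differences are dropped; ties in |d| take midranks.  The p-value
    is exact (full sign enumeration) for n <= ``exact_max_n`` and uses the
    tie- and continuity-corrected normal approximation beyond.
    """
    d, n, ranks, w_plus, w_minus = _signed_rank_stats(diffs)
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_nonzero=0,
                              method="degenerate", degenerate=True)
    if n < 5:
        warnings.warn("fewer than 5 nonzero differences: test has no power")
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(statistic=w, p_value=p, n_nonzero=n, method="exact")
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = float(((counts ** 3 - counts).sum())) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if var <= 0:
        return WilcoxonResult(statistic=w, p_value=1.0, n_nonzero=n,
                              method="normal", degenerate=True)
    # continuity correction toward the mean
    z = (w - mean + 0.5) / np.sqrt(var)
    p = float(min(1.0, 2 * stats.norm.cdf(z)))
    return WilcoxonResult(statistic=w, p_value=p, n_nonzero=n, method="normal")


# ------------------------------------------------------------- IQR groups

def select_extreme_diffs(
    pairs: pd.DataFrame, lo: float = 0.25, hi: float = 0.75
) -> pd.DataFrame:
    """Group pixels by b_DIFF outside the IQR, per land-cover category.

    Within each category, pixels below the ``lo`` quantile with negative
    b_DIFF form the faster-after-E1 group, pixels above the ``hi`` quantile
    with positive b_DIFF the faster-after-E2 group; the rest are "middle".
    Quantiles use linear interpolation between order statistics.
    """
    out = pairs.copy()
    out["group"] = GROUP_MIDDLE
    cats = out["landcover"].unique() if "landcover" in out else [None]
    for cat in cats:
        sel = out["landcover"] == cat if cat is not None else np.ones(len(out), bool)
        d = out.loc[sel, "b_diff"]
        q25 = d.quantile(lo, interpolation="linear")
        q75 = d.quantile(hi, interpolation="linear")
        if q25 == q75:
            warnings.warn(
                f"degenerate b_diff distribution in '{cat}': no extreme groups"
            )
            continue
        out.loc[sel & (out["b_diff"] < q25) & (out["b_diff"] < 0),
                "group"] = GROUP_FASTER_E1
        out.loc[sel & (out["b_diff"] > q75) & (out["b_diff"] > 0),
                "group"] = GROUP_FASTER_E2
    return out


# -------------------------------------------------------------------- KDE

def kde_bivariate(
    points: np.ndarray, grid_size: int = 100, margin_bw: float = 4.0
):
    """Gaussian product-kernel density of (a_REL, b) points on a grid.

    Bandwidths follow Scott's rule per axis (sd * n^(-1/6) for two
    dimensions), with a small floor when an axis is degenerate.  Returns
    ``(x_grid, y_grid, density, centroid)`` where the centroid is the
    sample mean of the points; the density integrates to 1 over the grid
    to within about 1%.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DataError("expected an (n, 2) array of (a_rel, b) points")
    n = pts.shape[0]
    if n < 10:
        raise DataError("need at least 10 points for a bivariate KDE")
    sds = pts.std(axis=0, ddof=1)
    scale = np.maximum(np.abs(pts).max(axis=0), 1.0)
    floor = 1e-3 * scale
    if (sds == 0).any():
        warnings.warn("zero variance on an axis: bandwidth floor applied")
    bw = np.maximum(sds * n ** (-1.0 / 6.0), floor)
    gx = np.linspace(pts[:, 0].min() - margin_bw * bw[0],
                     pts[:, 0].max() + margin_bw * bw[0], grid_size)
    gy = np.linspace(pts[:, 1].min() - margin_bw * bw[1],
                     pts[:, 1].max() + margin_bw * bw[1], grid_size)
    kx = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / bw[0]) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / bw[1]) ** 2)
    norm = 2 * np.pi * bw[0] * bw[1] * n
    density = (kx @ ky.T) / norm  # (grid_x, grid_y)
    centroid = pts.mean(axis=0)
    return gx, gy, density, centroid


# ------------------------------------------------------- quantile regression

def quantile_regression(x: np.ndarray, y: np.ndarray, tau: float) -> QuantileFit:
    """Linear quantile regression of y on x by linear programming.

    Minimises the pinball loss ``sum rho_tau(y - b0 - b1 x)`` exactly; the
    LP optimum sits at a vertex, i.e. a line through (at least) two sample
    points.  Slopes are in the units of y per unit of x (month^-1 per
    relative-severity unit for the severity-recovery envelopes).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 20:
        raise DataError("need at least 20 points for quantile regression")
    if not (0 < tau < 1):
        raise DataError("tau must be in (0, 1)")
    if np.ptp(x) == 0:
        raise DataError("x is degenerate (zero range)")
    # variables: [b0+, b0-, b1+, b1-, u+ (n), u- (n)]
    c = np.concatenate([[0, 0, 0, 0], tau * np.ones(n), (1 - tau) * np.ones(n)])
    A_eq = np.zeros((n, 4 + 2 * n))
    A_eq[:, 0] = 1.0
    A_eq[:, 1] = -1.0
    A_eq[:, 2] = x
    A_eq[:, 3] = -x
    A_eq[:, 4: 4 + n] = np.eye(n)
    A_eq[:, 4 + n:] = -np.eye(n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=[(0, None)] * (4 + 2 * n),
                  method="highs")
    if not res.success:
        raise DataError(f"quantile regression LP failed: {res.message}")
    b0 = res.x[0] - res.x[1]
    b1 = res.x[2] - res.x[3]
    resid = y - b0 - b1 * x
    loss = float(np.sum(resid * (tau - (resid < 0))))
    return QuantileFit(tau=tau, slope=float(b1), intercept=float(b0),
                       pinball_loss=loss, n=n)


def pinball_loss(x, y, intercept, slope, tau) -> float:
    resid = np.asarray(y, float) - intercept - slope * np.asarray(x, float)
    return float(np.sum(resid * (tau - (resid < 0))))


# ------------------------------------------------------------ pre-fire bins

def bin_prefire(
    pairs: pd.DataFrame,
    event: int = 2,
    n_bins: int = 6,
) -> pd.DataFrame:
    """Median pre-fire state in (a_REL x b) quantile bins, per group and
    land-cover category.

    For the chosen event, both axes are cut into ``n_bins`` equal-quantile
    bins; every (category, group, a_rel bin, b bin) cell reports the median
    y_PRE-FIRE and its point count, and the best-populated cell of each
    stratum is flagged.
    """
    a_col, b_col, y_col = f"a_rel{event}", f"b{event}", f"y_pre{event}"
    df = pairs.dropna(subset=[a_col, b_col, y_col]).copy()
    if df.empty:
        return pd.DataFrame(
            columns=["landcover", "group", "a_rel_bin", "b_bin",
                     "median_y_pre", "n", "is_mode_bin"]
        )
    def _qcut(col):
        binned = pd.qcut(df[col], n_bins, duplicates="drop")
        if binned.isna().all():  # constant axis collapses to one bin
            v = df[col].iloc[0]
            iv = pd.Interval(v - 0.5, v + 0.5)
            return pd.Series(pd.Categorical([iv] * len(df)), index=df.index)
        return binned

    df["a_rel_bin"] = _qcut(a_col)
    df["b_bin"] = _qcut(b_col)
    keys = [k for k in ("landcover", "group") if k in df.columns]
    grouped = (
        df.groupby(keys + ["a_rel_bin", "b_bin"], observed=True)[y_col]
        .agg(median_y_pre="median", n="size")
        .reset_index()
    )
    grouped = grouped[grouped["n"] > 0].reset_index(drop=True)
    if keys:
        idx = grouped.groupby(keys, observed=True)["n"].transform("max")
        grouped["is_mode_bin"] = grouped["n"] == idx
    else:
        grouped["is_mode_bin"] = grouped["n"] == grouped["n"].max()
    return grouped
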