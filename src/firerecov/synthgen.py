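"""Synthetic scene generator with a known-truth ledger.

Emulates the data stack of the analysis — a MODIS-like 16-day EVI cube with
quality flags, monthly burned-area maps with burn-date uncertainty, a
UN-LCCS-coded land-cover map, and coarse monthly climate grids — so every
downstream stage can be validated against known ground truth.

Generative model per pixel
--------------------------
``EVI(t) = clamp01( seasonal(doy) + trend(t) + AR1 noise + fire term )``

The seasonal cycle is a cosine of the day-of-year peaking in the local
growing season.  After a fire in month ``t0`` the fire term is
``a_true * exp(-b_true * (t - t0))`` with ``t`` counted in whole calendar
months since the event month, so the monthly-aggregated loss series is an
exact exponential and the generative truth matches the recovery model's
functional form.  A second fire resets the term (the burn re-sets the
vegetation state), so both events carry exact (a, b) truths.

All pixels of a scene burn in the same two calendar months (a fire sweeps a
scene), while drop depth ``a`` and recovery rate ``b`` vary per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .config import SimConfig
from .containers import CATEGORY_TO_CODE, EviCube, LandCoverMap, QUALITY_GOOD, QUALITY_LOW
from .errors import ConfigError, DataError
from .timeaxis import composite_dates, month_dates, n_months, nominal_month_index

#: default fire-season months by hemisphere (Mediterranean-type regions)
DEFAULT_FIRE_SEASON = {
    "north": (6, 7, 8, 9, 10),
    "south": (12, 1, 2, 3, 4),
}

#: day-of-year of the seasonal greenness peak
_PEAK_DOY = {"north": 121, "south": 305}

# climate generator baselines (winter-wet Mediterranean regime)
_PRECIP_MEAN, _PRECIP_AMP, _PRECIP_SD = 70.0, 45.0, 12.0  # mm/month
_TEMP_MEAN, _TEMP_AMP, _TEMP_SD = 15.0, 8.0, 1.2          # degC


@dataclass
class TruthLedger:
    """Ground truth of a simulated scene.

    ``events`` has one row per pixel x fire event (true fire month, a, b,
    burn day-of-year, burn-date uncertainty); ``pixels`` one row per pixel
    (land-cover category, trend slope, seasonal parameters).
    """

    events: pd.DataFrame
    pixels: pd.DataFrame


@dataclass
class Scene:
    evi: EviCube
    burns: xr.Dataset
    landcover: LandCoverMap
    climate: xr.Dataset
    ledger: TruthLedger
    config: SimConfig


def _ar1_noise(rng, shape, sd, ar1):
    """Stationary AR(1) noise along the first axis."""
    n_t = shape[0]
    e = np.empty(shape)
    if sd == 0:
        e[:] = 0.0
        return e
    e[0] = rng.normal(0.0, sd, shape[1:])
    innov_sd = sd * np.sqrt(1.0 - ar1 ** 2)
    w = rng.normal(0.0, innov_sd, shape)
    for t in range(1, n_t):
        e[t] = ar1 * e[t - 1] + w[t]
    return e


def _sample_event_months(cfg: SimConfig, rng) -> list[int]:
    """Scene-level fire months (indexes since record start).

    Constraints: in the fire season; >= 36 months of pre-fire record before
    the first event (Gorgeous-Year and pre-fire-state context); >= 24 months
    of record after the last event (shortest fit window); for two events a
    gap inside ``event_gap_range``.
    """
    if cfg.events_per_pixel == 0:
        return []
    season = set(cfg.fire_season_months or DEFAULT_FIRE_SEASON[cfg.hemisphere])
    total = n_months(cfg.start_year, cfg.end_year)
    in_season = [m for m in range(total) if (m % 12) + 1 in season]
    first_ok = [m for m in in_season if m >= 36]
    if cfg.events_per_pixel == 1:
        cands = [m for m in first_ok if m <= total - 1 - 24]
        if not cands:
            raise ConfigError("end_year", "record too short to place a fire event")
        return [int(rng.choice(cands))]
    lo, hi = cfg.event_gap_range
    pairs = [
        (m1, m2)
        for m1 in first_ok
        for m2 in in_season
        if lo <= m2 - m1 <= hi and m2 <= total - 1 - 24
    ]
    if not pairs:
        raise ConfigError("event_gap_range", "no feasible in-season event pair")
    m1, m2 = pairs[int(rng.integers(len(pairs)))]
    return [int(m1), int(m2)]


def simulate_scene(config: SimConfig) -> Scene:
    """Generate one synthetic scene plus its truth ledger.

    Identical configs (including the seed) produce bit-identical scenes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nr, nc = cfg.grid_rows, cfg.grid_cols
    npix = nr * nc

    dates = composite_dates(cfg.start_year, cfg.end_year)
    doy = dates.dayofyear.to_numpy()
    # nominal-calendar month per composite: matches the monthly aggregation
    # binning exactly, in leap years too
    comp_month = nominal_month_index(dates, cfg.start_year)
    n_t = len(dates)
    total_months = n_months(cfg.start_year, cfg.end_year)

    # --- per-pixel static parameters -----------------------------------
    mean_jitter = rng.uniform(-0.02, 0.02, npix)
    seas_mean = np.clip(
        cfg.seasonal_mean + mean_jitter,
        cfg.seasonal_amplitude,
        1.0 - cfg.seasonal_amplitude,
    )
    peak = _PEAK_DOY[cfg.hemisphere]
    categories = np.asarray(cfg.landcover_categories)[
        rng.integers(len(cfg.landcover_categories), size=npix)
    ]

    # --- undisturbed series --------------------------------------------
    seasonal = seas_mean[None, :] + cfg.seasonal_amplitude * np.cos(
        2 * np.pi * (doy[:, None] - peak) / 365.25
    )
    years_since = (dates - dates[0]).days.to_numpy() / 365.25
    trend = cfg.trend_slope * years_since[:, None]
    noise = _ar1_noise(rng, (n_t, npix), cfg.noise_sd, cfg.ar1_coeff)

    # --- fire events -----------------------------------------------------
    event_months = _sample_event_months(cfg, rng)
    n_ev = len(event_months)
    a_true = rng.uniform(cfg.a_true_range[0], cfg.a_true_range[1], (n_ev, npix))
    b_true = rng.uniform(cfg.b_true_range[0], cfg.b_true_range[1], (n_ev, npix))

    fire = np.zeros((n_t, npix))
    for k, t0 in enumerate(event_months):
        t_end = event_months[k + 1] if k + 1 < n_ev else total_months + 1
        sel = (comp_month >= t0) & (comp_month < t_end)
        dm = (comp_month[sel] - t0)[:, None].astype(float)
        fire[sel] = a_true[k][None, :] * np.exp(-b_true[k][None, :] * dm)

    evi = np.clip(seasonal + trend + noise + fire, 0.0, 1.0)

    # --- cloud / quality flags -------------------------------------------
    quality = np.full((n_t, npix), QUALITY_GOOD, dtype="int8")
    if cfg.cloud_fraction > 0:
        low = rng.random((n_t, npix)) < cfg.cloud_fraction
        quality[low] = QUALITY_LOW
        evi = np.where(low, evi * rng.uniform(0.2, 0.7, (n_t, npix)), evi)

    coords = {"time": dates, "row": np.arange(nr), "col": np.arange(nc)}
    cube = EviCube(
        data=xr.DataArray(
            evi.reshape(n_t, nr, nc), coords=coords, dims=("time", "row", "col"),
            name="evi",
        ),
        quality=xr.DataArray(
            quality.reshape(n_t, nr, nc), coords=coords, dims=("time", "row", "col"),
            name="quality",
        ),
        state="raw",
    )

    # --- burned-area maps -------------------------------------------------
    mdates = month_dates(cfg.start_year, cfg.end_year)
    burn_doy = np.zeros((total_months, npix), dtype="int32")
    burn_unc = np.zeros((total_months, npix), dtype="int32")
    event_rows = []
    ulo, uhi = cfg.burn_uncertainty_range
    for k, t0 in enumerate(event_months):
        mstart = mdates[t0]
        day_off = rng.integers(0, 28, npix)
        unc = rng.integers(ulo, uhi + 1, npix)
        bdoy = (mstart.dayofyear + day_off).astype("int32")
        burn_doy[t0] = bdoy
        burn_unc[t0] = unc
        for p in range(npix):
            event_rows.append(
                {
                    "pixel_id": p,
                    "row": p // nc,
                    "col": p % nc,
                    "event": k + 1,
                    "fire_month_idx": t0,
                    "fire_date": mstart,
                    "a_true": a_true[k, p],
                    "b_true": b_true[k, p],
                    "burn_doy": int(bdoy[p]),
                    "uncertainty_days": int(unc[p]),
                }
            )
    burns = xr.Dataset(
        {
            "burn_doy": xr.DataArray(
                burn_doy.reshape(total_months, nr, nc),
                coords={"time": mdates, "row": np.arange(nr), "col": np.arange(nc)},
                dims=("time", "row", "col"),
            ),
            "uncertainty_days": xr.DataArray(
                burn_unc.reshape(total_months, nr, nc),
                coords={"time": mdates, "row": np.arange(nr), "col": np.arange(nc)},
                dims=("time", "row", "col"),
            ),
        }
    )

    # --- land cover --------------------------------------------------------
    codes = np.vectorize(CATEGORY_TO_CODE.get)(categories).astype("int32")
    landcover = LandCoverMap(
        codes=xr.DataArray(codes.reshape(nr, nc), dims=("row", "col"))
    )

    # --- climate grids ------------------------------------------------------
    climate = _simulate_climate(cfg, rng, event_months, mdates)

    pixels = pd.DataFrame(
        {
            "pixel_id": np.arange(npix),
            "row": np.arange(npix) // nc,
            "col": np.arange(npix) % nc,
            "landcover": categories,
            "trend_slope": cfg.trend_slope,
            "seasonal_mean": seas_mean,
            "seasonal_amplitude": cfg.seasonal_amplitude,
        }
    )
    events = (
        pd.DataFrame(event_rows)
        if event_rows
        else pd.DataFrame(
            columns=[
                "pixel_id", "row", "col", "event", "fire_month_idx", "fire_date",
                "a_true", "b_true", "burn_doy", "uncertainty_days",
            ]
        )
    )
    return Scene(
        evi=cube,
        burns=burns,
        landcover=landcover,
        climate=climate,
        ledger=TruthLedger(events=events, pixels=pixels),
        config=cfg,
    )


def _simulate_climate(cfg: SimConfig, rng, event_months, mdates) -> xr.Dataset:
    """Monthly precipitation/temperature on a coarse grid.

    Anomalies requested in ``climate_anomaly_spec`` are injected into the
    four quarters following each fire event, scaled so that the *seasonal
    aggregate* (precipitation summed, temperature averaged over a 3-month
    season) shifts by the requested number of climatological standard
    deviations.
    """
    cell = cfg.climate_cell_size
    crows = -(-cfg.grid_rows // cell)
    ccols = -(-cfg.grid_cols // cell)
    n_m = len(mdates)
    month_of_year = mdates.month.to_numpy()

    if cfg.hemisphere == "north":
        precip_peak, temp_peak = 1, 7
    else:
        precip_peak, temp_peak = 7, 1
    precip_clim = _PRECIP_MEAN + _PRECIP_AMP * np.cos(
        2 * np.pi * (month_of_year - precip_peak) / 12
    )
    temp_clim = _TEMP_MEAN + _TEMP_AMP * np.cos(
        2 * np.pi * (month_of_year - temp_peak) / 12
    )

    shape = (n_m, crows, ccols)
    precip = precip_clim[:, None, None] + rng.normal(0, _PRECIP_SD, shape)
    temp = temp_clim[:, None, None] + rng.normal(0, _TEMP_SD, shape)

    # inject post-fire quarter anomalies (in seasonal-aggregate z units)
    spec = cfg.climate_anomaly_spec
    sd_agg_temp = _TEMP_SD / np.sqrt(3.0)      # mean of 3 iid months
    sd_agg_precip = _PRECIP_SD * np.sqrt(3.0)  # sum of 3 iid months
    for t0 in event_months:
        for q in range(4):
            months = np.arange(t0 + 1 + 3 * q, t0 + 4 + 3 * q)
            months = months[months < n_m]
            if "temperature" in spec:
                temp[months] += spec["temperature"][q] * sd_agg_temp
            if "precipitation" in spec:
                precip[months] += spec["precipitation"][q] * sd_agg_precip / 3.0

    precip = np.clip(precip, 0.0, None)
    crow_centers = (np.arange(crows) + 0.5) * cell - 0.5
    ccol_centers = (np.arange(ccols) + 0.5) * cell - 0.5
    ds = xr.Dataset(
        {
            "precipitation": (("time", "crow", "ccol"), precip),
            "temperature": (("time", "crow", "ccol"), temp),
        },
        coords={"time": mdates, "crow": crow_centers, "ccol": ccol_centers},
        attrs={"hemisphere": cfg.hemisphere, "cell_size": cell},
    )
    return ds


# --------------------------------------------------------------------------
# event-level cohorts (loss-series space)
# --------------------------------------------------------------------------

def simulate_loss_cohort(
    n_pixels: int,
    n_months: int = 72,
    a_range: tuple[float, float] = (-0.5, -0.2),
    b_range: tuple[float, float] = (0.03, 0.12),
    noise_sd: float = 0.02,
    ar1: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Monthly loss-of-greenness series for ``n_pixels`` independent events.

    Each row is ``y(t) = a e^{-b t} + noise`` for t = 0..n_months-1, the
    direct generative counterpart of the recovery model; used for
    estimator-level Monte-Carlo experiments where the drop depth and rate
    must be controlled exactly per event.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(a_range[0], a_range[1], n_pixels)
    b = rng.uniform(b_range[0], b_range[1], n_pixels)
    t = np.arange(n_months)
    clean = a[:, None] * np.exp(-b[:, None] * t[None, :])
    noise = _ar1_noise(rng, (n_months, n_pixels), noise_sd, ar1).T
    truth = pd.DataFrame({"pixel_id": np.arange(n_pixels), "a_true": a, "b_true": b})
    return clean + noise, truth


def simulate_pair_cohort(
    n_pixels: int,
    delta_b: float = 0.0,
    n_months: int = 72,
    a_range: tuple[float, float] = (-0.5, -0.2),
    b1_range: tuple[float, float] = (0.03, 0.12),
    noise_sd: float = 0.02,
    ar1: float = 0.0,
    landcover: str = "NL",
    seed: int = 0,
) -> dict:
    """Paired-event cohort with an injected recovery-rate difference.

    The second event of every pixel recovers at ``b2 = b1 + delta_b`` from
    an independently drawn drop depth; observation noise is independent
    between events.  Mirrors the event-contrast experiment design.
    """
    rng = np.random.default_rng(seed)
    a1 = rng.uniform(a_range[0], a_range[1], n_pixels)
    a2 = rng.uniform(a_range[0], a_range[1], n_pixels)
    b1 = rng.uniform(b1_range[0], b1_range[1], n_pixels)
    b2 = b1 + delta_b
    t = np.arange(n_months)
    y1 = a1[:, None] * np.exp(-b1[:, None] * t) + _ar1_noise(
        rng, (n_months, n_pixels), noise_sd, ar1
    ).T
    y2 = a2[:, None] * np.exp(-b2[:, None] * t) + _ar1_noise(
        rng, (n_months, n_pixels), noise_sd, ar1
    ).T
    truth = pd.DataFrame(
        {
            "pixel_id": np.arange(n_pixels),
            "a1_true": a1, "a2_true": a2,
            "b1_true": b1, "b2_true": b2,
            "landcover": landcover,
        }
    )
    return {"y1": y1, "y2": y2, "truth": truth}


# --------------------------------------------------------------------------
# scene I/O
# --------------------------------------------------------------------------

_FILES = {
    "evi": "evi.nc",
    "burns": "burns.nc",
    "landcover": "landcover.nc",
    "climate": "climate.nc",
    "events": "ledger_events.csv",
    "pixels": "ledger_pixels.csv",
    "config": "simconfig.yaml",
}


def write_scene(scene: Scene, directory) -> dict[str, Path]:
    """Persist a scene as NetCDF cubes + CSV ledger + YAML config."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        probe = d / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"cannot write to directory {d}: {exc}") from exc
    paths = {k: d / v for k, v in _FILES.items()}
    scene.evi.to_netcdf(paths["evi"])
    scene.burns.to_netcdf(paths["burns"], engine="scipy")
    scene.landcover.to_netcdf(paths["landcover"])
    scene.climate.to_netcdf(paths["climate"], engine="scipy")
    scene.ledger.events.to_csv(paths["events"], index=False)
    scene.ledger.pixels.to_csv(paths["pixels"], index=False)
    scene.config.to_yaml(paths["config"])
    return paths


def read_scene(directory) -> Scene:
    d = Path(directory)
    for key in _FILES.values():
        if not (d / key).exists():
            raise DataError(f"scene directory {d} is missing {key}")
    with xr.open_dataset(d / _FILES["burns"], engine="scipy") as ds:
        burns = ds.load()
    with xr.open_dataset(d / _FILES["climate"], engine="scipy") as ds:
        climate = ds.load()
    events = pd.read_csv(d / _FILES["events"], parse_dates=["fire_date"])
    pixels = pd.read_csv(d / _FILES["pixels"])
    return Scene(
        evi=EviCube.open(d / _FILES["evi"]),
        burns=burns,
        landcover=LandCoverMap.open(d / _FILES["landcover"]),
        climate=climate,
        ledger=TruthLedger(events=events, pixels=pixels),
        config=SimConfig.from_yaml(d / _FILES["config"]),
    )
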