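"""End-to-end orchestration: simulate -> preprocess -> detect fires ->
fit recovery -> modulation -> climate, with a machine-readable run report.

Every intermediate product is persisted under the configured output
directory; the report records effective parameters and per-stage counts so
a run can be audited and reproduced (identical config and seed give
identical outputs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as clim
from . import firehist, modulation, preprocess, recovery, synthgen
from .config import RunConfig
from .containers import EviCube

log = logging.getLogger("firerecov")


@dataclass
class RunResult:
    monthly: EviCube
    gy: recovery.GorgeousYear
    fits: pd.DataFrame
    pairs: pd.DataFrame
    groups: pd.DataFrame
    wilcoxon: pd.DataFrame
    quantile_fits: pd.DataFrame
    prefire_bins: pd.DataFrame
    climate_profiles: pd.DataFrame
    climate_groups: pd.DataFrame
    report: dict = field(default_factory=dict)


def preprocess_cube(cube: EviCube, cfg: RunConfig) -> EviCube:
    """Run the preprocessing chain with the configured stages."""
    out = preprocess.fill_low_quality(cube)
    log.info("fill: %d pixels masked", int(out.mask.sum()) if out.mask is not None else 0)
    if cfg.apply_smoothing:
        out = preprocess.fft_smooth(out, cfg.keep_period_months)
    else:
        out = preprocess.advance_state(out, "smoothed")
    if cfg.apply_detrending:
        out = preprocess.loess_detrend(out, cfg.loess_span)
    else:
        out = preprocess.advance_state(out, "detrended")
    return preprocess.monthly_aggregate(out)


def run_pipeline(cfg: RunConfig, scene: synthgen.Scene | None = None) -> RunResult:
    """Execute the full analysis on a (simulated or supplied) scene."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": _jsonable(asdict(cfg)), "stages": {}}

    # --- stage 1: scene -----------------------------------------------------
    if scene is None:
        scene = synthgen.simulate_scene(cfg.sim)
    synthgen.write_scene(scene, out_dir / "scene")
    nr, nc = cfg.sim.grid_rows, cfg.sim.grid_cols
    n_pixels = nr * nc
    report["stages"]["simulate"] = {
        "pixels": n_pixels,
        "composites": int(scene.evi.data.sizes["time"]),
        "events": int(len(scene.ledger.events)),
    }
    log.info("scene: %dx%d pixels, %d events", nr, nc, len(scene.ledger.events))

    # --- stage 2: preprocessing ----------------------------------------------
    monthly = preprocess_cube(scene.evi, cfg)
    monthly.to_netcdf(out_dir / "monthly.nc")
    report["stages"]["preprocess"] = {
        "monthly_steps": int(monthly.data.sizes["time"]),
        "masked_pixels": int(monthly.mask.sum()) if monthly.mask is not None else 0,
    }

    # --- stage 3: fire histories ----------------------------------------------
    season = firehist.REGION_SEASONS[cfg.region]
    events = firehist.events_from_burn_maps(scene.burns, cfg.sim.start_year)
    n_events_raw = len(events)
    events = firehist.filter_burn_uncertainty(events, cfg.max_uncertainty_days)
    n_unc_removed = n_events_raw - len(events)
    events = firehist.flag_in_season(events, season)
    counts, freq_table = firehist.fire_frequency(events, (nr, nc))
    n_record_months = 12 * cfg.sim.n_years
    pairs_cand, exclusions = firehist.select_twice_burned(
        events, n_record_months, cfg.min_gap_months, cfg.min_tail_months
    )
    pixels_with_events = events["pixel_id"].nunique()
    excl_counts = exclusions["rule"].value_counts().to_dict() if len(exclusions) else {}
    report["stages"]["firehist"] = {
        "events_in": n_events_raw,
        "events_removed_uncertainty": n_unc_removed,
        "pixels_with_events": int(pixels_with_events),
        "pixels_no_fire": int(n_pixels - pixels_with_events),
        "excluded_by_rule": {k: int(v) for k, v in excl_counts.items()},
        "pair_candidates": int(len(pairs_cand)),
    }
    freq_table.to_csv(out_dir / "fire_frequency.csv", index=False)
    pairs_cand.to_csv(out_dir / "pair_candidates.csv", index=False)

    # --- stage 4: recovery fits --------------------------------------------
    gy = recovery.compute_gorgeous_year(monthly)
    loss = recovery.loss_series(monthly, gy)
    lc = preprocess.aggregate_landcover(scene.landcover)
    lc_series = pd.Series(
        lc.categories.values.reshape(-1), index=np.arange(n_pixels), name="landcover"
    )
    fits = recovery.fit_events(
        loss, gy, pairs_cand, landcover=lc_series,
        search_months=cfg.severity_search_months, windows=cfg.fit_windows,
        r2_min=cfg.r2_min, fit_intercept=cfg.fit_intercept,
        se_method=cfg.se_method,
    )
    fits.to_csv(out_dir / "fits.csv", index=False)
    n_valid = int(fits["valid"].fillna(False).sum()) if len(fits) else 0
    report["stages"]["recovery"] = {
        "fits": int(len(fits)),
        "valid_fits": n_valid,
    }

    # --- stage 5: modulation --------------------------------------------------
    pairs = modulation.pair_events(fits, cfg.validity_rule)
    groups = modulation.select_extreme_diffs(pairs, *cfg.iqr_bounds)
    wilc_rows = []
    for cat, grp in pairs.groupby("landcover") if "landcover" in pairs else []:
        if len(grp) >= 5:
            res = modulation.wilcoxon_signed_rank(grp["b_diff"].to_numpy())
            wilc_rows.append(
                {"landcover": cat, "n": res.n_nonzero, "statistic": res.statistic,
                 "p_value": res.p_value, "method": res.method,
                 "median_b_diff": float(grp["b_diff"].median())}
            )
    if len(pairs) >= 5:
        res = modulation.wilcoxon_signed_rank(pairs["b_diff"].to_numpy())
        wilc_rows.append(
            {"landcover": "ALL", "n": res.n_nonzero, "statistic": res.statistic,
             "p_value": res.p_value, "method": res.method,
             "median_b_diff": float(pairs["b_diff"].median())}
        )
    wilcoxon = pd.DataFrame(wilc_rows)
    qr_rows = []
    x = np.concatenate([pairs["a_rel1"].to_numpy(), pairs["a_rel2"].to_numpy()])
    y = np.concatenate([pairs["b1"].to_numpy(), pairs["b2"].to_numpy()])
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() >= 20:
        for tau in cfg.taus:
            qf = modulation.quantile_regression(x[ok], y[ok], tau)
            qr_rows.append(asdict(qf))
    quantile_fits = pd.DataFrame(qr_rows)
    bins = pd.concat(
        [modulation.bin_prefire(groups, event=e, n_bins=cfg.n_bins).assign(event=e)
         for e in (1, 2)],
        ignore_index=True,
    ) if len(groups) else pd.DataFrame()
    pairs.to_csv(out_dir / "pairs.csv", index=False)
    groups.to_csv(out_dir / "groups.csv", index=False)
    wilcoxon.to_csv(out_dir / "wilcoxon.csv", index=False)
    quantile_fits.to_csv(out_dir / "quantile_fits.csv", index=False)
    bins.to_csv(out_dir / "prefire_bins.csv", index=False)
    report["stages"]["modulation"] = {
        "pairs": int(len(pairs)),
        "excluded_poor_fit": int(len(pairs_cand) - len(pairs)),
        "group_sizes": groups["group"].value_counts().to_dict() if len(groups) else {},
    }

    # --- stage 6: climate -----------------------------------------------------
    climatology = clim.seasonal_climatology(scene.climate)
    zmonthly = clim.seasonal_z(scene.climate, climatology)
    ev_rows = []
    for rec in pairs.itertuples(index=False):
        for event, m in ((1, rec.e1_month_idx), (2, rec.e2_month_idx)):
            ev_rows.append({"pixel_id": rec.pixel_id, "event": event,
                            "row": rec.row, "col": rec.col, "fire_month_idx": m})
    profiles = (
        clim.postfire_profile(zmonthly, pd.DataFrame(ev_rows), cfg.sim.start_year)
        if ev_rows else pd.DataFrame(columns=["pixel_id", "event", "variable",
                                              "quarter", "z"])
    )
    climate_groups = (
        clim.group_anomalies(profiles, groups) if len(profiles) else pd.DataFrame()
    )
    profiles.to_csv(out_dir / "climate_profiles.csv", index=False)
    climate_groups.to_csv(out_dir / "climate_groups.csv", index=False)
    report["stages"]["climate"] = {"profiles": int(len(profiles))}

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return RunResult(
        monthly=monthly, gy=gy, fits=fits, pairs=pairs, groups=groups,
        wilcoxon=wilcoxon, quantile_fits=quantile_fits, prefire_bins=bins,
        climate_profiles=profiles, climate_groups=climate_groups, report=report,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
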