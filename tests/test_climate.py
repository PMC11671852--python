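"""Seasonal climatology, standardized anomalies and post-fire profiles."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from firerecov import SimConfig, simulate_scene
from firerecov.climate import (
    group_anomalies,
    postfire_profile,
    season_local_name,
    seasonal_climatology,
    seasonal_z,
    standardized_anomaly,
)


def _series(temp=None, precip=None, start="2001-01", n=264, hemisphere="north"):
    time = pd.date_range(start, periods=n, freq="MS")
    data = {}
    if temp is not None:
        data["temperature"] = (("time", "crow", "ccol"),
                               np.asarray(temp).reshape(n, 1, 1))
    if precip is not None:
        data["precipitation"] = (("time", "crow", "ccol"),
                                 np.asarray(precip).reshape(n, 1, 1))
    return xr.Dataset(data, coords={"time": time, "crow": [0.0], "ccol": [0.0]},
                      attrs={"hemisphere": hemisphere, "cell_size": 1})


class TestSeasonalClimatology:
    def test_constant_temperature_is_degenerate(self):
        series = _series(temp=np.full(264, 15.0))
        with pytest.warns(UserWarning, match="degenerate"):
            clim = seasonal_climatology(series)
        np.testing.assert_allclose(clim["temperature_mean"].values, 15.0)
        np.testing.assert_allclose(clim["temperature_sd"].values, 0.0)
        assert clim["temperature_degenerate"].values.all()

    def test_alternating_years_match_direct_instance_computation(self):
        # +1 degC in even years, -1 in odd years
        years = np.repeat(np.arange(22), 12)
        temp = 15.0 + np.where(years % 2 == 0, 1.0, -1.0)
        clim = seasonal_climatology(_series(temp=temp))
        # oracle: build the season instances directly and aggregate
        time = pd.date_range("2001-01", periods=264, freq="MS")
        df = pd.DataFrame({"t": temp, "m": time.month, "y": time.year})
        df["season"] = df.m.map({12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM",
                                 4: "MAM", 5: "MAM", 6: "JJA", 7: "JJA",
                                 8: "JJA", 9: "SON", 10: "SON", 11: "SON"})
        df["iy"] = np.where(df.m == 12, df.y + 1, df.y)
        inst = df.groupby(["season", "iy"]).filter(lambda g: len(g) == 3)
        agg = inst.groupby(["season", "iy"])["t"].mean()
        for season in ("DJF", "MAM", "JJA", "SON"):
            vals = agg.loc[season]
            assert clim["temperature_mean"].sel(season=season).values[0, 0] == (
                pytest.approx(vals.mean())
            )
            assert clim["temperature_sd"].sel(season=season).values[0, 0] == (
                pytest.approx(vals.std(ddof=1))
            )

    def test_pure_seasonal_precipitation_matches_generator_sums(self):
        months = pd.date_range("2001-01", periods=264, freq="MS").month
        precip = 70.0 + 45.0 * np.cos(2 * np.pi * (months - 1) / 12)
        with pytest.warns(UserWarning, match="degenerate"):
            clim = seasonal_climatology(_series(precip=precip))
        # JJA sum: months 6,7,8 of the cosine climatology
        expected = sum(70.0 + 45.0 * np.cos(2 * np.pi * (m - 1) / 12)
                       for m in (6, 7, 8))
        assert clim["precipitation_mean"].sel(season="JJA").values[0, 0] == (
            pytest.approx(expected)
        )


class TestStandardizedAnomaly:
    def test_aggregate_at_the_mean_is_zero(self):
        assert standardized_anomaly(10.0, 10.0, 2.0) == 0.0

    def test_one_sd_above_the_mean_is_one(self):
        assert standardized_anomaly(12.0, 10.0, 2.0) == pytest.approx(1.0)

    def test_degenerate_sd_is_masked(self):
        assert np.isnan(standardized_anomaly(10.0, 10.0, 0.0))

    def test_idempotent_in_expectation(self):
        rng = np.random.default_rng(14)
        temp = 15.0 + rng.normal(0, 2, 264)
        series = _series(temp=temp)
        clim = seasonal_climatology(series)
        z1 = seasonal_z(series, clim)
        z_series = _series(temp=np.nan_to_num(z1["temperature_z"].values[:, 0, 0]))
        clim2 = seasonal_climatology(z_series)
        z_mean = clim2["temperature_mean"].values
        z_sd = clim2["temperature_sd"].values
        assert np.abs(z_mean).max() < 0.3
        assert np.abs(z_sd - 1).max() < 0.3

    def test_temperature_location_shift_leaves_z_unchanged(self):
        rng = np.random.default_rng(15)
        temp = 15.0 + rng.normal(0, 2, 264)
        s1, s2 = _series(temp=temp), _series(temp=temp + 7.5)
        z1 = seasonal_z(s1, seasonal_climatology(s1))
        z2 = seasonal_z(s2, seasonal_climatology(s2))
        np.testing.assert_allclose(z1["temperature_z"].values,
                                   z2["temperature_z"].values, atol=1e-10)

    def test_injected_generator_offset_is_recovered(self):
        # an August fire aligns Q1..Q4 with SON, DJF, MAM, JJA exactly
        cfg = SimConfig(
            grid_rows=16, grid_cols=16, seed=17, events_per_pixel=1,
            fire_season_months=(8,),
            climate_anomaly_spec={"precipitation": [0.0, 2.0, 0.0, 0.0],
                                  "temperature": [0.0, 0.0, -2.0, 0.0]},
        )
        scene = simulate_scene(cfg)
        clim = seasonal_climatology(scene.climate)
        z = seasonal_z(scene.climate, clim)
        ev = scene.ledger.events.copy()  # one row per pixel, 16 climate cells
        profiles = postfire_profile(z, ev, cfg.start_year)
        mean_z = profiles.groupby(["variable", "quarter"])["z"].mean()
        # recovered within sampling noise of a 22-instance climatology
        assert mean_z["precipitation", "Q2"] == pytest.approx(2.0, abs=0.7)
        assert mean_z["temperature", "Q3"] == pytest.approx(-2.0, abs=0.7)
        assert abs(mean_z["precipitation", "Q4"]) < 0.7
        assert abs(mean_z["temperature", "Q1"]) < 0.7


class TestPostfireProfile:
    def _z_dataset(self, z_values):
        time = pd.date_range("2001-01", periods=264, freq="MS")
        return xr.Dataset(
            {"temperature_z": (("time", "crow", "ccol"),
                               np.asarray(z_values).reshape(264, 1, 1))},
            coords={"time": time, "crow": [1.5], "ccol": [1.5]},
        )

    def test_uniform_z_gives_unit_quarters(self):
        z = self._z_dataset(np.ones(264))
        ev = pd.DataFrame([{"pixel_id": 0, "event": 1, "row": 0, "col": 0,
                            "fire_month_idx": 100}])
        profiles = postfire_profile(z, ev, 2001)
        assert (profiles["z"] == 1.0).all()
        assert sorted(profiles["quarter"]) == ["Q1", "Q2", "Q3", "Q4"]

    def test_anomaly_lands_in_the_right_quarter(self):
        # fire in August (month idx 7): local spring (MAM next year) covers
        # post-fire months 7..9 -> quarter Q3
        zvals = np.zeros(264)
        time = pd.date_range("2001-01", periods=264, freq="MS")
        in_spring_2002 = (time.year == 2002) & time.month.isin([3, 4, 5])
        zvals[in_spring_2002] = 2.0
        z = self._z_dataset(zvals)
        ev = pd.DataFrame([{"pixel_id": 0, "event": 1, "row": 0, "col": 0,
                            "fire_month_idx": 7}])
        profiles = postfire_profile(z, ev, 2001).set_index("quarter")
        assert profiles.loc["Q3", "z"] == pytest.approx(2.0)
        assert profiles.loc["Q1", "z"] == 0.0
        assert profiles.loc["Q2", "z"] == 0.0
        assert profiles.loc["Q4", "z"] == 0.0

    def test_short_tail_masks_missing_quarters(self):
        z = self._z_dataset(np.ones(264))
        ev = pd.DataFrame([{"pixel_id": 0, "event": 2, "row": 0, "col": 0,
                            "fire_month_idx": 260}])
        profiles = postfire_profile(z, ev, 2001).set_index("quarter")
        assert profiles.loc["Q1", "z"] == 1.0
        assert np.isnan(profiles.loc["Q3", "z"])
        assert np.isnan(profiles.loc["Q4", "z"])

    def test_hemisphere_changes_labels_not_values(self):
        assert season_local_name("DJF", "north") == "winter"
        assert season_local_name("DJF", "south") == "summer"
        assert season_local_name("SON", "south") == "spring"


class TestGroupAnomalies:
    def _profiles(self, pixel_ids, z):
        rows = []
        for pid in pixel_ids:
            for q in range(4):
                rows.append({"pixel_id": pid, "event": 1,
                             "variable": "precipitation",
                             "quarter": f"Q{q + 1}", "z": z[pid]})
        return pd.DataFrame(rows)

    def test_single_pixel_group_reports_its_own_profile(self):
        profiles = self._profiles([0], {0: 1.5})
        groups = pd.DataFrame([{"pixel_id": 0, "group": "b1_lt_b2",
                                "landcover": "NL"}])
        out = group_anomalies(profiles, groups)
        assert (out["mean_z"] == 1.5).all()
        assert (out["n"] == 1).all()

    def test_opposite_sign_offsets_produce_opposite_means(self):
        profiles = self._profiles([0, 1], {0: 1.0, 1: -1.0})
        groups = pd.DataFrame([
            {"pixel_id": 0, "group": "b1_lt_b2", "landcover": "NL"},
            {"pixel_id": 1, "group": "b1_gt_b2", "landcover": "NL"},
        ])
        out = group_anomalies(profiles, groups).set_index("group")
        assert (out.loc["b1_lt_b2", "mean_z"] > 0).all()
        assert (out.loc["b1_gt_b2", "mean_z"] < 0).all()

    def test_counts_sum_to_group_sizes_per_cell(self):
        profiles = self._profiles([0, 1, 2], {0: 1.0, 1: 0.5, 2: -1.0})
        groups = pd.DataFrame([
            {"pixel_id": 0, "group": "b1_lt_b2", "landcover": "NL"},
            {"pixel_id": 1, "group": "b1_lt_b2", "landcover": "NL"},
            {"pixel_id": 2, "group": "b1_gt_b2", "landcover": "NL"},
        ])
        out = group_anomalies(profiles, groups)
        sizes = out.groupby("group")["n"].unique()
        assert list(sizes["b1_lt_b2"]) == [2]
        assert list(sizes["b1_gt_b2"]) == [1]
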