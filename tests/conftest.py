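"""Shared fixtures: small synthetic scenes and their monthly products."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from firerecov import SimConfig, simulate_scene, compute_gorgeous_year, loss_series
from firerecov.config import RunConfig
from firerecov.containers import EviCube
from firerecov.pipeline import preprocess_cube
from firerecov.timeaxis import composite_dates


def make_cube(values: np.ndarray, dates, state="raw", quality=None) -> EviCube:
    """Build an EviCube from a (time, row, col) array."""
    values = np.asarray(values, dtype=float)
    coords = {
        "time": pd.DatetimeIndex(dates),
        "row": np.arange(values.shape[1]),
        "col": np.arange(values.shape[2]),
    }
    q = None
    if quality is not None:
        q = xr.DataArray(np.asarray(quality, dtype="int8"), coords=coords,
                         dims=("time", "row", "col"))
    return EviCube(
        data=xr.DataArray(values, coords=coords, dims=("time", "row", "col")),
        quality=q, state=state,
    )


def monthly_cube(values: np.ndarray, start_year=2001) -> EviCube:
    """Monthly-state cube from a (12*n_years, rows, cols) array."""
    n = values.shape[0]
    assert n % 12 == 0
    dates = pd.date_range(f"{start_year}-01-01", periods=n, freq="MS")
    return make_cube(values, dates, state="monthly")


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig(
        grid_rows=4, grid_cols=4, noise_sd=0.0, cloud_fraction=0.0,
        ar1_coeff=0.0, trend_slope=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    return simulate_scene(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_monthly(noiseless_scene):
    cfg = RunConfig(apply_smoothing=False, apply_detrending=False)
    return preprocess_cube(noiseless_scene.evi, cfg)


@pytest.fixture(scope="session")
def noiseless_loss(noiseless_monthly):
    gy = compute_gorgeous_year(noiseless_monthly)
    return loss_series(noiseless_monthly, gy), gy


@pytest.fixture(scope="session")
def noisy_scene():
    return simulate_scene(SimConfig(grid_rows=6, grid_cols=6, seed=3))


@pytest.fixture(scope="session")
def composite_axis():
    return composite_dates(2001, 2022)
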