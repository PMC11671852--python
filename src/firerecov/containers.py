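"""Gridded containers: the EVI cube with its processing-state tag, and the
land-cover map.

The cube's ``state`` records where it sits in the fixed preprocessing chain
``raw -> gapfilled -> smoothed -> detrended -> monthly``.  Every operation
asserts the exact state it requires, so a step can neither be skipped
silently nor applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .errors import DataError, StateError

#: ordered processing states of an EVI cube
STATES = ("raw", "gapfilled", "smoothed", "detrended", "monthly")

QUALITY_GOOD = 0
QUALITY_LOW = 1

# UN-LCCS 37-class codes aggregated to the eight analysis categories.
# Forest classes by leaf type, shrub/grass/crop mosaics, and everything
# from sparse vegetation to bare/urban/water lumped into "Oth".
LANDCOVER_CATEGORIES = ("BL", "NL", "MF", "Shb", "TW", "Gs", "Cp", "Oth")

_CODE_TO_CATEGORY: dict[int, str] = {}
for _code in (50, 60, 61, 62):
    _CODE_TO_CATEGORY[_code] = "BL"
for _code in (70, 71, 72, 80, 81, 82):
    _CODE_TO_CATEGORY[_code] = "NL"
_CODE_TO_CATEGORY[90] = "MF"
for _code in (40, 110, 120, 121, 122):
    _CODE_TO_CATEGORY[_code] = "Shb"
_CODE_TO_CATEGORY[100] = "TW"
_CODE_TO_CATEGORY[130] = "Gs"
for _code in (10, 11, 12, 20, 30):
    _CODE_TO_CATEGORY[_code] = "Cp"
for _code in (140, 150, 151, 152, 153, 160, 170, 180, 190, 200, 201, 202, 210, 220):
    _CODE_TO_CATEGORY[_code] = "Oth"

#: one representative UN-LCCS code per category (used by the generator)
CATEGORY_TO_CODE = {
    "BL": 50, "NL": 70, "MF": 90, "Shb": 120, "TW": 100,
    "Gs": 130, "Cp": 10, "Oth": 150,
}


@dataclass
class EviCube:
    """Vegetation-index cube on (time, row, col) with per-observation quality.

    Parameters
    ----------
    data
        EVI values in [0, 1]; NaN only for pixels under ``mask``.
    quality
        Per-observation flag, 0 = good, 1 = low quality.  Present on raw
        cubes, optional afterwards.
    state
        Processing state, one of :data:`STATES`.
    mask
        Boolean (row, col) array marking pixels excluded from analysis
        (e.g. fewer than 4 good observations over the record).
    """

    data: xr.DataArray
    quality: xr.DataArray | None = None
    state: str = "raw"
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.state not in STATES:
            raise StateError(f"unknown cube state '{self.state}'")
        t = self.data.coords["time"].to_index()
        if not t.is_monotonic_increasing or t.has_duplicates:
            raise DataError("cube time axis must be strictly increasing")

    @property
    def time(self) -> pd.DatetimeIndex:
        return self.data.coords["time"].to_index()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def require_state(self, expected: str, op: str) -> None:
        if self.state != expected:
            raise StateError(
                f"{op} requires a cube in state '{expected}', got '{self.state}'"
            )

    def replace(self, data: xr.DataArray, state: str, quality=None) -> "EviCube":
        return EviCube(data=data, quality=quality, state=state,
                       mask=None if self.mask is None else self.mask.copy())

    # ------------------------------------------------------------------ I/O

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset({"evi": self.data})
        if self.quality is not None:
            ds["quality"] = self.quality
        if self.mask is not None:
            ds["pixel_mask"] = xr.DataArray(
                self.mask.astype("int8"), dims=("row", "col")
            )
        ds.attrs["state"] = self.state
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "EviCube":
        mask = None
        if "pixel_mask" in ds:
            mask = ds["pixel_mask"].values.astype(bool)
        quality = ds["quality"] if "quality" in ds else None
        return cls(data=ds["evi"], quality=quality,
                   state=ds.attrs.get("state", "raw"), mask=mask)

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def open(cls, path) -> "EviCube":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass
class LandCoverMap:
    """Per-pixel UN-LCCS class codes with (optionally) derived categories."""

    codes: xr.DataArray  # (row, col) int
    categories: xr.DataArray | None = field(default=None)

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset({"lc_code": self.codes.astype("int32")})
        if self.categories is not None:
            # NETCDF3 has no string type; store the category index
            idx = np.vectorize(LANDCOVER_CATEGORIES.index)(self.categories.values)
            ds["lc_category_index"] = xr.DataArray(
                idx.astype("int32"), dims=("row", "col")
            )
            ds.attrs["lc_categories"] = ",".join(LANDCOVER_CATEGORIES)
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def open(cls, path) -> "LandCoverMap":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        categories = None
        if "lc_category_index" in ds:
            cats = np.asarray(LANDCOVER_CATEGORIES)[ds["lc_category_index"].values]
            categories = xr.DataArray(cats, dims=("row", "col"))
        return cls(codes=ds["lc_code"], categories=categories)


def code_to_category(code: int) -> str:
    try:
        return _CODE_TO_CATEGORY[int(code)]
    except KeyError:
        raise DataError(f"unmapped land-cover class code: {code}") from None
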