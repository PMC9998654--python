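"""Reading and writing the pipeline's standard formats.

Gridded fields travel as CF-style NetCDF (dimensions time/lat/lon, a
``units`` attribute per variable); time series, profiles, bottle casts
and NPP records as documented CSV; reports as JSON.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GeometryError, REQUIRED_DIMS
from .profiles import BottleCast

KNOWN_UNITS = {"mg m-3", "m s-1", "1", "fraction", "percent"}


def read_gridded(path: str | Path, var: str | None = None) -> xr.DataArray:
    """Load one gridded variable from a NetCDF file.

    Requires time/lat/lon coordinates; latitude and longitude are
    sorted ascending (values permuted consistently).  An unfamiliar or
    absent ``units`` attribute raises a warning, not an error.
    """
    ds = xr.open_dataset(path)
    if var is None:
        candidates = [v for v in ds.data_vars if set(REQUIRED_DIMS) <= set(ds[v].dims)]
        if not candidates:
            raise GeometryError(f"{path}: no variable with dims {REQUIRED_DIMS}")
        var = candidates[0]
    if var not in ds:
        raise GeometryError(f"{path}: no variable {var!r}")
    da = ds[var]
    missing = [d for d in REQUIRED_DIMS if d not in da.dims]
    if missing:
        raise GeometryError(f"{path}:{var} missing coordinate(s) {missing}")
    for dim in ("lat", "lon"):
        coord = da[dim].values
        if coord.size > 1 and not np.all(np.diff(coord) > 0):
            da = da.sortby(dim)
    units = da.attrs.get("units")
    if units not in KNOWN_UNITS:
        warnings.warn(f"{path}:{var} has unrecognized units {units!r}")
    return da.load()


def write_gridded(field: xr.DataArray, path: str | Path) -> None:
    field.to_dataset(name=field.name or "field").to_netcdf(path, engine="scipy")


def read_series_csv(path: str | Path, time_col: str = "time",
                    value_col: str = "value") -> pd.Series:
    """Time-stamped scalar series from CSV; blank values become NaN."""
    df = pd.read_csv(path, parse_dates=[time_col])
    s = pd.Series(df[value_col].to_numpy(), index=pd.DatetimeIndex(df[time_col]))
    if not s.index.is_monotonic_increasing:
        s = s.sort_index()
    return s


def read_bottles_csv(path: str | Path) -> BottleCast:
    """Bottle calibration cast: columns depth_m and chl/poc in mg m-3."""
    df = pd.read_csv(path)
    if "depth_m" not in df.columns:
        raise ValueError(f"{path}: bottle CSV needs a depth_m column")
    return BottleCast(
        depths=df["depth_m"].to_numpy(),
        chl=df["chl_mg_m3"].to_numpy() if "chl_mg_m3" in df else None,
        poc=df["poc_mg_m3"].to_numpy() if "poc_mg_m3" in df else None)


def read_npp_csv(path: str | Path) -> pd.Series:
    """Daily NPP series: columns date, npp_mgC_m2_d."""
    df = pd.read_csv(path, parse_dates=["date"])
    return pd.Series(df["npp_mgC_m2_d"].to_numpy(),
                     index=pd.DatetimeIndex(df["date"]), name="npp_mgC_m2_d")
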