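"""Light-weight conventions for gridded (cell x time) data.

A "GridCube" is an :class:`xarray.DataArray` with dims ``("cell", "time")``,
a datetime64 ``time`` coordinate at a fixed step, integer ``cell`` ids and
optional per-cell ``lat``/``lon`` coordinates; units live in ``attrs``.
An "AnomalyCube" is an :class:`xarray.Dataset` with variables ``anomaly``
and ``trend`` (cell x time) plus ``climatology`` (cell x month).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

CELL = "cell"
TIME = "time"


def make_cube(
    values: np.ndarray,
    time,
    cells=None,
    lat=None,
    lon=None,
    units: str = "",
    name: str | None = None,
) -> xr.DataArray:
    """Wrap a (cell x time) array into the package's cube convention."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("cube values must be 2-D (cell x time)")
    n_cells, n_time = values.shape
    if cells is None:
        cells = np.arange(n_cells)
    time = pd.DatetimeIndex(time)
    if len(time) != n_time:
        raise ValueError("time coordinate length does not match values")
    if not time.is_monotonic_increasing or time.has_duplicates:
        raise ValueError("time must be strictly increasing")
    coords = {CELL: np.asarray(cells), TIME: time}
    da = xr.DataArray(values, dims=(CELL, TIME), coords=coords, name=name)
    if lat is not None:
        da = da.assign_coords(lat=(CELL, np.asarray(lat, dtype=float)))
    if lon is not None:
        da = da.assign_coords(lon=(CELL, np.asarray(lon, dtype=float)))
    if units:
        da.attrs["units"] = units
    return da


def like(cube: xr.DataArray, values: np.ndarray, name=None, units=None) -> xr.DataArray:
    out = xr.DataArray(
        np.asarray(values, dtype=float), dims=cube.dims, coords=cube.coords, name=name
    )
    out.attrs.update(cube.attrs)
    if units is not None:
        out.attrs["units"] = units
    return out


def months_of(cube: xr.DataArray) -> np.ndarray:
    """Calendar month (1..12) of each step's centre date."""
    return cube[TIME].dt.month.values


def years_of(cube: xr.DataArray) -> np.ndarray:
    return cube[TIME].dt.year.values


def save_dataset(ds: xr.Dataset, path) -> None:
    # NetCDF3 via the scipy backend; attrs must be plain types
    ds.to_netcdf(path, engine="scipy")


def load_dataset(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")
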