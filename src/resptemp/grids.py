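"""Gridded monthly fields.

Fields are plain :class:`xarray.DataArray` objects with dimensions
``("time", "lat", "lon")``, a CF-like ``units`` attribute, and NaN marking
invalid cell-months. Monthly 1-degree resolution is assumed throughout;
``time`` is an integer month index (0-based) rather than a calendar axis.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import xarray as xr

from .exceptions import GridMismatchError

DIMS = ("time", "lat", "lon")


def gridded_field(
    values: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    units: str,
    name: str | None = None,
    time: np.ndarray | None = None,
) -> xr.DataArray:
    """Wrap a ``(time, lat, lon)`` array as a unit-carrying DataArray."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise GridMismatchError(f"expected 3-d (time, lat, lon) array, got shape {values.shape}")
    if time is None:
        time = np.arange(values.shape[0])
    if values.shape[1:] != (len(lat), len(lon)):
        raise GridMismatchError(
            f"array shape {values.shape} inconsistent with {len(lat)} lats / {len(lon)} lons"
        )
    return xr.DataArray(
        values,
        dims=DIMS,
        coords={"time": time, "lat": np.asarray(lat, float), "lon": np.asarray(lon, float)},
        name=name,
        attrs={"units": units},
    )


def like(template: xr.DataArray, values: np.ndarray, units: str | None = None,
         name: str | None = None) -> xr.DataArray:
    """New field on the same grid as ``template``."""
    out = template.copy(data=np.asarray(values, dtype=float))
    if units is not None:
        out.attrs["units"] = units
    if name is not None:
        out.name = name
    return out


def check_same_grid(*fields: xr.DataArray) -> None:
    ref = fields[0]
    for f in fields[1:]:
        if f.shape != ref.shape:
            raise GridMismatchError(f"field shapes differ: {f.shape} vs {ref.shape}")


def valid_mask(field: xr.DataArray) -> np.ndarray:
    """Boolean mask of valid (finite) cell-months."""
    return np.isfinite(np.asarray(field.values, dtype=float))


def broadcast_spatial_mask(mask2d: np.ndarray | None, shape3d: tuple[int, int, int]) -> np.ndarray:
    """Expand a (lat, lon) selector over time; ``None`` selects everything."""
    if mask2d is None:
        return np.ones(shape3d, dtype=bool)
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.shape != shape3d[1:]:
        raise GridMismatchError(f"spatial mask {mask2d.shape} does not match grid {shape3d[1:]}")
    return np.broadcast_to(mask2d[None, :, :], shape3d).copy()


def save_fields(path, fields: Mapping[str, xr.DataArray], attrs: Mapping[str, object] | None = None) -> None:
    """Write fields into one classic-NetCDF file (scipy backend, no netCDF4 needed)."""
    ds = xr.Dataset({k: v for k, v in fields.items()})
    if attrs:
        ds.attrs.update({k: str(v) for k, v in attrs.items()})
    ds.to_netcdf(path, engine="scipy")


def load_fields(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")
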