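"""Conventions and helpers for gridded geophysical fields.

A gridded field is an :class:`xarray.DataArray` with dimensions
``(time, lat, lon)``, coordinates in degrees north/east, ``NaN`` for
missing cells (cloud, sea ice, off-swath) and a ``units`` attribute.
All public functions in this package accept and return fields in that
form; no bespoke container is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

REQUIRED_DIMS = ("time", "lat", "lon")


class GeometryError(ValueError):
    """A spatial selection does not overlap the field's grid."""


@dataclass(frozen=True)
class RegionBox:
    """Geographic bounding box (cell centers inside are selected).

    Longitudes in degrees east, latitudes in degrees north; southern
    latitudes are negative, e.g. the recurrent-bloom core box spanning
    4-8 degrees E and 67.8-68.4 degrees S is
    ``RegionBox(4, 8, -68.4, -67.8)``.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if not self.lon_min < self.lon_max:
            raise ValueError(f"lon_min must be < lon_max, got {self.lon_min}, {self.lon_max}")
        if not self.lat_min < self.lat_max:
            raise ValueError(f"lat_min must be < lat_max, got {self.lat_min}, {self.lat_max}")

    def select(self, field: xr.DataArray) -> xr.DataArray:
        """Subset of cells whose centers lie inside the box (inclusive)."""
        validate_field(field)
        sel = field.where(
            (field.lat >= self.lat_min) & (field.lat <= self.lat_max)
            & (field.lon >= self.lon_min) & (field.lon <= self.lon_max),
            drop=True,
        )
        if sel.sizes.get("lat", 0) == 0 or sel.sizes.get("lon", 0) == 0:
            raise GeometryError(f"box {self} does not overlap the grid")
        return sel

    def mask(self, field: xr.DataArray) -> xr.DataArray:
        """Boolean (lat, lon) mask of cell centers inside the box."""
        return (
            (field.lat >= self.lat_min) & (field.lat <= self.lat_max)
            & (field.lon >= self.lon_min) & (field.lon <= self.lon_max)
        )


# Core box of the recurrent eastern Weddell Gyre bloom (4-8 E, 67.8-68.4 S).
BLOOM_CORE_BOX = RegionBox(4.0, 8.0, -68.4, -67.8)


def validate_field(field: xr.DataArray) -> xr.DataArray:
    """Check the (time, lat, lon) layout; raise ``GeometryError`` otherwise."""
    missing = [d for d in REQUIRED_DIMS if d not in field.dims]
    if missing:
        raise GeometryError(f"field is missing dimensions {missing}; has {field.dims}")
    lat = np.asarray(field.lat)
    lon = np.asarray(field.lon)
    if lat.size > 1 and not (np.all(np.diff(lat) > 0) or np.all(np.diff(lat) < 0)):
        raise GeometryError("latitude coordinate is not monotonic")
    if lon.size > 1 and not (np.all(np.diff(lon) > 0) or np.all(np.diff(lon) < 0)):
        raise GeometryError("longitude coordinate is not monotonic")
    return field
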