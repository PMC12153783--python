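"""Lightweight georeferenced single-band rasters (ESRI ASCII grid).

Interpolated surfaces are carried as a :class:`Raster` — a 2-D value array
on a regular lon/lat grid — and serialized to the plain-text ESRI ASCII
grid format (``.asc``), which any GIS reads directly.  Each prediction
surface is written alongside a companion standard-error raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

NODATA = -9999.0


@dataclass(frozen=True)
class Raster:
    """Single-band raster on a regular grid.

    ``values`` has shape (nrows, ncols) with row 0 the *southernmost* row
    (ascending latitude), matching the lat/lon axis arrays.
    """

    values: np.ndarray
    lons: np.ndarray
    lats: np.ndarray

    def __post_init__(self):
        if self.values.shape != (self.lats.size, self.lons.size):
            raise InvalidInputError("raster shape must be (n_lats, n_lons)")

    @property
    def cellsize(self) -> float:
        steps = np.concatenate([np.diff(self.lons), np.diff(self.lats)])
        return float(steps[0])


def make_grid(bounds, step) -> tuple[np.ndarray, np.ndarray]:
    """Regular lon/lat axes over ``bounds = (lon_min, lon_max, lat_min, lat_max)``."""
    lon_min, lon_max, lat_min, lat_max = bounds
    if step <= 0:
        raise InvalidInputError("grid step must be > 0")
    lons = np.arange(lon_min, lon_max + 1e-9, step)
    lats = np.arange(lat_min, lat_max + 1e-9, step)
    return lons, lats


def write_ascii_grid(raster: Raster, path) -> None:
    """Write a raster to an ESRI ASCII grid (.asc) file."""
    step = raster.cellsize
    if not (
        np.allclose(np.diff(raster.lons), step) and np.allclose(np.diff(raster.lats), step)
    ):
        raise InvalidInputError("ASCII grid export requires uniform cell size")
    values = np.where(np.isfinite(raster.values), raster.values, NODATA)
    header = (
        f"ncols {raster.lons.size}\n"
        f"nrows {raster.lats.size}\n"
        f"xllcenter {raster.lons[0]:.10g}\n"
        f"yllcenter {raster.lats[0]:.10g}\n"
        f"cellsize {step:.10g}\n"
        f"nodata_value {NODATA:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids store rows north to south
        np.savetxt(fh, values[::-1], fmt="%.8g")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols, nrows = int(meta["ncols"]), int(meta["nrows"])
    values = values.reshape(nrows, ncols)[::-1]
    step = meta["cellsize"]
    lons = meta["xllcenter"] + step * np.arange(ncols)
    lats = meta["yllcenter"] + step * np.arange(nrows)
    values = np.where(values == meta.get("nodata_value", NODATA), np.nan, values)
    return Raster(values=values, lons=lons, lats=lats)
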