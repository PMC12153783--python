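"""Georeferenced climate point tables and their on-disk formats.

The working container is a long-format pandas DataFrame with one row per
(point, year):

    id, lon, lat, year, tair_c, ws_ms, precip_mm, region

``region`` and ``precip_mm`` are optional (drought indexing needs
``precip_mm``; regional aggregation needs ``region``).  Two encodings are
supported: a CSV point table with exactly that header, and a CF-style
NetCDF grid with ``lat``/``lon``/``year`` coordinates and ``tair``/``ws``/
``precip`` variables (regular grids only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

POINT_COLUMNS = ["id", "lon", "lat", "year", "tair_c", "ws_ms", "precip_mm", "region"]
_REQUIRED = ["id", "lon", "lat", "year", "tair_c", "ws_ms"]


@dataclass
class ClimateField:
    """Validated georeferenced climate point table.

    Parameters
    ----------
    table : DataFrame
        Long-format table with the point-table columns; missing optional
        columns (``precip_mm``, ``region``) are added as NA.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise InvalidInputError(f"point table is missing required columns: {missing}")
        for c in ("precip_mm", "region"):
            if c not in df.columns:
                df[c] = np.nan
        df = df[POINT_COLUMNS]
        for c in ("lon", "lat", "tair_c", "ws_ms"):
            if not np.all(np.isfinite(df[c].to_numpy(dtype=float))):
                raise InvalidInputError(f"column {c!r} contains non-finite values")
        if df.duplicated(subset=["id", "year"]).any():
            raise InvalidInputError("duplicate (id, year) rows: point ids must be unique per year")
        # every point must carry the same set of years
        years_per_point = df.groupby("id")["year"].apply(frozenset)
        if years_per_point.nunique() != 1:
            raise InvalidInputError("years are inconsistent across points")
        self.table = df.reset_index(drop=True)

    @property
    def years(self) -> list:
        return sorted(self.table["year"].unique().tolist())

    @property
    def points(self) -> pd.DataFrame:
        """One row per point: id, lon, lat (and region when present)."""
        return (
            self.table.drop_duplicates(subset="id")[["id", "lon", "lat", "region"]]
            .reset_index(drop=True)
        )

    @property
    def has_precip(self) -> bool:
        return bool(np.all(np.isfinite(self.table["precip_mm"].to_numpy(dtype=float))))

    def year_slice(self, year) -> pd.DataFrame:
        out = self.table[self.table["year"] == year]
        if out.empty:
            raise InvalidInputError(f"year {year} not present in the field")
        return out.reset_index(drop=True)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClimateField":
        df = pd.read_csv(path)
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise InvalidInputError(
                f"malformed point-table header in {path}: missing columns {missing}"
            )
        return cls(df)

    def to_netcdf(self, path) -> None:
        """Write as a CF-style NetCDF grid (requires a regular lon/lat grid)."""
        import xarray as xr

        df = self.table
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        years = np.sort(df["year"].unique())
        if len(lats) * len(lons) != df.drop_duplicates("id").shape[0]:
            raise InvalidInputError("NetCDF export requires points on a regular lon/lat grid")
        shape = (len(years), len(lats), len(lons))
        data = {}
        idx = df.set_index(["year", "lat", "lon"]).sort_index()
        for var, col in (("tair", "tair_c"), ("ws", "ws_ms"), ("precip", "precip_mm")):
            values = idx[col].to_numpy(dtype=float).reshape(shape)
            data[var] = (("year", "lat", "lon"), values)
        ds = xr.Dataset(
            data,
            coords={"year": years, "lat": lats, "lon": lons},
            attrs={"Conventions": "CF-1.8"},
        )
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        ds["tair"].attrs.update(units="degC", long_name="annual mean air temperature")
        ds["ws"].attrs.update(units="m s-1", long_name="annual mean wind speed")
        ds["precip"].attrs.update(units="mm", long_name="annual precipitation")
        ds.to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")

    @classmethod
    def from_netcdf(cls, path) -> "ClimateField":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        for required in ("lat", "lon", "year", "tair", "ws"):
            if required not in ds:
                raise InvalidInputError(f"NetCDF grid is missing {required!r}")
        df = ds.to_dataframe().reset_index()
        glon, glat = np.meshgrid(ds["lon"].values, ds["lat"].values)
        point_id = pd.DataFrame(
            {
                "lat": glat.ravel(),
                "lon": glon.ravel(),
                "id": np.arange(glat.size),
            }
        )
        df = df.merge(point_id, on=["lat", "lon"], how="left")
        df = df.rename(columns={"tair": "tair_c", "ws": "ws_ms"})
        if "precip" in df.columns:
            df = df.rename(columns={"precip": "precip_mm"})
        return cls(df)
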