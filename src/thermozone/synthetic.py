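"""Synthetic climate fields with the statistical structure the zoning analysis assumes.

The generator emulates a gridded annual climatology over a tropical,
state-sized domain: spatially autocorrelated air-temperature and wind-speed
fields with a north–south thermal gradient, gamma-distributed annual
precipitation, and injected drought years (reduced precipitation, elevated
temperature).  Defaults mirror the study conditions of the analysis this
package implements: a 2012–2023 record over a domain shaped like Maranhão
(mean Tair 27.3 °C, mean annual precipitation 1623 mm, wind speeds in the
0.7–2.8 m s⁻¹ band, statewide drought years 2012/2015/2016/2023, and a
spherical generating variogram with sill ≈ 0.35 THI-scale units).

Gaussian random fields are synthesized by dense Cholesky factorization of
the covariance matrix C(h) = sill − γ(h) (nugget realized as independent
white noise on the diagonal), which is exact but limits a single field to
a few thousand points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import InvalidInputError
from .field import ClimateField, POINT_COLUMNS
from .variogram import VariogramModel

import pandas as pd

_MAX_DENSE_POINTS = 6000


def _default_variogram() -> VariogramModel:
    return VariogramModel("spherical", nugget=0.01, partial_sill=0.35, range_a=1.5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic climate-field generator.

    Attributes
    ----------
    grid_extent : (lon_min, lon_max, lat_min, lat_max)
        Bounding box in decimal degrees; default approximates Maranhão.
    grid_step : float
        Grid spacing in degrees (> 0).
    years : sequence of int
        Calendar years to generate.
    seed : int
        RNG seed; identical configs yield bit-identical fields.
    base_tair : float
        Domain-mean air temperature (°C) in non-drought years.
    tair_gradient : float
        °C change per degree latitude; positive values warm the north
        (toward the equator) relative to the south.
    variogram : VariogramModel
        Generating covariance of the temperature field (degree units).
    precip_shape, precip_scale : float
        Gamma parameters of annual precipitation (mm); defaults give a
        1623 mm mean with CV ≈ 18%, typical of annual totals.
    drought_years : sequence of int
        Years receiving the drought treatment.
    drought_multiplier : float
        Precipitation multiplier in drought years, in (0, 1).
    drought_tair_offset : float
        Additive Tair offset (°C, > 0) in drought years.
    ws_median, ws_log_sigma : float
        Wind speed is exp(Gaussian field): lognormal with this median and
        log-scale spread, so positivity is structural; defaults keep the
        bulk of values within 0.7–2.8 m s⁻¹.
    """

    grid_extent: Tuple[float, float, float, float] = (-47.5, -41.8, -10.2, -1.1)
    grid_step: float = 0.5
    years: Sequence[int] = tuple(range(2012, 2024))
    seed: int = 0
    base_tair: float = 27.3
    tair_gradient: float = 0.15
    variogram: VariogramModel = field(default_factory=_default_variogram)
    precip_shape: float = 30.0
    precip_scale: float = 54.1
    drought_years: Sequence[int] = (2012, 2015, 2016, 2023)
    drought_multiplier: float = 0.6
    drought_tair_offset: float = 0.5
    ws_median: float = 1.4
    ws_log_sigma: float = 0.25

    def __post_init__(self):
        lon_min, lon_max, lat_min, lat_max = self.grid_extent
        if not (lon_min < lon_max and lat_min < lat_max):
            raise InvalidInputError("grid_extent must satisfy lon_min < lon_max, lat_min < lat_max")
        if self.grid_step <= 0:
            raise InvalidInputError("grid_step must be > 0")
        if len(self.years) == 0:
            raise InvalidInputError("years must be non-empty")
        if self.precip_shape <= 0 or self.precip_scale <= 0:
            raise InvalidInputError("gamma precipitation parameters must be > 0")
        if not (0 < self.drought_multiplier < 1):
            raise InvalidInputError("drought multiplier must lie in (0, 1)")
        if self.drought_tair_offset < 0:
            raise InvalidInputError("drought Tair offset must be >= 0")
        if self.ws_median <= 0 or self.ws_log_sigma < 0:
            raise InvalidInputError("wind-speed parameters out of range")

    def grid(self) -> pd.DataFrame:
        """Regular lon/lat grid over the extent (point id, lon, lat)."""
        lon_min, lon_max, lat_min, lat_max = self.grid_extent
        lons = np.arange(lon_min, lon_max + 1e-9, self.grid_step)
        lats = np.arange(lat_min, lat_max + 1e-9, self.grid_step)
        glon, glat = np.meshgrid(lons, lats)
        return pd.DataFrame(
            {
                "id": np.arange(glon.size),
                "lon": glon.ravel(),
                "lat": glat.ravel(),
            }
        )


def generate_gaussian_random_field(
    model: VariogramModel,
    locations,
    mean: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """One realization of a stationary Gaussian field with variogram ``model``.

    The covariance between distinct locations is C(h) = sill − γ(h); the
    diagonal carries the full sill, so the nugget appears as independent
    white noise per location.  Synthesis is by dense Cholesky factorization,
    exact but O(n³): the number of locations must stay below ~5000.

    Parameters
    ----------
    model : VariogramModel
    locations : (n, d) array of distinct coordinates
    mean : float, constant mean of the field
    seed : int, RNG seed (ignored if ``rng`` is given)
    rng : numpy Generator, alternative randomness source
    """
    loc = np.asarray(locations, dtype=float)
    if loc.ndim != 2:
        raise InvalidInputError("locations must be an (n, d) array")
    n = loc.shape[0]
    if n > _MAX_DENSE_POINTS:
        raise InvalidInputError(
            f"dense Cholesky synthesis is limited to {_MAX_DENSE_POINTS} points, got {n}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    if model.sill == 0.0:
        return np.full(n, float(mean))
    d = squareform(pdist(loc))
    if n > 1 and np.min(d[np.triu_indices(n, k=1)]) == 0.0:
        raise InvalidInputError("locations must be distinct")
    cov = model.covariance(d)
    np.fill_diagonal(cov, model.sill)
    jitter = 1e-10 * model.sill
    try:
        chol = np.linalg.cholesky(cov + jitter * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise InvalidInputError(
            "covariance matrix not positive definite after nugget "
            "regularization; check the variogram model and locations"
        ) from exc
    return mean + chol @ rng.standard_normal(n)


def assign_mesoregions(lon, lat) -> np.ndarray:
    """Deterministic five-region labelling (north/south/west/east/central).

    Splits the bounding box by latitude quartiles and longitude terciles —
    a stand-in for administrative mesoregion membership, which in real use
    arrives as an input column.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lat_hi = np.quantile(lat, 0.75)
    lat_lo = np.quantile(lat, 0.25)
    lon_lo = np.quantile(lon, 1 / 3)
    lon_hi = np.quantile(lon, 2 / 3)
    out = np.full(lon.shape, "central", dtype=object)
    out[lon <= lon_lo] = "west"
    out[lon >= lon_hi] = "east"
    out[lat >= lat_hi] = "north"
    out[lat <= lat_lo] = "south"
    return out


def generate_climate_series(config: SyntheticConfig) -> ClimateField:
    """Generate a multi-year climate point table from a config.

    Per year: Tair = base + latitude gradient + Gaussian random field
    (+ drought offset in drought years); wind speed is the exponential of
    an independent standardized Gaussian field (lognormal, hence > 0);
    annual precipitation is drawn per point from the gamma law, times the
    drought multiplier in drought years.  Fully reproducible under
    ``config.seed``.
    """
    grid = config.grid()
    n = len(grid)
    loc = grid[["lon", "lat"]].to_numpy()
    lat_centered = grid["lat"].to_numpy() - grid["lat"].mean()
    region = assign_mesoregions(grid["lon"], grid["lat"])

    # one independent child stream per (year, variable): insertion/removal of
    # a year never perturbs the other years' draws
    root = np.random.SeedSequence(config.seed)
    streams = {
        (year, var): np.random.default_rng(child)
        for year, children in zip(
            config.years,
            (s.spawn(3) for s in root.spawn(len(config.years))),
        )
        for var, child in zip(("tair", "ws", "precip"), children)
    }

    ws_model = VariogramModel(
        config.variogram.family,
        nugget=0.05,
        partial_sill=0.95,
        range_a=config.variogram.range_a,
    )

    frames = []
    for year in config.years:
        drought = year in set(config.drought_years)
        tair = (
            config.base_tair
            + config.tair_gradient * lat_centered
            + generate_gaussian_random_field(
                config.variogram, loc, mean=0.0, rng=streams[(year, "tair")]
            )
            + (config.drought_tair_offset if drought else 0.0)
        )
        g = generate_gaussian_random_field(ws_model, loc, mean=0.0, rng=streams[(year, "ws")])
        ws = config.ws_median * np.exp(config.ws_log_sigma * g)
        precip = streams[(year, "precip")].gamma(
            shape=config.precip_shape, scale=config.precip_scale, size=n
        )
        if drought:
            precip = precip * config.drought_multiplier
        frames.append(
            pd.DataFrame(
                {
                    "id": grid["id"],
                    "lon": grid["lon"],
                    "lat": grid["lat"],
                    "year": year,
                    "tair_c": tair,
                    "ws_ms": ws,
                    "precip_mm": precip,
                    "region": region,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)[POINT_COLUMNS]
    return ClimateField(table)
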