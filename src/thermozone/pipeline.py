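"""End-to-end bioclimatic zoning: indices → variography → kriging → reports.

``run_zoning`` executes the full historical workflow per year: THI and DMP
at every point, experimental semivariogram, fit of the three model
families, leave-one-out cross-validation and model selection, ordinary
kriging of THI and DMP onto an output grid, heat-stress classification of
the surfaces, and descriptive/validation reporting.  ``run_scenarios``
pushes climate-projection fields (per pathway and horizon) through the same
geostatistical pathway.

The knobs that published zoning studies usually leave implicit — THI
formula, distance metric, lag design, neighborhood size, whether indices
are computed before or after interpolation — are explicit configuration
here and echoed into every report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import spi as spi_mod
from .coords import METRICS, to_cartesian
from .errors import InvalidInputError
from .field import ClimateField
from .indices import (
    DAIRY_CLASSES,
    DEFAULT_THI_FORMULA,
    LWSI_CLASSES,
    classify_cv,
    classify_dairy_stress,
    classify_lwsi,
    compute_dmp,
    compute_thi,
)
from .kriging import ordinary_kriging
from .raster import Raster, make_grid, write_ascii_grid
from .validation import (
    CrossValidation,
    compute_dsd,
    loo_cross_validate,
    select_model,
)
from .variogram import FAMILIES, empirical_semivariogram, fit_variogram

logger = logging.getLogger(__name__)

PATHWAYS = ("RCP4.5", "RCP8.5")
HORIZONS = ("short", "mid", "long")
HORIZON_PERIODS = {"short": "2011-2040", "mid": "2041-2070", "long": "2071-2100"}


@dataclass(frozen=True)
class DescriptiveStats:
    """Mean, extremes, sample SD (n−1) and coefficient of variation (%)."""

    mean: float
    minimum: float
    maximum: float
    sd: float
    cv_percent: float
    cv_defined: bool = True


def descriptive_stats(values) -> DescriptiveStats:
    """Descriptive summary of one year's values; CV% = 100·SD/mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidInputError("descriptive statistics need at least two values")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("values must be finite")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0.0:
        if sd == 0.0:
            cv, defined = 0.0, True
        else:
            cv, defined = float("nan"), False
    else:
        cv, defined = 100.0 * sd / mean, True
    return DescriptiveStats(
        mean=mean,
        minimum=float(x.min()),
        maximum=float(x.max()),
        sd=sd,
        cv_percent=cv,
        cv_defined=defined,
    )


@dataclass(frozen=True)
class ZoningConfig:
    """Configuration of the zoning pipeline.

    Attributes
    ----------
    thi_formula : str
        Registered THI formula name; recorded in every output.
    np_levels : tuple of float
        Potential production levels for the milk-loss regression
        (kg day⁻¹ cow⁻¹); the regional-zoning settings are (10, 25).
    metric : str
        Distance metric for all geostatistics (see :mod:`thermozone.coords`).
    n_lags, max_dist : lag design of the experimental semivariogram.
    n_neighbors : kriging neighborhood size (None = global).
    families : variogram families to fit and compare.
    krige_mode : ``index-then-krige`` computes THI/DMP per point and
        interpolates them; ``krige-then-index`` interpolates Tair and wind
        and derives indices from the interpolated surfaces.
    grid_step : output grid spacing in degrees (None = native spacing of
        the input points).
    compute_spi : include drought indexing (requires precipitation).
    seed : recorded for provenance; the pipeline itself is deterministic.
    """

    thi_formula: str = DEFAULT_THI_FORMULA
    np_levels: Tuple[float, ...] = (10.0, 25.0)
    metric: str = "equirectangular-meters"
    n_lags: int = 12
    max_dist: Optional[float] = None
    n_neighbors: Optional[int] = 16
    families: Tuple[str, ...] = FAMILIES
    krige_mode: str = "index-then-krige"
    grid_step: Optional[float] = None
    compute_spi: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.metric not in METRICS:
            raise InvalidInputError(f"unknown metric {self.metric!r}")
        if self.krige_mode not in ("index-then-krige", "krige-then-index"):
            raise InvalidInputError(f"unknown krige_mode {self.krige_mode!r}")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise InvalidInputError(f"unknown variogram families: {sorted(unknown)}")
        if any(np_level < 0 for np_level in self.np_levels):
            raise InvalidInputError("np_levels must be non-negative")


@dataclass(frozen=True)
class ScenarioSpec:
    """One climate-projection layer: pathway, horizon, and its fields.

    ``fields`` is a DataFrame with columns id, lon, lat, tmed_c, ws_ms —
    projected mean temperature and wind speed on the analysis point set.
    """

    pathway: str
    horizon: str
    fields: pd.DataFrame

    def __post_init__(self):
        if self.pathway not in PATHWAYS:
            raise InvalidInputError(f"unknown pathway {self.pathway!r}; expected {PATHWAYS}")
        if self.horizon not in HORIZONS:
            raise InvalidInputError(f"unknown horizon {self.horizon!r}; expected {HORIZONS}")
        missing = {"id", "lon", "lat", "tmed_c", "ws_ms"} - set(self.fields.columns)
        if missing:
            raise InvalidInputError(f"scenario fields missing columns: {sorted(missing)}")

    @property
    def label(self) -> str:
        return f"{self.pathway}_{self.horizon}"

    @property
    def period(self) -> str:
        return HORIZON_PERIODS[self.horizon]


@dataclass
class LayerResult:
    """Geostatistical analysis of one annual (or scenario) layer."""

    label: str
    thi_points: np.ndarray
    dmp_points: Dict[float, np.ndarray]
    selection: object  # ModelSelection
    models: dict  # family -> VariogramModel
    cv: Dict[str, CrossValidation]
    rasters: Dict[str, Raster]
    area_fractions: pd.DataFrame


@dataclass
class ZoningReport:
    """Aggregated pipeline output (tables mirror the reporting of zoning studies)."""

    thi_stats: pd.DataFrame
    model_summary: pd.DataFrame
    dsd_table: pd.DataFrame
    area_fractions: pd.DataFrame
    dmp_summary: pd.DataFrame
    spi: Optional[dict]
    thi_formula: str
    metric: str
    config: ZoningConfig


def _native_step(values: np.ndarray) -> float:
    uniq = np.sort(np.unique(values))
    if uniq.size < 2:
        raise InvalidInputError("cannot infer a grid step from a single coordinate")
    return float(np.median(np.diff(uniq)))


def _output_grid(pts: pd.DataFrame, config: ZoningConfig):
    step = config.grid_step
    if step is None:
        step = min(_native_step(pts["lon"].to_numpy()), _native_step(pts["lat"].to_numpy()))
    bounds = (
        pts["lon"].min(),
        pts["lon"].max(),
        pts["lat"].min(),
        pts["lat"].max(),
    )
    return make_grid(bounds, step)


def _area_fractions(label, thi_surface: np.ndarray) -> pd.DataFrame:
    """Equal-weight cell fractions per classification scheme (sum to 1)."""
    flat = thi_surface.ravel()
    flat = flat[np.isfinite(flat)]
    rows = []
    for scheme, classes, classifier in (
        ("lwsi", LWSI_CLASSES, classify_lwsi),
        ("dairy", DAIRY_CLASSES, classify_dairy_stress),
    ):
        labels = classifier(flat)
        for cls in classes:
            rows.append(
                {
                    "layer": label,
                    "scheme": scheme,
                    "class": cls,
                    "fraction": float(np.mean(labels == cls)) if flat.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _krige_surface(model, coords, values, tcoords, shape, n_neighbors):
    pred = ordinary_kriging(model, coords, values, tcoords, n_neighbors=n_neighbors)
    return pred.estimate.reshape(shape), pred.std_error.reshape(shape)


def _analyze_layer(label: str, pts: pd.DataFrame, tair, ws, config: ZoningConfig) -> LayerResult:
    """Shared per-layer workflow for historical years and scenarios."""
    tair = np.asarray(tair, dtype=float)
    ws = np.asarray(ws, dtype=float)
    thi = compute_thi(tair, ws, formula=config.thi_formula)
    dmp = {np_level: compute_dmp(np_level, thi).dmp for np_level in config.np_levels}

    ref_lat = float(pts["lat"].mean())
    coords = to_cartesian(pts["lon"], pts["lat"], config.metric, ref_lat=ref_lat)

    if np.ptp(thi) == 0.0:
        # spatially constant field: interpolation is the identity, and the
        # variogram is degenerate — emit constant surfaces directly
        lons, lats = _output_grid(pts, config)
        shape = (lats.size, lons.size)
        rasters = {
            "thi": Raster(np.full(shape, float(thi[0])), lons, lats),
            "thi_se": Raster(np.zeros(shape), lons, lats),
        }
        for np_level, dvals in dmp.items():
            rasters[f"dmp_pl{np_level:g}"] = Raster(np.full(shape, float(dvals[0])), lons, lats)
        from .validation import ModelSelection

        return LayerResult(
            label=label,
            thi_points=thi,
            dmp_points=dmp,
            selection=ModelSelection(family=config.families[0], ranking=pd.DataFrame()),
            models={},
            cv={},
            rasters=rasters,
            area_fractions=_area_fractions(label, rasters["thi"].values),
        )

    emp = empirical_semivariogram(coords, thi, n_lags=config.n_lags, max_dist=config.max_dist)
    models = {}
    cv = {}
    for family in config.families:
        m = fit_variogram(emp, family)
        models[family] = m
        cv[family] = loo_cross_validate(coords, thi, m, n_neighbors=config.n_neighbors)
    selection = select_model(cv)
    best = models[selection.family]
    logger.info(
        "%s: selected %s (RMSSE %.4f); formula=%s metric=%s n_lags=%d",
        label,
        selection.family,
        cv[selection.family].rmsse,
        config.thi_formula,
        config.metric,
        config.n_lags,
    )

    lons, lats = _output_grid(pts, config)
    glon, glat = np.meshgrid(lons, lats)
    tcoords = to_cartesian(glon.ravel(), glat.ravel(), config.metric, ref_lat=ref_lat)
    shape = glat.shape

    rasters: Dict[str, Raster] = {}
    if config.krige_mode == "index-then-krige":
        est, se = _krige_surface(best, coords, thi, tcoords, shape, config.n_neighbors)
        thi_surface = est
        rasters["thi"] = Raster(est, lons, lats)
        rasters["thi_se"] = Raster(se, lons, lats)
        for np_level, dvals in dmp.items():
            dest, dse = _krige_surface(best, coords, dvals, tcoords, shape, config.n_neighbors)
            rasters[f"dmp_pl{np_level:g}"] = Raster(dest, lons, lats)
            rasters[f"dmp_pl{np_level:g}_se"] = Raster(dse, lons, lats)
    else:  # krige-then-index: interpolate drivers, derive indices on the grid
        tair_est, tair_se = _krige_surface(best, coords, tair, tcoords, shape, config.n_neighbors)
        ws_est, _ = _krige_surface(best, coords, ws, tcoords, shape, config.n_neighbors)
        thi_surface = compute_thi(tair_est, np.maximum(ws_est, 0.0), formula=config.thi_formula)
        rasters["thi"] = Raster(thi_surface, lons, lats)
        rasters["thi_se"] = Raster(tair_se, lons, lats)  # driver uncertainty proxy
        for np_level in dmp:
            rasters[f"dmp_pl{np_level:g}"] = Raster(
                compute_dmp(np_level, thi_surface).dmp, lons, lats
            )

    return LayerResult(
        label=label,
        thi_points=thi,
        dmp_points=dmp,
        selection=selection,
        models=models,
        cv=cv,
        rasters=rasters,
        area_fractions=_area_fractions(label, thi_surface),
    )


def run_zoning(field: ClimateField, config: ZoningConfig = ZoningConfig(), out_dir=None):
    """Run the historical zoning workflow over every year of a climate field.

    Returns ``(report, rasters)`` where ``rasters`` maps
    ``(year, name) -> Raster``.  When ``out_dir`` is given, rasters are
    written as ASCII grids and the report as CSV + JSON.
    """
    if config.compute_spi and not field.has_precip:
        raise InvalidInputError(
            "drought indexing requires a complete precip_mm column; "
            "disable compute_spi or supply precipitation"
        )

    stats_rows = []
    model_rows = []
    dsd_rows = []
    area_frames = []
    dmp_rows = []
    rasters: Dict[tuple, Raster] = {}

    for year in field.years:
        pts = field.year_slice(year)
        layer = _analyze_layer(
            str(year), pts, pts["tair_c"].to_numpy(), pts["ws_ms"].to_numpy(), config
        )

        ds = descriptive_stats(layer.thi_points)
        stats_rows.append(
            {
                "year": year,
                "mean": ds.mean,
                "min": ds.minimum,
                "max": ds.maximum,
                "sd": ds.sd,
                "cv_percent": ds.cv_percent,
                "cv_class": classify_cv(ds.cv_percent) if ds.cv_defined else "undefined",
            }
        )
        for family, cvm in layer.cv.items():
            model_rows.append(
                {"year": year, "family": family, **cvm.as_dict(),
                 "selected": family == layer.selection.family}
            )
        if layer.models:
            best = layer.models[layer.selection.family]
            dep = compute_dsd(best)
            dsd_rows.append(
                {
                    "year": year,
                    "family": layer.selection.family,
                    "nugget": best.nugget,
                    "sill": best.sill,
                    "range": best.range_a,
                    "dsd_percent": dep.dsd_percent,
                    "dsd_class": dep.dsd_class,
                }
            )
        af = layer.area_fractions.rename(columns={"layer": "year"})
        af["year"] = year
        area_frames.append(af)
        for np_level, dvals in layer.dmp_points.items():
            dmp_rows.append(
                {
                    "year": year,
                    "np_level": np_level,
                    "mean_dmp": float(np.mean(dvals)),
                    "max_dmp": float(np.max(dvals)),
                    "frac_points_with_loss": float(np.mean(dvals > 0)),
                }
            )
        for name, r in layer.rasters.items():
            rasters[(year, name)] = r

    spi_result = None
    if config.compute_spi:
        table = field.table
        try:
            if table["region"].notna().all():
                spi_result = spi_mod.aggregate_spi_by_region(table)
            else:
                spi_result = {"all": spi_mod.compute_spi(table.groupby("year")["precip_mm"].mean())}
        except spi_mod.UnfittableSeriesError as exc:
            logger.warning("drought indexing skipped: %s", exc)

    report = ZoningReport(
        thi_stats=pd.DataFrame(stats_rows),
        model_summary=pd.DataFrame(model_rows),
        dsd_table=pd.DataFrame(dsd_rows),
        area_fractions=pd.concat(area_frames, ignore_index=True),
        dmp_summary=pd.DataFrame(dmp_rows),
        spi=spi_result,
        thi_formula=config.thi_formula,
        metric=config.metric,
        config=config,
    )
    if out_dir is not None:
        write_report(report, out_dir)
        out = Path(out_dir)
        for (year, name), r in rasters.items():
            write_ascii_grid(r, out / f"{name}_{year}.asc")
    return report, rasters


def run_scenarios(
    scenarios: Sequence[ScenarioSpec],
    config: ZoningConfig = ZoningConfig(),
    out_dir=None,
) -> dict:
    """Run the geostatistical pathway on climate-projection layers.

    Each scenario layer (pathway × horizon) is processed exactly like a
    historical year: THI and DMP per point, variogram fitting/selection,
    kriged surfaces, and a summary table.  Returns a mapping
    ``label -> LayerResult`` (label = ``<pathway>_<horizon>``).
    """
    results = {}
    for spec in scenarios:
        pts = spec.fields.reset_index(drop=True)
        layer = _analyze_layer(
            spec.label, pts, pts["tmed_c"].to_numpy(), pts["ws_ms"].to_numpy(), config
        )
        results[spec.label] = layer
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for name, r in layer.rasters.items():
                write_ascii_grid(r, out / f"{name}_{spec.label}.asc")
            summary = pd.DataFrame(
                [
                    {
                        "scenario": spec.label,
                        "period": spec.period,
                        "np_level": np_level,
                        "mean_dmp": float(np.mean(d)),
                        "max_dmp": float(np.max(d)),
                    }
                    for np_level, d in layer.dmp_points.items()
                ]
            )
            summary.to_csv(out / f"dmp_summary_{spec.label}.csv", index=False)
    return results


def read_points(path) -> ClimateField:
    """Read a climate field from a CSV point table or a NetCDF grid."""
    p = Path(path)
    if p.suffix.lower() in (".nc", ".nc4", ".cdf"):
        return ClimateField.from_netcdf(p)
    return ClimateField.from_csv(p)


def write_report(report: ZoningReport, out_dir) -> None:
    """Write report tables as CSV plus a JSON run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.thi_stats.to_csv(out / "thi_stats.csv", index=False)
    report.model_summary.to_csv(out / "model_summary.csv", index=False)
    report.dsd_table.to_csv(out / "dsd_table.csv", index=False)
    report.area_fractions.to_csv(out / "area_fractions.csv", index=False)
    report.dmp_summary.to_csv(out / "dmp_summary.csv", index=False)
    if report.spi:
        for region, series in report.spi.items():
            series.table.to_csv(out / f"spi_{region}.csv", index=False)
    cfg = asdict(report.config)
    cfg["families"] = list(cfg["families"])
    cfg["np_levels"] = list(cfg["np_levels"])
    summary = {
        "thi_formula": report.thi_formula,
        "metric": report.metric,
        "config": cfg,
        "years": report.thi_stats["year"].tolist(),
        "selected_models": report.model_summary.loc[
            report.model_summary["selected"], ["year", "family"]
        ].to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
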