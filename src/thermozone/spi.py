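"""Standardized Precipitation Index (SPI) on annual precipitation totals.

The SPI expresses a precipitation amount as the standard-normal quantile of
its cumulative probability under a gamma distribution fitted to a reference
series by maximum likelihood: SPI = Φ⁻¹(H(x)) with
H(x) = q₀ + (1 − q₀)·F_gamma(x), where q₀ is the fraction of
zero-precipitation observations (the mixed-distribution treatment needed
because the gamma law has no mass at zero).  Negative SPI means drier than
typical; the seven-band classification runs from "Extremely Dry" (≤ −2)
to "Extremely Wet" (≥ 2).

Annual (12-month accumulation) totals are the working scale here; zeros are
rare at that scale, so the default path has q₀ = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UnfittableSeriesError

#: SPI classification bands, implemented as contiguous intervals at the
#: conventional cut points (−2, −1, −0.5, 0.5, 1, 2) so that every finite
#: value classifies.  Boundary membership follows the printed convention:
#: −2 → Extremely Dry, −1 → Very Dry, −0.5 → Moderately Dry,
#: 0.5 → Moderately Wet, 1 → Very Wet, 2 → Extremely Wet.
SPI_CLASSES = (
    "Extremely Dry",
    "Very Dry",
    "Moderately Dry",
    "Near Normal",
    "Moderately Wet",
    "Very Wet",
    "Extremely Wet",
)

_MIN_POSITIVE = 10


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma fit of a precipitation series.

    Attributes
    ----------
    alpha : float
        Shape parameter (> 0).
    beta : float
        Scale parameter (> 0, mm).
    q_zero : float
        Fraction of zero-precipitation observations in [0, 1).
    n : int
        Total number of observations used.
    """

    alpha: float
    beta: float
    q_zero: float
    n: int

    def cdf(self, x):
        """Mixed CDF H(x) = q₀ + (1 − q₀)·F_gamma(x) for x ≥ 0."""
        return self.q_zero + (1.0 - self.q_zero) * stats.gamma.cdf(
            x, a=self.alpha, scale=self.beta
        )


@dataclass(frozen=True)
class SPISeries:
    """Per-year SPI values with drought/wet class labels."""

    table: pd.DataFrame  # columns: year, precip_mm, spi, spi_class
    fit: GammaFit

    @property
    def spi(self) -> pd.Series:
        return self.table.set_index("year")["spi"]

    @property
    def classes(self) -> pd.Series:
        return self.table.set_index("year")["spi_class"]


def fit_gamma_mle(values) -> GammaFit:
    """Fit a gamma distribution to precipitation amounts by maximum likelihood.

    Zero values are separated out into the mixture weight ``q_zero``; the
    gamma parameters are fitted on the strictly positive remainder, which
    must contain at least 10 values with nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("precipitation values must be finite")
    if np.any(x < 0):
        raise InvalidInputError("precipitation values cannot be negative")
    pos = x[x > 0]
    n = x.size
    if pos.size < _MIN_POSITIVE:
        raise UnfittableSeriesError(
            f"need at least {_MIN_POSITIVE} positive values to fit a gamma law, got {pos.size}"
        )
    if np.std(pos) == 0:
        raise UnfittableSeriesError("all positive values are equal; gamma fit is degenerate")
    alpha, _, beta = stats.gamma.fit(pos, floc=0.0)
    return GammaFit(alpha=float(alpha), beta=float(beta), q_zero=float((n - pos.size) / n), n=n)


def _as_series(series) -> pd.Series:
    if isinstance(series, pd.Series):
        return series.astype(float)
    if isinstance(series, Mapping):
        return pd.Series(series, dtype=float)
    raise InvalidInputError("series must be a pandas Series or a year→precip mapping")


def compute_spi(series, reference=None) -> SPISeries:
    """SPI for each year of an annual precipitation series.

    Parameters
    ----------
    series : pandas Series or mapping, year → precipitation (mm)
        Years to evaluate.
    reference : optional, same type
        Series used to fit the gamma distribution; defaults to ``series``
        itself (the self-referenced SPI used for within-record anomaly
        analysis).
    """
    s = _as_series(series)
    ref = s if reference is None else _as_series(reference)
    fit = fit_gamma_mle(ref.to_numpy())
    h = np.clip(fit.cdf(s.to_numpy()), 1e-12, 1 - 1e-12)
    spi = stats.norm.ppf(h)
    table = pd.DataFrame(
        {
            "year": s.index.to_numpy(),
            "precip_mm": s.to_numpy(),
            "spi": spi,
            "spi_class": classify_spi(spi),
        }
    )
    return SPISeries(table=table, fit=fit)


def classify_spi(spi) -> Union[str, np.ndarray]:
    """Seven-band SPI classification.

    Bands (boundary membership as printed): ≥ 2 Extremely Wet; [1, 2) Very
    Wet; [0.5, 1) Moderately Wet; (−0.5, 0.5) Near Normal; (−1, −0.5]
    Moderately Dry; (−2, −1] Very Dry; ≤ −2 Extremely Dry.
    """
    spi_a = np.asarray(spi, dtype=float)
    if not np.all(np.isfinite(spi_a)):
        raise InvalidInputError("SPI values must be finite")
    out = np.select(
        [
            spi_a >= 2.0,
            spi_a >= 1.0,
            spi_a >= 0.5,
            spi_a > -0.5,
            spi_a > -1.0,
            spi_a > -2.0,
        ],
        [
            "Extremely Wet",
            "Very Wet",
            "Moderately Wet",
            "Near Normal",
            "Moderately Dry",
            "Very Dry",
        ],
        default="Extremely Dry",
    )
    return str(out[()]) if np.isscalar(spi) else out.astype(object)


def aggregate_spi_by_region(points: pd.DataFrame, region_col: str = "region") -> dict:
    """Regional and whole-domain SPI from a point table.

    For each region the annual precipitation series is the region-mean
    precipitation per year; the SPI is then fitted on that regional series.
    The key ``"all"`` holds the series computed on the domain-wide mean.

    Parameters
    ----------
    points : DataFrame
        Long-format table with at least ``year``, ``precip_mm`` and the
        ``region_col`` column; every point must carry a region label.
    """
    required = {"year", "precip_mm", region_col}
    missing = required - set(points.columns)
    if missing:
        raise InvalidInputError(f"point table is missing columns: {sorted(missing)}")
    if points[region_col].isna().any():
        raise InvalidInputError("every point must be assigned to exactly one region")
    out: dict = {}
    for region, grp in points.groupby(region_col, sort=True):
        if grp.empty:
            continue
        series = grp.groupby("year")["precip_mm"].mean()
        out[str(region)] = compute_spi(series)
    out["all"] = compute_spi(points.groupby("year")["precip_mm"].mean())
    return out
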