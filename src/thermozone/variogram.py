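"""Experimental semivariograms and parametric variogram models.

The experimental semivariogram estimates spatial dependence as
γ(h) = 1/(2N(h)) Σ [Z(xᵢ) − Z(xᵢ+h)]² over point pairs binned by
separation distance.  Three isotropic model families are fitted to it —
spherical, exponential and gaussian — parameterized by nugget C0, partial
sill C and range a, with the "practical range" convention for the
exponential/gaussian families (the factor 3 in the exponent, so γ reaches
≈95% of the sill at h = a).

Fitting is weighted least squares with weights N(h), the pair counts —
well-populated lags constrain the fit more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .errors import DegenerateGeometryError, InvalidInputError, NoSpatialStructureWarning

FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic variogram model γ(h).

    Attributes
    ----------
    family : str
        One of ``spherical``, ``exponential``, ``gaussian``.
    nugget : float
        C0 ≥ 0, semivariance discontinuity at the origin (micro-scale
        variation plus measurement error).
    partial_sill : float
        C ≥ 0; the sill is ``nugget + partial_sill``.
    range_a : float
        a > 0, distance (in coordinate units) at which the sill is reached
        (spherical) or effectively reached (exponential/gaussian).
    diagnostics : dict or None
        Fit diagnostics (weighted SSE, number of lags) when produced by
        :func:`fit_variogram`.
    """

    family: str
    nugget: float
    partial_sill: float
    range_a: float
    diagnostics: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidInputError(f"unknown variogram family {self.family!r}")
        if not (np.isfinite(self.nugget) and self.nugget >= 0):
            raise InvalidInputError("nugget must be finite and >= 0")
        if not (np.isfinite(self.partial_sill) and self.partial_sill >= 0):
            raise InvalidInputError("partial sill must be finite and >= 0")
        if not (np.isfinite(self.range_a) and self.range_a > 0):
            raise InvalidInputError("range must be finite and > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def semivariance(self, h):
        return model_semivariance(self, h)

    def covariance(self, h):
        """Stationary covariance C(h) = sill − γ(h); C(0) = sill."""
        return self.sill - model_semivariance(self, h)


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned experimental semivariogram.

    ``gamma_hat`` is NaN for empty bins (``pair_counts == 0``).
    """

    lag_centers: np.ndarray
    gamma_hat: np.ndarray
    pair_counts: np.ndarray
    max_dist: float

    @property
    def occupied(self) -> np.ndarray:
        return self.pair_counts > 0


def model_semivariance(model: VariogramModel, h):
    """Model semivariance γ(h) for h ≥ 0; γ(0) = 0 exactly.

    The nugget is a discontinuity at the origin: any h > 0 includes C0.
    """
    h_a = np.asarray(h, dtype=float)
    if np.any(h_a < 0):
        raise InvalidInputError("separation distance must be non-negative")
    c0, c, a = model.nugget, model.partial_sill, model.range_a
    if model.family == "spherical":
        r = np.minimum(h_a / a, 1.0)
        g = c0 + c * (1.5 * r - 0.5 * r**3)
    elif model.family == "exponential":
        g = c0 + c * (1.0 - np.exp(-3.0 * h_a / a))
    else:  # gaussian
        g = c0 + c * (1.0 - np.exp(-3.0 * h_a**2 / a**2))
    g = np.where(h_a == 0.0, 0.0, g)
    return float(g[()]) if np.isscalar(h) else g


def empirical_semivariogram(
    coords,
    values,
    n_lags: int = 12,
    max_dist: Optional[float] = None,
) -> EmpiricalVariogram:
    """Experimental semivariogram by equal-width distance binning.

    Parameters
    ----------
    coords : (n, d) array
        Point coordinates in a Euclidean space (see :mod:`thermozone.coords`).
    values : (n,) array
        Observed values Z(xᵢ).
    n_lags : int
        Number of equal-width bins.
    max_dist : float, optional
        Upper cutoff; defaults to half the maximum pairwise distance, the
        conventional choice beyond which lags are poorly populated.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.ndim != 2 or coords.shape[0] != values.shape[0]:
        raise InvalidInputError("coords must be (n, d) matching values of length n")
    n = coords.shape[0]
    if n < 2:
        raise InvalidInputError("need at least two points")
    if n_lags < 1:
        raise InvalidInputError("n_lags must be >= 1")
    d = pdist(coords)
    dmax = d.max()
    if dmax == 0:
        raise DegenerateGeometryError("all points coincide; semivariogram undefined")
    if max_dist is None:
        max_dist = dmax / 2.0
    if max_dist <= 0:
        raise InvalidInputError("max_dist must be > 0")

    # half squared difference per pair, same condensed ordering as pdist
    sq = pdist(values[:, None], metric="sqeuclidean") / 2.0
    width = max_dist / n_lags
    keep = d <= max_dist
    idx = np.minimum((d[keep] / width).astype(int), n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=sq[keep], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / counts
    gamma[counts == 0] = np.nan
    centers = (np.arange(n_lags) + 0.5) * width
    return EmpiricalVariogram(
        lag_centers=centers,
        gamma_hat=gamma,
        pair_counts=counts,
        max_dist=float(max_dist),
    )


def fit_variogram(emp: EmpiricalVariogram, family: str) -> VariogramModel:
    """Fit one model family to an experimental semivariogram.

    Minimizes the pair-count-weighted squared error between ``gamma_hat``
    and the model curve over (C0, C, a) with C0 ≥ 0, C ≥ 0, a > 0, using a
    small multi-start on the range to avoid local minima.  Fit diagnostics
    (weighted SSE, lag count) are attached to the returned model.

    A flat empirical variogram yields a (near) pure-nugget model and emits
    :class:`NoSpatialStructureWarning`.
    """
    if family not in FAMILIES:
        raise InvalidInputError(f"unknown variogram family {family!r}")
    occ = emp.occupied
    h = emp.lag_centers[occ]
    g = emp.gamma_hat[occ]
    w = np.sqrt(emp.pair_counts[occ].astype(float))
    if h.size < 4:
        raise InvalidInputError("need at least 4 occupied lags to fit a variogram")

    g_min, g_max = float(g.min()), float(g.max())
    spread = max(g_max - g_min, 1e-12 * max(abs(g_max), 1.0))
    h_max = float(h.max())

    def residuals(theta, fam):
        m = VariogramModel(fam, max(theta[0], 0.0), max(theta[1], 0.0), max(theta[2], 1e-12))
        return w * (model_semivariance(m, h) - g)

    best = None
    for a0_frac in (0.25, 0.5, 1.0):
        x0 = np.array([max(g_min, 0.0), spread, a0_frac * h_max])
        try:
            sol = least_squares(
                residuals,
                x0,
                args=(family,),
                bounds=([0.0, 0.0, 1e-12 * h_max if h_max > 0 else 1e-12], np.inf),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise InvalidInputError("variogram fit failed for all starting points")

    c0, c, a = best.x
    wsse = float(2 * best.cost)
    model = VariogramModel(
        family,
        float(max(c0, 0.0)),
        float(max(c, 0.0)),
        float(max(a, 1e-12)),
        diagnostics={"wsse": wsse, "n_lags": int(h.size)},
    )
    if model.sill > 0 and model.partial_sill < 1e-6 * model.sill:
        warnings.warn(
            "empirical variogram is flat: fitted model is (near) pure nugget, "
            "no spatial structure detected",
            NoSpatialStructureWarning,
            stacklevel=2,
        )
    return model
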