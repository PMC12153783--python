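"""Cross-validation of kriging models, model selection, and spatial-dependence class.

Leave-one-out cross-validation holds each sample out in turn, predicts it by
ordinary kriging from the remaining samples, and summarizes the errors with
five metrics:

- ME    mean error, mean(Ẑ − Z)
- MSE   mean standardized error, mean((Ẑ − Z)/σ₁) — a *mean of standardized
        errors*, not a mean of squares (named to match field usage)
- ASE   average standard error, mean(σ₁)
- RMSE  root mean square error
- RMSSE root mean square standardized error; ≈ 1 indicates the kriging
        standard errors σ₁ are well calibrated

Model selection formalizes the usual reading of these diagnostics: pick the
family whose RMSSE is closest to 1; break ties by |RMSE − ASE|, then RMSE,
then a fixed family order.

The degree of spatial dependence (DSD) is the nugget-to-sill ratio in
percent, classed strong (< 25%), moderate (25–75%), weak (> 75%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .kriging import ordinary_kriging
from .variogram import VariogramModel

FAMILY_ORDER = ("spherical", "exponential", "gaussian")

DSD_CLASSES = ("strong", "moderate", "weak")


@dataclass(frozen=True)
class CrossValidation:
    """Leave-one-out cross-validation metrics for one model/dataset."""

    me: float
    mse: float
    ase: float
    rmse: float
    rmsse: float
    n: int

    def as_dict(self) -> dict:
        return {
            "me": self.me,
            "mse": self.mse,
            "ase": self.ase,
            "rmse": self.rmse,
            "rmsse": self.rmsse,
            "n": self.n,
        }


@dataclass(frozen=True)
class SpatialDependence:
    """Nugget-to-sill ratio (%) and its Cambardella-style class."""

    dsd_percent: float
    dsd_class: str


@dataclass(frozen=True)
class ModelSelection:
    """Selected family plus the full ranking table."""

    family: str
    ranking: pd.DataFrame


@dataclass(frozen=True)
class NormalityTest:
    """Shapiro–Wilk test of residual normality."""

    statistic: float
    p_value: float
    non_normal: bool  # True when p < 0.05


def cross_validation_metrics(observed, predicted, std_errors) -> CrossValidation:
    """The five metrics from held-out observations, predictions and σ₁."""
    z = np.asarray(observed, dtype=float)
    zhat = np.asarray(predicted, dtype=float)
    s1 = np.asarray(std_errors, dtype=float)
    if not (z.shape == zhat.shape == s1.shape):
        raise InvalidInputError("observed, predicted and std_errors must align")
    if z.size < 2:
        raise InvalidInputError("need at least two held-out points")
    if np.any(s1 <= 0):
        raise InvalidInputError(
            "zero kriging standard error during standardization; use a nonzero "
            "nugget or deduplicate points"
        )
    err = zhat - z
    std = err / s1
    return CrossValidation(
        me=float(err.mean()),
        mse=float(std.mean()),
        ase=float(s1.mean()),
        rmse=float(np.sqrt((err**2).mean())),
        rmsse=float(np.sqrt((std**2).mean())),
        n=int(z.size),
    )


def loo_cross_validate(
    coords,
    values,
    model: VariogramModel,
    n_neighbors: Optional[int] = 16,
) -> CrossValidation:
    """Leave-one-out cross-validation of ordinary kriging under ``model``.

    Each point is predicted from all other points (restricted to the
    ``n_neighbors`` nearest, as in production kriging).
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 3:
        raise InvalidInputError("leave-one-out requires at least three points")
    predicted = np.empty(n)
    sigma = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        pred = ordinary_kriging(
            model, coords[mask], values[mask], coords[i][None, :], n_neighbors=n_neighbors
        )
        predicted[i] = pred.estimate[0]
        sigma[i] = pred.std_error[0]
        mask[i] = True
    return cross_validation_metrics(values, predicted, sigma)


def select_model(candidates: Mapping[str, CrossValidation], rmsse_tol: float = 1e-6) -> ModelSelection:
    """Pick the variogram family with best-calibrated errors.

    Rule: minimize |RMSSE − 1|; ties within ``rmsse_tol`` broken by smaller
    |RMSE − ASE|, then smaller RMSE, then the fixed order
    spherical → exponential → gaussian.
    """
    if not candidates:
        raise InvalidInputError("no candidate models to select from")
    rows = []
    for fam, cv in candidates.items():
        fam_rank = FAMILY_ORDER.index(fam) if fam in FAMILY_ORDER else len(FAMILY_ORDER)
        rows.append(
            {
                "family": fam,
                "rmsse": cv.rmsse,
                "abs_rmsse_dev": abs(cv.rmsse - 1.0),
                "abs_rmse_ase_gap": abs(cv.rmse - cv.ase),
                "rmse": cv.rmse,
                "ase": cv.ase,
                "me": cv.me,
                "mse": cv.mse,
                "_order": fam_rank,
            }
        )
    table = pd.DataFrame(rows)
    # quantize the primary key so near-ties fall through to the gap criterion
    table["_dev_q"] = np.round(table["abs_rmsse_dev"] / rmsse_tol).astype(np.int64)
    table = table.sort_values(
        ["_dev_q", "abs_rmse_ase_gap", "rmse", "_order"], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["selected"] = table["rank"] == 1
    selected = str(table.loc[0, "family"])
    return ModelSelection(
        family=selected, ranking=table.drop(columns=["_order", "_dev_q"])
    )


def compute_dsd(model: VariogramModel) -> SpatialDependence:
    """Degree of spatial dependence: 100·C0/(C0+C), classed per Cambardella."""
    sill = model.sill
    if sill <= 0:
        raise InvalidInputError("total sill must be positive to compute DSD")
    pct = 100.0 * model.nugget / sill
    if pct < 25.0:
        cls = "strong"
    elif pct <= 75.0:
        cls = "moderate"
    else:
        cls = "weak"
    return SpatialDependence(dsd_percent=float(pct), dsd_class=cls)


def residual_normality(values) -> NormalityTest:
    """Shapiro–Wilk test; residuals are flagged non-normal when p < 0.05.

    Supported for sample sizes 3 ≤ n ≤ 5000.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("residuals must be finite")
    if not (3 <= x.size <= 5000):
        raise InvalidInputError("Shapiro–Wilk supported for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise InvalidInputError("constant sample: normality test undefined")
    stat, p = stats.shapiro(x)
    return NormalityTest(statistic=float(stat), p_value=float(p), non_normal=bool(p < 0.05))
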