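"""Ordinary kriging: best linear unbiased spatial prediction.

The estimate at a target x₀ is Ẑ(x₀) = Σ λᵢ Z(xᵢ) with weights λ solving
the ordinary-kriging system

    [ Γ  1 ] [ λ ]   [ γ₀ ]
    [ 1ᵀ 0 ] [ μ ] = [ 1  ]

where Γᵢⱼ = γ(‖xᵢ−xⱼ‖) is the model semivariance between samples, γ₀ the
vector of semivariances between samples and target, and μ the Lagrange
multiplier enforcing Σλᵢ = 1 (unbiasedness).  The kriging variance is
σ² = λᵀγ₀ + μ.

Prediction is local by default: only the ``n_neighbors`` nearest samples
enter each system, which keeps large grids tractable; ``n_neighbors=None``
uses every sample (global kriging).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import InvalidInputError, SingularKrigingSystemError
from .variogram import VariogramModel, model_semivariance

WEIGHT_SUM_TOL = 1e-8


@dataclass(frozen=True)
class KrigingPrediction:
    """Ordinary-kriging output at one or more targets.

    Attributes
    ----------
    estimate : (m,) ndarray
        Predicted values Ẑ(x₀).
    std_error : (m,) ndarray
        Kriging standard errors σ ≥ 0.
    weights : (m, k) ndarray
        Weights λ per neighbor (k = neighborhood size).
    neighbor_idx : (m, k) ndarray
        Indices into the sample arrays of each target's neighbors.
    """

    estimate: np.ndarray
    std_error: np.ndarray
    weights: np.ndarray
    neighbor_idx: np.ndarray


def _solve_ok_system(gamma_nn: np.ndarray, gamma_0: np.ndarray):
    """Solve one ordinary-kriging system; returns (weights, sigma2)."""
    k = gamma_nn.shape[0]
    a = np.empty((k + 1, k + 1))
    a[:k, :k] = gamma_nn
    a[k, :k] = 1.0
    a[:k, k] = 1.0
    a[k, k] = 0.0
    b = np.empty(k + 1)
    b[:k] = gamma_0
    b[k] = 1.0
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise SingularKrigingSystemError(
            "singular kriging system (duplicate sample locations with zero "
            "nugget?); deduplicate samples or add a small nugget"
        ) from exc
    lam = sol[:k]
    mu = sol[k]
    sigma2 = float(lam @ gamma_0 + mu)
    return lam, max(sigma2, 0.0)


def ordinary_kriging(
    model: VariogramModel,
    coords,
    values,
    targets,
    n_neighbors: Optional[int] = 16,
) -> KrigingPrediction:
    """Predict at target locations by ordinary kriging.

    Parameters
    ----------
    model : VariogramModel
        Fitted variogram model in the same distance units as ``coords``.
    coords : (n, d) array
        Sample coordinates (Euclidean space; see :mod:`thermozone.coords`).
    values : (n,) array
        Sample values.
    targets : (m, d) array
        Prediction locations.
    n_neighbors : int or None
        Neighborhood size for local kriging; ``None`` (or ≥ n) solves each
        system with all samples.  Equidistant neighbors at the cutoff are
        broken by ascending sample index so results are deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if coords.ndim != 2 or coords.shape[0] != values.shape[0]:
        raise InvalidInputError("coords must be (n, d) matching values of length n")
    n = coords.shape[0]
    if n < 2:
        raise InvalidInputError("need at least two samples to krige")
    if targets.shape[1] != coords.shape[1]:
        raise InvalidInputError("targets and coords must share the coordinate dimension")
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("sample values must be finite")

    k = n if n_neighbors is None else min(int(n_neighbors), n)
    if k < 2:
        raise InvalidInputError("neighborhood must contain at least two samples")
    m = targets.shape[0]

    if k == n:
        neighbor_idx = np.broadcast_to(np.arange(n), (m, n)).copy()
        dist_t = cdist(targets, coords)
    else:
        tree = cKDTree(coords)
        dist_t, neighbor_idx = tree.query(targets, k=k)
        dist_t = np.atleast_2d(dist_t)
        neighbor_idx = np.atleast_2d(neighbor_idx)
        # stable tie-break: among equal distances, prefer smaller sample index
        order = np.lexsort((neighbor_idx, np.round(dist_t, 12)), axis=1)
        neighbor_idx = np.take_along_axis(neighbor_idx, order, axis=1)
        dist_t = np.take_along_axis(dist_t, order, axis=1)

    estimate = np.empty(m)
    std_error = np.empty(m)
    weights = np.empty((m, k))

    # cache factorization work per unique neighbor set
    gamma_cache: dict[bytes, np.ndarray] = {}
    for j in range(m):
        idx = neighbor_idx[j]
        key = idx.tobytes()
        gamma_nn = gamma_cache.get(key)
        if gamma_nn is None:
            sub = coords[idx]
            gamma_nn = model_semivariance(model, cdist(sub, sub))
            gamma_cache[key] = gamma_nn
        gamma_0 = model_semivariance(model, dist_t[j])
        lam, sigma2 = _solve_ok_system(gamma_nn, gamma_0)
        if abs(lam.sum() - 1.0) > 1e-6:
            raise SingularKrigingSystemError(
                "kriging weights failed the unbiasedness constraint; the "
                "system is ill-conditioned"
            )
        weights[j] = lam
        estimate[j] = lam @ values[idx]
        std_error[j] = np.sqrt(sigma2)

    return KrigingPrediction(
        estimate=estimate,
        std_error=std_error,
        weights=weights,
        neighbor_idx=neighbor_idx,
    )
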