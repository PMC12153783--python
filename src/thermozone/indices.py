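"""Thermal-stress indices and categorical classifications for cattle.

The core quantity is the annual Temperature–Humidity Index (THI) computed
from mean air temperature (°C) and mean wind speed (m s⁻¹), and the decrease
in milk production (DMP, kg day⁻¹ cow⁻¹) it implies for a cow of a given
potential production level NP under thermal comfort.  Heat-stress categories
follow the Livestock Weather Safety Index (LWSI) and the dairy-specific
onset thresholds used in bioclimatic zoning studies.

THI formulas are kept in a registry because published THI variants differ
in which meteorological drivers they include and how; every pipeline output
records which formula produced it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .errors import InvalidInputError

ArrayLike = Union[float, np.ndarray]

#: Registry of named THI formulas, each ``f(tair, ws) -> thi``.
THI_FORMULAS: dict[str, Callable] = {}

#: Default THI formula: linear in air temperature with a quadratic
#: wind-speed adjustment, THI = 6.3952 + 0.08964·Tair + 0.01018·Ws².
DEFAULT_THI_FORMULA = "tair_ws2"

# LWSI category cut points (Mader-style): normal ≤ 74 < alert < 79 ≤ danger < 84 ≤ emergency
LWSI_CLASSES = ("normal", "alert", "danger", "emergency")
# Dairy-cattle stress onsets: moderate at 72, high at 79, extreme at 89 (inclusive)
DAIRY_CLASSES = ("none", "moderate", "high", "extreme")
DAIRY_ONSETS = (72.0, 79.0, 89.0)
# Coefficient-of-variation dispersion bands (%): low < 12 ≤ medium ≤ 24 < high
CV_CLASSES = ("low", "medium", "high")


def register_thi_formula(name: str):
    """Decorator registering a THI formula under ``name``."""

    def _register(fn):
        THI_FORMULAS[name] = fn
        return fn

    return _register


@register_thi_formula("tair_ws2")
def _thi_tair_ws2(tair, ws):
    return 6.3952 + 0.08964 * tair + 0.01018 * ws**2


@dataclass(frozen=True)
class MilkLoss:
    """Milk-production decrease for one potential production level.

    Attributes
    ----------
    np_level : float
        Potential production under thermal comfort, NP (kg day⁻¹ cow⁻¹).
    dmp_raw : float or ndarray
        Raw regression value; may be negative below the stress threshold.
    dmp : float or ndarray
        Reported loss, ``max(dmp_raw, 0)`` — a production *decrease* cannot
        be negative.
    """

    np_level: float
    dmp_raw: ArrayLike
    dmp: ArrayLike


def _validate_finite(name: str, x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise InvalidInputError(f"{name} contains non-finite values")


def compute_thi(tair: ArrayLike, ws: ArrayLike, formula: str = DEFAULT_THI_FORMULA) -> ArrayLike:
    """Temperature–Humidity Index from air temperature and wind speed.

    Parameters
    ----------
    tair : float or array
        Mean air temperature (°C).
    ws : float or array
        Mean wind speed (m s⁻¹); must be non-negative.
    formula : str
        Name of a registered THI formula (default :data:`DEFAULT_THI_FORMULA`).
    """
    tair_a = np.asarray(tair, dtype=float)
    ws_a = np.asarray(ws, dtype=float)
    _validate_finite("tair", tair_a)
    _validate_finite("ws", ws_a)
    if np.any(ws_a < 0):
        raise InvalidInputError("wind speed must be non-negative")
    try:
        fn = THI_FORMULAS[formula]
    except KeyError:
        raise InvalidInputError(
            f"unknown THI formula {formula!r}; registered: {sorted(THI_FORMULAS)}"
        ) from None
    out = fn(tair_a, ws_a)
    if np.isscalar(tair) and np.isscalar(ws):
        return float(out)
    return out


def compute_dmp(np_level: float, thi: ArrayLike) -> MilkLoss:
    """Decrease in milk production from the DMP regression.

    ``dmp_raw = −1.075 − 1.736·NP + 0.02474·NP·THI``; the reported ``dmp``
    is clamped at zero.

    Parameters
    ----------
    np_level : float
        Potential production NP (kg day⁻¹ cow⁻¹); must be ≥ 0.  The
        production settings used for regional zoning are NP = 10 (PL10)
        and NP = 25 (PL25).
    thi : float or array
        Temperature–Humidity Index.
    """
    if not np.isfinite(np_level) or np_level < 0:
        raise InvalidInputError("np_level must be a finite non-negative production level")
    thi_a = np.asarray(thi, dtype=float)
    _validate_finite("thi", thi_a)
    raw = -1.075 - 1.736 * np_level + 0.02474 * np_level * thi_a
    clamped = np.maximum(raw, 0.0)
    if np.isscalar(thi):
        return MilkLoss(np_level=float(np_level), dmp_raw=float(raw), dmp=float(clamped))
    return MilkLoss(np_level=float(np_level), dmp_raw=raw, dmp=clamped)


def classify_lwsi(thi: ArrayLike) -> Union[str, np.ndarray]:
    """Livestock Weather Safety Index category for a THI value.

    normal (THI ≤ 74), alert (74 < THI < 79), danger (79 ≤ THI < 84),
    emergency (THI ≥ 84).
    """
    thi_a = np.asarray(thi, dtype=float)
    _validate_finite("thi", thi_a)
    out = np.select(
        [thi_a <= 74.0, thi_a < 79.0, thi_a < 84.0],
        ["normal", "alert", "danger"],
        default="emergency",
    )
    return str(out[()]) if np.isscalar(thi) else out.astype(object)


def classify_dairy_stress(thi: ArrayLike) -> Union[str, np.ndarray]:
    """Dairy-cattle heat-stress category for a THI value.

    Onset thresholds (inclusive lower bounds): moderate at 72, high at 79,
    extreme at 89; below 72 there is no heat stress.
    """
    thi_a = np.asarray(thi, dtype=float)
    _validate_finite("thi", thi_a)
    m, h, e = DAIRY_ONSETS
    out = np.select(
        [thi_a < m, thi_a < h, thi_a < e],
        ["none", "moderate", "high"],
        default="extreme",
    )
    return str(out[()]) if np.isscalar(thi) else out.astype(object)


def classify_cv(cv_percent: ArrayLike) -> Union[str, np.ndarray]:
    """Dispersion class for a coefficient of variation (%).

    low (CV < 12), medium (12 ≤ CV ≤ 24), high (CV > 24).
    """
    cv_a = np.asarray(cv_percent, dtype=float)
    _validate_finite("cv_percent", cv_a)
    if np.any(cv_a < 0):
        raise InvalidInputError("coefficient of variation cannot be negative")
    out = np.select([cv_a < 12.0, cv_a <= 24.0], ["low", "medium"], default="high")
    return str(out[()]) if np.isscalar(cv_percent) else out.astype(object)
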