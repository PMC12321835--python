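"""Canopy light interception and dry-matter production.

Daily dry-matter production follows the classical light-use-efficiency
chain: half of the daily solar radiation integral is photosynthetically
active (PAR); the canopy intercepts the Beer-Lambert fraction
``1 - exp(-k * LAI)`` of it (or, when a camera-derived interception fraction
iLAI is available, simply ``PAR * iLAI`` with no extinction coefficient);
and each MJ of intercepted PAR is converted to LUE grams of above-ground
dry matter.

LUE itself is calibrated as the slope of an ordinary least-squares
regression of cumulative above-ground dry matter on cumulative intercepted
PAR across destructive-sampling dates (free intercept, because the stand
starts from a nonzero transplant dry mass).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np

from .errors import EstimationError, InputError
from .params import ModelParameters

__all__ = [
    "CalibrationPoint",
    "par_from_radiation",
    "intercepted_light",
    "intercepted_light_ilai",
    "dm_production",
    "estimate_lue",
]


class CalibrationPoint(NamedTuple):
    """One destructive-sampling point for LUE calibration."""

    cum_par: float  #: cumulative intercepted PAR, MJ m^-2
    tdm: float  #: total above-ground dry matter, g m^-2


def par_from_radiation(sr, params: ModelParameters | None = None):
    """Photosynthetically active radiation from the daily solar integral.

    PAR = Sr * par_fraction (default 0.5). Accepts scalars or arrays.
    """
    params = params or ModelParameters()
    sr = np.asarray(sr, dtype=float)
    if np.any(sr < 0):
        raise InputError("solar radiation must be non-negative")
    out = sr * params.par_fraction
    return float(out) if out.ndim == 0 else out


def intercepted_light(par, lai, k: float):
    """Beer-Lambert intercepted PAR: I = PAR * (1 - exp(-k * LAI)).

    I is zero for a bare stand, strictly below PAR for finite LAI, and
    saturates to PAR as the canopy closes.
    """
    par = np.asarray(par, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(par < 0):
        raise InputError("PAR must be non-negative")
    if np.any(lai < 0):
        raise InputError("LAI must be non-negative")
    if k <= 0:
        raise InputError("extinction coefficient k must be positive")
    out = par * -np.expm1(-k * lai)
    return float(out) if out.ndim == 0 else out


def intercepted_light_ilai(par, ilai):
    """Intercepted PAR from a measured interception fraction: I = PAR * iLAI.

    iLAI is the camera-derived fraction of ground covered by light-intercepting
    leaf area; no extinction coefficient is involved. Values above 1 are
    clamped to 1 (the series loader already warns about them).
    """
    par = np.asarray(par, dtype=float)
    ilai = np.asarray(ilai, dtype=float)
    if np.any(par < 0):
        raise InputError("PAR must be non-negative")
    if np.any(ilai < 0):
        raise InputError("iLAI must be non-negative")
    out = par * np.minimum(ilai, 1.0)
    return float(out) if out.ndim == 0 else out


def dm_production(i, lue: float):
    """Daily dry-matter production: dDM = I * LUE (g m^-2 d^-1).

    The caller accumulates TDM_n = TDM_{n-1} + dDM_n starting from the
    transplant dry mass TDM_0.
    """
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise InputError("intercepted light must be non-negative")
    if lue <= 0:
        raise InputError("LUE must be positive")
    out = i * lue
    return float(out) if out.ndim == 0 else out


def estimate_lue(points: Iterable[CalibrationPoint | tuple[float, float]]) -> float:
    """LUE as the OLS slope of total dry matter on cumulative intercepted PAR.

    The fit has a free intercept: the calibration data start from the nonzero
    transplant dry mass, so forcing the line through the origin would bias the
    slope. Requires at least three points with non-identical abscissae and a
    positive slope (negative apparent LUE means the calibration data are not
    usable).

    Returns
    -------
    float
        The slope, g dry matter per MJ intercepted PAR.
    """
    pts = [CalibrationPoint(float(a), float(b)) for a, b in points]
    if len(pts) < 3:
        raise EstimationError("LUE calibration needs at least 3 points")
    x = np.array([p.cum_par for p in pts])
    y = np.array([p.tdm for p in pts])
    if np.any(x < 0) or np.any(y < 0):
        raise InputError("calibration points must be non-negative")
    if np.ptp(x) == 0:
        raise EstimationError("calibration abscissae are identical; slope undefined")
    slope, _ = np.polyfit(x, y, 1)
    if slope <= 0:
        raise EstimationError(f"non-positive LUE slope ({slope:.4g}); calibration invalid")
    return float(slope)
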