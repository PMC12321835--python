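"""Validation statistics for simulated-vs-observed trajectories.

RMSE, relative RMSE (RMSE divided by the observed mean), the coefficient of
determination, and the interval dry-matter distribution to fruit AF' --
the realized fruit fraction between two destructive-sampling dates,
(DF_{i+1} - DF_i) / ((TDM_{i+1} - TDM_i) / Pd), with fruit dry weight per
plant and total dry matter per ground area.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EstimationError, InputError

__all__ = [
    "PairedSeries",
    "IntervalObservation",
    "rmse",
    "rrmse",
    "r_squared",
    "interval_fruit_fraction",
]


@dataclass(frozen=True)
class PairedSeries:
    """Simulated and observed values matched by date (no interpolation)."""

    dates: tuple
    simulated: tuple
    observed: tuple

    def __post_init__(self) -> None:
        if not len(self.dates) == len(self.simulated) == len(self.observed):
            raise InputError("paired series must have equal lengths")


@dataclass(frozen=True)
class IntervalObservation:
    """One destructive measurement: total fruit DW per plant and total DM."""

    date: dt.date
    df: float  # g plant^-1
    tdm: float  # g m^-2

    def __post_init__(self) -> None:
        if self.df < 0 or self.tdm < 0:
            raise InputError("fruit DW and total DM must be non-negative")


def _pair(simulated, observed) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(simulated, dtype=float)
    o = np.asarray(observed, dtype=float)
    if s.size == 0:
        raise InputError("empty paired series")
    if s.shape != o.shape:
        raise InputError("simulated and observed series differ in length")
    return s, o


def rmse(simulated, observed) -> float:
    """Root mean squared error sqrt(mean((S - O)^2))."""
    s, o = _pair(simulated, observed)
    return float(np.sqrt(np.mean((s - o) ** 2)))


def rrmse(simulated, observed) -> float:
    """Relative RMSE: RMSE divided by the observed mean (which must be nonzero)."""
    s, o = _pair(simulated, observed)
    o_mean = float(np.mean(o))
    if o_mean == 0:
        raise EstimationError("observed mean is zero; RRMSE undefined")
    return rmse(s, o) / o_mean


def r_squared(simulated, observed, method: str = "determination") -> float:
    """Coefficient of determination of simulated against observed values.

    ``method="determination"`` (default): 1 - SSE/SST about the observed
    mean, which penalises bias as well as scatter. ``method="correlation"``:
    squared Pearson correlation, which only measures linear association.
    """
    s, o = _pair(simulated, observed)
    if s.size < 2:
        raise InputError("R^2 needs at least 2 points")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise EstimationError("observed variance is zero; R^2 undefined")
    if method == "determination":
        return 1.0 - float(np.sum((o - s) ** 2)) / sst
    if method == "correlation":
        return float(np.corrcoef(s, o)[0, 1] ** 2)
    raise InputError(f"unknown R^2 method {method!r}")


def interval_fruit_fraction(
    observations: Sequence[IntervalObservation | tuple],
    pd_: float,
) -> list[float]:
    """Realized dry-matter distribution to fruit over each sampling interval.

    For consecutive destructive measurements i and i+1:
    AF' = (DF_{i+1} - DF_i) / ((TDM_{i+1} - TDM_i) / Pd). Applies identically
    to observed data and to a simulated trajectory sampled at the same dates.

    Raises
    ------
    EstimationError
        If total dry matter does not strictly increase over some interval
        (named in the message); the denominator would vanish or flip sign.
    """
    obs = [
        o if isinstance(o, IntervalObservation) else IntervalObservation(*o)
        for o in observations
    ]
    if len(obs) < 2:
        raise InputError("need at least 2 observations for interval fractions")
    if pd_ <= 0:
        raise InputError("plant density must be positive")
    out = []
    for a, b in zip(obs, obs[1:]):
        dtdm = b.tdm - a.tdm
        if dtdm <= 0:
            raise EstimationError(
                f"total DM not increasing over interval {a.date}..{b.date}"
            )
        out.append((b.df - a.df) / (dtdm / pd_))
    return out
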