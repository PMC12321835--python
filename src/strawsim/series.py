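"""Dated input series: greenhouse climate, leaf area, flowering schedule.

The simulator runs on a strict daily grid. `EnvironmentSeries` therefore
requires one record per calendar day with no gaps; its first date is the
transplant date and defines DAT (days after transplanting) = 0.

Leaf area is observed sparsely (destructive LAI harvests every few weeks, or
weekly camera-derived iLAI) and linearly interpolated between observation
dates; outside the observation window the nearest observation is held
constant.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "EnvironmentDay",
    "EnvironmentSeries",
    "LeafAreaSeries",
    "FloweringSchedule",
]

#: Default plausibility window for greenhouse daily mean temperature, degC.
TEMP_PLAUSIBLE = (-5.0, 45.0)


@dataclass(frozen=True)
class EnvironmentDay:
    """One day of greenhouse climate: daily mean temperature and solar integral."""

    date: dt.date
    temp_mean: float  # degC
    sr: float  # MJ m^-2 d^-1

    def __post_init__(self) -> None:
        if self.sr < 0:
            raise InputError(f"negative solar radiation on {self.date}: {self.sr}")


class EnvironmentSeries:
    """Gap-free daily climate series; day 0 is the transplant date.

    Parameters
    ----------
    dates, temp_mean, sr
        Parallel sequences: strictly consecutive calendar dates, daily mean
        air temperature (degC) and daily solar radiation integral (MJ m^-2).
    temp_bounds
        Plausibility window for temperatures; values outside raise
        :class:`InputError`.
    """

    def __init__(
        self,
        dates: Sequence[dt.date],
        temp_mean: Iterable[float],
        sr: Iterable[float],
        temp_bounds: tuple[float, float] = TEMP_PLAUSIBLE,
    ) -> None:
        self.dates = list(dates)
        self.temp_mean = np.asarray(list(temp_mean), dtype=float)
        self.sr = np.asarray(list(sr), dtype=float)
        if not self.dates:
            raise InputError("climate series is empty")
        if not (len(self.dates) == len(self.temp_mean) == len(self.sr)):
            raise InputError("climate columns have unequal lengths")
        for prev, cur in zip(self.dates, self.dates[1:]):
            if (cur - prev).days != 1:
                raise InputError(
                    f"climate series has a gap or disorder between {prev} and {cur}"
                )
        if np.any(self.sr < 0):
            bad = self.dates[int(np.argmax(self.sr < 0))]
            raise InputError(f"negative solar radiation on {bad}")
        lo, hi = temp_bounds
        if np.any((self.temp_mean < lo) | (self.temp_mean > hi)):
            bad = self.dates[int(np.argmax((self.temp_mean < lo) | (self.temp_mean > hi)))]
            raise InputError(
                f"daily mean temperature outside plausibility window {temp_bounds} on {bad}"
            )

    @property
    def transplant_date(self) -> dt.date:
        return self.dates[0]

    def __len__(self) -> int:
        return len(self.dates)

    def __iter__(self):
        for d, t, s in zip(self.dates, self.temp_mean, self.sr):
            yield EnvironmentDay(d, float(t), float(s))

    def dat(self, date: dt.date) -> int:
        """Days after transplanting for a calendar date."""
        return (date - self.transplant_date).days


@dataclass
class LeafAreaSeries:
    """Sparse dated leaf-area observations with an interpolation mode.

    ``mode="lai"`` holds destructively measured leaf area index (m^2 m^-2);
    ``mode="ilai"`` holds camera-derived intercepted leaf area, used directly
    as the canopy light-interception fraction and therefore clamped to [0, 1]
    (values above 1 are clamped with a warning).
    """

    mode: Literal["lai", "ilai"]
    dates: list[dt.date]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) == 0:
            raise InputError("leaf-area series is empty")
        if len(self.dates) != len(self.values):
            raise InputError("leaf-area dates and values have unequal lengths")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise InputError("leaf-area observation dates must be strictly increasing")
        if np.any(self.values < 0):
            raise InputError("leaf-area values must be non-negative")
        if self.mode not in ("lai", "ilai"):
            raise InputError(f"unknown leaf-area mode {self.mode!r}")
        if self.mode == "ilai" and np.any(self.values > 1.0):
            warnings.warn(
                "iLAI values above 1 clamped to 1 (interception-fraction semantics)",
                stacklevel=2,
            )
            self.values = np.minimum(self.values, 1.0)

    def at(self, date: dt.date) -> float:
        """Leaf area on `date`: linear interpolation between observations,
        constant (nearest observation) outside the observed window."""
        x = np.array([d.toordinal() for d in self.dates], dtype=float)
        return float(np.interp(date.toordinal(), x, self.values))

    def on_dates(self, dates: Sequence[dt.date]) -> np.ndarray:
        x = np.array([d.toordinal() for d in self.dates], dtype=float)
        q = np.array([d.toordinal() for d in dates], dtype=float)
        return np.interp(q, x, self.values)


@dataclass(frozen=True)
class FloweringSchedule:
    """First-flower anthesis dates, one per inflorescence, ascending.

    Inflorescence q (1-based) opens its first flower on ``anthesis_dates[q-1]``;
    from that day the cluster accumulates post-anthesis degree-days.
    """

    anthesis_dates: tuple[dt.date, ...]

    def __init__(self, anthesis_dates: Sequence[dt.date]):
        object.__setattr__(self, "anthesis_dates", tuple(anthesis_dates))
        if any(
            b <= a
            for a, b in zip(self.anthesis_dates, self.anthesis_dates[1:])
        ):
            raise InputError("anthesis dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.anthesis_dates)

    def __iter__(self):
        return iter(self.anthesis_dates)
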