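"""Synthetic forcing-culture scenarios.

Generates complete, self-consistent model inputs with no external data:
a seasonal greenhouse climate (annual sinusoids plus truncated Gaussian
day-to-day noise), a flowering schedule (first anthesis ~55 days after the
mid-September transplant, successive inflorescences every ~53 days), a
logistic leaf-area rise from ~0.3 to ~3 m^2 m^-2, and optional top-down
canopy images with known green-cover fraction for exercising the
camera-based interception estimator.

Every generator is fully deterministic per seed. Defaults emulate the
Japanese forcing-culture season: transplant September 18, 220 days through
late April, daily mean temperatures within 9.8-25.5 degC, greenhouse solar
integrals within 1-18 MJ m^-2 d^-1 declining mid-winter.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.special import expit

from .errors import InputError, ScenarioError
from .series import EnvironmentSeries, FloweringSchedule, LeafAreaSeries

__all__ = [
    "ScenarioSpec",
    "CanopyImageSpec",
    "generate_climate",
    "generate_flowering_schedule",
    "generate_lai_trajectory",
    "generate_scenario",
    "render_canopy_image",
    "estimate_ilai_from_image",
]

_DAYS_PER_YEAR = 365.0


class ScenarioSpec(BaseModel):
    """Parameters of a synthetic forcing-culture season."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    transplant_date: dt.date = dt.date(2021, 9, 18)
    season_days: int = Field(default=220, gt=0)

    # daily mean air temperature: annual sinusoid + noise, clipped to bounds
    temp_mean: float = 17.65  # degC, annual mean inside the greenhouse
    temp_amplitude: float = Field(default=7.5, ge=0.0)  # degC
    temp_peak_doy: int = 205  # day of year of the warmest daily mean
    temp_noise_sd: float = Field(default=1.0, ge=0.0)  # degC
    temp_bounds: tuple[float, float] = (9.8, 25.5)  # degC

    # daily solar radiation integral: annual sinusoid + noise, clipped.
    # The scale is set by the reported seasonal dry-matter budget: ~600 g m^-2
    # over 220 days at LUE 2.75 g/MJ implies ~1 MJ m^-2 d^-1 of intercepted
    # PAR, i.e. mean inside-greenhouse solar integrals near 2.8 MJ m^-2 d^-1.
    rad_mean: float = 2.8  # MJ m^-2 d^-1 inside the greenhouse
    rad_amplitude: float = Field(default=1.5, ge=0.0)
    rad_peak_doy: int = 172  # summer solstice
    rad_noise_sd: float = Field(default=0.6, ge=0.0)
    rad_bounds: tuple[float, float] = (1.0, 18.0)

    # flowering schedule
    first_anthesis_dat: int = Field(default=55, gt=0)
    anthesis_interval_days: int = Field(default=53, gt=0)
    n_inflorescences: int = Field(default=3, gt=0)

    # leaf-area trajectory (logistic rise, sparse observations)
    lai_start: float = Field(default=0.3, ge=0.0)
    lai_plateau: float = Field(default=3.0, gt=0.0)
    lai_mid_dat: float = 90.0  # DAT of the half rise
    lai_scale_days: float = Field(default=22.0, gt=0.0)
    lai_obs_interval_days: int = Field(default=14, gt=0)

    seed: int = 0


class CanopyImageSpec(BaseModel):
    """Parameters of a rendered top-down canopy image."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    width: int = Field(default=240, gt=0)
    height: int = Field(default=240, gt=0)
    ground_area_m2: float = Field(default=2.0, gt=0.0)  # area the frame covers
    n_leaves: int = Field(default=40, ge=0)
    leaf_radius_px: float = Field(default=18.0, gt=0.0)  # mean semi-axis
    background_rgb: tuple[int, int, int] = (120, 85, 60)  # substrate brown
    seed: int = 0


def _sinusoid(spec_mean: float, amp: float, peak_doy: int, doy: np.ndarray) -> np.ndarray:
    return spec_mean + amp * np.cos(2 * math.pi * (doy - peak_doy) / _DAYS_PER_YEAR)


def generate_climate(spec: ScenarioSpec) -> EnvironmentSeries:
    """Daily temperature and radiation series for the scenario.

    Both variables are annual sinusoids evaluated on the calendar day of
    year, with seeded Gaussian noise truncated (clipped) at the physical
    bounds; with zero noise the series is the pure sinusoid.
    """
    for name, mean, bounds in (
        ("temperature", spec.temp_mean, spec.temp_bounds),
        ("radiation", spec.rad_mean, spec.rad_bounds),
    ):
        lo, hi = bounds
        if not lo < hi:
            raise ScenarioError(f"{name} bounds {bounds} are empty")
        if not lo <= mean <= hi:
            raise ScenarioError(f"{name} mean {mean} outside bounds {bounds}")

    dates = [spec.transplant_date + dt.timedelta(days=i) for i in range(spec.season_days)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    rng = np.random.default_rng(spec.seed)

    temp = _sinusoid(spec.temp_mean, spec.temp_amplitude, spec.temp_peak_doy, doy)
    temp = temp + rng.normal(0.0, spec.temp_noise_sd, len(dates)) if spec.temp_noise_sd else temp
    temp = np.clip(temp, *spec.temp_bounds)

    rad = _sinusoid(spec.rad_mean, spec.rad_amplitude, spec.rad_peak_doy, doy)
    rad = rad + rng.normal(0.0, spec.rad_noise_sd, len(dates)) if spec.rad_noise_sd else rad
    rad = np.clip(rad, *spec.rad_bounds)

    return EnvironmentSeries(dates, temp, rad)


def generate_flowering_schedule(spec: ScenarioSpec) -> FloweringSchedule:
    """Anthesis dates: first at ``first_anthesis_dat``, then every interval."""
    dats = [
        spec.first_anthesis_dat + spec.anthesis_interval_days * i
        for i in range(spec.n_inflorescences)
    ]
    if dats[-1] >= spec.season_days:
        raise ScenarioError(
            f"anthesis at {dats[-1]} DAT exceeds the {spec.season_days}-day season"
        )
    return FloweringSchedule(
        [spec.transplant_date + dt.timedelta(days=d) for d in dats]
    )


def generate_lai_trajectory(
    spec: ScenarioSpec, mode: str = "lai", k: float = 0.85
) -> LeafAreaSeries:
    """Sparse leaf-area observations following a logistic rise.

    In ``"ilai"`` mode the logistic LAI is mapped through the Beer-Lambert
    cover fraction 1 - exp(-k * LAI), emulating what a top-down camera sees.
    """
    dats = np.arange(0, spec.season_days, spec.lai_obs_interval_days)
    lai = spec.lai_start + (spec.lai_plateau - spec.lai_start) * expit(
        (dats - spec.lai_mid_dat) / spec.lai_scale_days
    )
    if mode == "ilai":
        values = -np.expm1(-k * lai)
    elif mode == "lai":
        values = lai
    else:
        raise ScenarioError(f"unknown leaf-area mode {mode!r}")
    dates = [spec.transplant_date + dt.timedelta(days=int(d)) for d in dats]
    return LeafAreaSeries(mode=mode, dates=dates, values=values)


def generate_scenario(
    spec: ScenarioSpec | None = None, mode: str = "lai"
) -> tuple[EnvironmentSeries, FloweringSchedule, LeafAreaSeries]:
    """All three inputs of a season in one call (climate, flowering, leaf area)."""
    spec = spec or ScenarioSpec()
    return (
        generate_climate(spec),
        generate_flowering_schedule(spec),
        generate_lai_trajectory(spec, mode=mode),
    )


def render_canopy_image(spec: CanopyImageSpec) -> tuple[np.ndarray, float]:
    """Render a top-down canopy image of green ellipses on substrate.

    Returns the uint8 RGB array and the exact rendered green-cover fraction
    (ground truth for the estimator). Leaf colours are drawn so their
    excess-green index is well above the background's.
    """
    if spec.width <= 0 or spec.height <= 0:
        raise ScenarioError("image must have positive size")
    rng = np.random.default_rng(spec.seed)
    img = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
    img[..., 0] = spec.background_rgb[0]
    img[..., 1] = spec.background_rgb[1]
    img[..., 2] = spec.background_rgb[2]
    mask = np.zeros((spec.height, spec.width), dtype=bool)

    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    for _ in range(spec.n_leaves):
        cx = rng.uniform(0, spec.width)
        cy = rng.uniform(0, spec.height)
        a = rng.uniform(0.6, 1.4) * spec.leaf_radius_px
        b = rng.uniform(0.4, 0.9) * spec.leaf_radius_px
        theta = rng.uniform(0, math.pi)
        ct, st = math.cos(theta), math.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        leaf = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        color = (
            int(rng.integers(25, 75)),
            int(rng.integers(120, 200)),
            int(rng.integers(25, 75)),
        )
        img[leaf] = color
        mask |= leaf

    return img, float(mask.mean())


def estimate_ilai_from_image(image: np.ndarray, exg_threshold: int = 20) -> float:
    """Green-cover fraction of a top-down canopy image, used as iLAI.

    Pixels are classified as leaf where the excess-green index
    2G - R - B exceeds ``exg_threshold``; the returned fraction of leaf
    pixels is the canopy light-interception fraction.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise InputError("expected an RGB raster (H x W x 3)")
    rgb = image[..., :3].astype(np.int32)
    exg = 2 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]
    return float((exg > exg_threshold).mean())
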