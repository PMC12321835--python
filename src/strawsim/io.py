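"""CSV readers/writers, run configuration, and metadata sidecars.

File formats
------------
Climate CSV: ``date`` (ISO-8601), ``temp_mean_c``, ``solar_mj_m2`` — one row
per day, no gaps.
Flowering CSV: ``inflorescence_index``, ``anthesis_date``.
Leaf-area CSV: ``date``, ``value`` (the LAI/iLAI mode is declared in the
run configuration, not in the file).
Calibration CSV: ``cum_par_mj_m2``, ``tdm_g_m2``.

All dates are ISO-8601; DAT is always derived from the transplant date,
never stored as a primary key.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .canopy import CalibrationPoint
from .errors import InputError
from .params import ModelParameters
from .series import EnvironmentSeries, FloweringSchedule, LeafAreaSeries
from .simulate import SimulationResult, monthly_yield

__all__ = [
    "RunConfig",
    "load_config",
    "load_inputs",
    "read_climate_csv",
    "read_flowering_csv",
    "read_leaf_area_csv",
    "read_calibration_csv",
    "write_climate_csv",
    "write_flowering_csv",
    "write_leaf_area_csv",
    "write_trajectory_csv",
    "write_monthly_yield_csv",
    "write_metadata",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _parse_dates(series: pd.Series, path) -> list[dt.date]:
    out = []
    for i, v in enumerate(series):
        try:
            out.append(dt.date.fromisoformat(str(v).strip()))
        except ValueError as e:
            raise InputError(f"{path}: line {i + 2}: malformed date {v!r}") from e
    return out


def read_climate_csv(path, temp_bounds=(-5.0, 45.0)) -> EnvironmentSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["date", "temp_mean_c", "solar_mj_m2"], path)
    dates = _parse_dates(df["date"], path)
    return EnvironmentSeries(
        dates, df["temp_mean_c"].to_numpy(float), df["solar_mj_m2"].to_numpy(float),
        temp_bounds=temp_bounds,
    )


def write_climate_csv(env: EnvironmentSeries, path) -> None:
    pd.DataFrame(
        {
            "date": [d.isoformat() for d in env.dates],
            "temp_mean_c": env.temp_mean,
            "solar_mj_m2": env.sr,
        }
    ).to_csv(path, index=False)


def read_flowering_csv(path) -> FloweringSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["inflorescence_index", "anthesis_date"], path)
    df = df.sort_values("inflorescence_index")
    return FloweringSchedule(_parse_dates(df["anthesis_date"], path))


def write_flowering_csv(flowering: FloweringSchedule, path) -> None:
    pd.DataFrame(
        {
            "inflorescence_index": range(1, len(flowering) + 1),
            "anthesis_date": [d.isoformat() for d in flowering],
        }
    ).to_csv(path, index=False)


def read_leaf_area_csv(path, mode: str) -> LeafAreaSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["date", "value"], path)
    return LeafAreaSeries(
        mode=mode, dates=_parse_dates(df["date"], path), values=df["value"].to_numpy(float)
    )


def write_leaf_area_csv(series: LeafAreaSeries, path) -> None:
    pd.DataFrame(
        {"date": [d.isoformat() for d in series.dates], "value": series.values}
    ).to_csv(path, index=False)


def read_calibration_csv(path) -> list[CalibrationPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["cum_par_mj_m2", "tdm_g_m2"], path)
    return [
        CalibrationPoint(float(a), float(b))
        for a, b in zip(df["cum_par_mj_m2"], df["tdm_g_m2"])
    ]


def write_trajectory_csv(result: SimulationResult, path) -> None:
    result.to_frame().to_csv(path, index=False)


def write_monthly_yield_csv(result: SimulationResult, path) -> None:
    monthly_yield(result).to_csv(path, index=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_metadata(path, params: ModelParameters, inputs: dict[str, Any], **extra) -> None:
    """JSON sidecar recording the package version, parameters, and input digests."""
    from . import __version__

    meta = {
        "strawsim_version": __version__,
        "parameters": params.model_dump(),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in inputs.items()
            if p is not None
        },
        **extra,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")


class RunConfig(BaseModel):
    """A simulation run: input files, leaf-area mode, parameter overrides."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    climate: str
    flowering: str
    leaf_area: str
    leaf_area_mode: str = "lai"
    parameters: dict[str, Any] = Field(default_factory=dict)
    out_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0


def load_config(path) -> RunConfig:
    """Parse a YAML (or JSON) run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InputError(f"{path}: configuration must be a mapping")
    base = Path(path).parent
    cfg = RunConfig(**raw)
    # resolve input paths relative to the config file
    return cfg.model_copy(
        update={
            "climate": str((base / cfg.climate)),
            "flowering": str((base / cfg.flowering)),
            "leaf_area": str((base / cfg.leaf_area)),
        }
    )


def load_inputs(
    config: RunConfig,
) -> tuple[EnvironmentSeries, FloweringSchedule, LeafAreaSeries, ModelParameters]:
    """Read and validate the full input bundle of a run.

    Parameter overrides from the configuration are applied on top of the
    default calibration; anthesis dates are checked against the climate
    window here so errors surface before the simulation starts.
    """
    params = ModelParameters(**{**ModelParameters().model_dump(), **config.parameters})
    env = read_climate_csv(config.climate)
    flowering = read_flowering_csv(config.flowering)
    leaf_area = read_leaf_area_csv(config.leaf_area, mode=config.leaf_area_mode)
    first, last = env.dates[0], env.dates[-1]
    bad = [d for d in flowering if not first <= d <= last]
    if bad:
        raise InputError(
            f"{config.flowering}: anthesis dates {bad} outside climate window {first}..{last}"
        )
    return env, flowering, leaf_area, params
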