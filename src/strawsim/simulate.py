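"""Daily dry-matter partitioning and the full season simulation loop.

Each simulated day proceeds source-to-sink:

1. interpolate leaf area and convert solar radiation to intercepted PAR and
   new dry matter (``canopy``);
2. advance degree-day sums and evaluate the potential-growth increments of
   every emerged leaf cohort and post-anthesis fruit cluster, giving the
   vegetative and generative sink strengths (``phenology``);
3. allocate the day's dry matter: the fruit fraction AF = GS / (GS + VS) of
   the per-plant dry matter goes to clusters in proportion to their
   potential increments; cluster dry weights accumulate, convert to fresh
   weight through the dry-matter content, and scale to yield per ground area.

Harvest is implicit: cumulative cluster fresh weight is the cumulative
yield; no ripeness or removal submodel is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import canopy, phenology
from .errors import InputError
from .params import ModelParameters
from .phenology import FruitCluster
from .series import EnvironmentSeries, FloweringSchedule, LeafAreaSeries

__all__ = [
    "DailyState",
    "SimulationResult",
    "fruit_partition_fraction",
    "allocate_to_clusters",
    "update_cluster_weights",
    "yield_per_area",
    "simulate_season",
    "monthly_yield",
]


def fruit_partition_fraction(gs: float, vs: float) -> float:
    """Fraction of daily dry matter allocated to fruit: AF = GS / (GS + VS).

    By convention AF = 0 when both sink strengths are zero (pre-anthesis,
    pre-emergence days with no competing sinks).
    """
    if gs < 0 or vs < 0:
        raise InputError("sink strengths must be non-negative")
    total = gs + vs
    return gs / total if total > 0 else 0.0


def allocate_to_clusters(
    ddm: float,
    af: float,
    drfg: Sequence[float] | np.ndarray,
    params: ModelParameters | None = None,
) -> np.ndarray:
    """Split the day's fruit-bound dry matter among clusters.

    Cluster q receives DMF_q = (dDM / Pd) * AF * (dRFG_q / sum dRFG): the
    per-plant dry matter times the fruit fraction, shared in proportion to
    each cluster's potential increment. All allocations are zero on days
    with no growing cluster (sum dRFG = 0).
    """
    params = params or ModelParameters()
    drfg = np.asarray(drfg, dtype=float)
    if ddm < 0:
        raise InputError("daily dry matter must be non-negative")
    if not 0.0 <= af <= 1.0:
        raise InputError("fruit partition fraction must lie in [0, 1]")
    if np.any(drfg < 0):
        raise InputError("cluster increments must be non-negative")
    total = drfg.sum()
    if drfg.size == 0 or total <= 0:
        return np.zeros(drfg.size)
    return (ddm / params.pd) * af * (drfg / total)


def update_cluster_weights(
    df: Sequence[float] | np.ndarray,
    dmf: Sequence[float] | np.ndarray,
    dmc: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate cluster dry weights and convert to fresh weight.

    DF is the running sum of all daily allocations since anthesis
    (DF_n = DF_{n-1} + DMF_n); FF = DF / DMC. Returns (DF, FF) as new arrays.
    """
    df = np.asarray(df, dtype=float)
    dmf = np.asarray(dmf, dtype=float)
    if np.any(dmf < 0):
        raise InputError("daily allocations must be non-negative")
    if not 0 < dmc < 1:
        raise InputError("dry-matter content must lie in (0, 1)")
    new_df = df + dmf
    return new_df, new_df / dmc


def yield_per_area(ff: Sequence[float] | np.ndarray, pd_: float) -> float:
    """Cumulative yield per ground area: Y = (sum of cluster FW) * Pd / 1000.

    FF is cumulative per plant (g), so F = sum(FF) is the per-plant fruit
    fresh weight and Y is in kg m^-2.
    """
    ff = np.asarray(ff, dtype=float)
    if np.any(ff < 0):
        raise InputError("cluster fresh weights must be non-negative")
    if pd_ <= 0:
        raise InputError("plant density must be positive")
    return float(ff.sum() * pd_ / 1000.0)


@dataclass(frozen=True)
class DailyState:
    """Complete model state at the end of one simulated day."""

    date: object  # datetime.date
    dat: int  # days after transplanting
    temp_mean: float  # degC
    sr: float  # MJ m^-2
    leaf_area: float  # interpolated LAI or iLAI
    par: float  # MJ m^-2
    intercepted: float  # MJ m^-2
    ct: float  # degC d since transplanting
    ddm: float  # g m^-2 d^-1
    tdm: float  # g m^-2
    gs: float  # g
    vs: float  # g
    af: float  # dimensionless
    dmf: tuple[float, ...]  # per-cluster allocation, g plant^-1 d^-1
    df: tuple[float, ...]  # per-cluster cumulative DW, g plant^-1
    ff: tuple[float, ...]  # per-cluster cumulative FW, g plant^-1
    f: float  # per-plant total cluster FW, g
    y: float  # cumulative yield, kg m^-2


@dataclass
class SimulationResult:
    """Daily trajectory of a season simulation plus run metadata."""

    days: list[DailyState]
    params: ModelParameters
    leaf_area_mode: str
    n_clusters: int

    def __len__(self) -> int:
        return len(self.days)

    @property
    def final(self) -> DailyState:
        return self.days[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy daily trajectory, one row per day; per-cluster columns wide
        (``dmf_q1 ...``, ``df_q1 ...``, ``ff_q1 ...``)."""
        rows = []
        for s in self.days:
            row = {
                "date": s.date.isoformat(),
                "dat": s.dat,
                "temp_mean_c": s.temp_mean,
                "solar_mj_m2": s.sr,
                "leaf_area": s.leaf_area,
                "par_mj_m2": s.par,
                "intercepted_mj_m2": s.intercepted,
                "ct_cd": s.ct,
                "ddm_g_m2": s.ddm,
                "tdm_g_m2": s.tdm,
                "gs_g": s.gs,
                "vs_g": s.vs,
                "af": s.af,
                "f_g_plant": s.f,
                "y_kg_m2": s.y,
            }
            for q in range(self.n_clusters):
                row[f"dmf_q{q + 1}"] = s.dmf[q]
                row[f"df_q{q + 1}"] = s.df[q]
                row[f"ff_q{q + 1}"] = s.ff[q]
            rows.append(row)
        return pd.DataFrame(rows)


def simulate_season(
    env: EnvironmentSeries,
    flowering: FloweringSchedule,
    leaf_area: LeafAreaSeries,
    params: ModelParameters | None = None,
) -> SimulationResult:
    """Run the daily source-sink loop over a full season.

    Parameters
    ----------
    env
        Gap-free daily climate; its first date is the transplant date.
    flowering
        First-flower anthesis date of each inflorescence; every date must
        fall inside the climate window.
    leaf_area
        Sparse LAI or iLAI observations, interpolated daily.
    params
        Model coefficients; defaults to the 'Benihoppe' calibration.

    Returns
    -------
    SimulationResult
        One :class:`DailyState` per climate day. Deterministic given
        identical inputs.
    """
    params = params or ModelParameters()
    first, last = env.dates[0], env.dates[-1]
    bad = [d for d in flowering if not first <= d <= last]
    if bad:
        raise InputError(
            f"anthesis dates {bad} outside the climate window {first}..{last}"
        )

    clusters = [FruitCluster(q=i + 1, anthesis_date=d) for i, d in enumerate(flowering)]
    use_ilai = leaf_area.mode == "ilai"
    la_daily = leaf_area.on_dates(env.dates)

    tdm = params.tdm0
    ct_prev = 0.0
    days: list[DailyState] = []
    df = np.zeros(len(clusters))

    for n, day in enumerate(env):
        la = float(la_daily[n])
        par = canopy.par_from_radiation(day.sr, params)
        if use_ilai:
            inter = canopy.intercepted_light_ilai(par, la)
        else:
            inter = canopy.intercepted_light(par, la, params.k)
        ddm = canopy.dm_production(inter, params.lue)
        tdm += ddm

        ct_now = ct_prev + day.temp_mean
        drlg = phenology.active_leaf_increments(ct_now, ct_prev, params)

        tf_now = [
            c.tf + day.temp_mean if day.date >= c.anthesis_date else 0.0
            for c in clusters
        ]
        drfg = phenology.cluster_increments(clusters, tf_now, params)

        gs = phenology.generative_sink(drfg, params)
        vs = phenology.vegetative_sink(drlg, params)
        af = fruit_partition_fraction(gs, vs)

        dmf = allocate_to_clusters(ddm, af, drfg, params)
        df, ff = update_cluster_weights(df, dmf, params.dmc)
        f = float(ff.sum())
        y = yield_per_area(ff, params.pd)

        for c, tf in zip(clusters, tf_now):
            if day.date >= c.anthesis_date:
                c.rfg_prev = phenology.fruit_relative_growth(tf, params)
                c.tf = tf
                c.df = df[c.q - 1]

        days.append(
            DailyState(
                date=day.date,
                dat=n,
                temp_mean=day.temp_mean,
                sr=day.sr,
                leaf_area=la,
                par=par,
                intercepted=inter,
                ct=ct_now,
                ddm=ddm,
                tdm=tdm,
                gs=gs,
                vs=vs,
                af=af,
                dmf=tuple(dmf),
                df=tuple(df),
                ff=tuple(ff),
                f=f,
                y=y,
            )
        )
        ct_prev = ct_now

    return SimulationResult(
        days=days,
        params=params,
        leaf_area_mode=leaf_area.mode,
        n_clusters=len(clusters),
    )


def monthly_yield(result: SimulationResult) -> pd.DataFrame:
    """Monthly yield increments from a daily trajectory.

    Each calendar month's increment is the cumulative yield at the month's
    last simulated day minus the cumulative yield at the end of the previous
    month; the increments sum to the final cumulative yield exactly.
    """
    if not result.days:
        raise InputError("empty simulation result")
    months: list[str] = []
    end_y: list[float] = []
    for s in result.days:
        m = f"{s.date.year:04d}-{s.date.month:02d}"
        if months and months[-1] == m:
            end_y[-1] = s.y
        else:
            months.append(m)
            end_y.append(s.y)
    prev = np.concatenate([[0.0], np.asarray(end_y)[:-1]])
    return pd.DataFrame(
        {"month": months, "yield_kg_m2": np.asarray(end_y) - prev}
    )
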