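"""Degree-day phenology and sink strengths of leaves and fruit clusters.

Both organ types follow fixed logistic "potential growth" curves in
cumulative temperature. A new leaf cohort emerges every ``leaf_interval``
(160) degree-days after transplanting; leaf p's relative growth is a
logistic in cumulative temperature past its emergence threshold. Each fruit
cluster (all fruits of one inflorescence) follows a single logistic in
degree-days accumulated since its first-flower anthesis, scaled by the
cluster potential dry weight (25 g).

The daily *increments* of these curves, summed over the organs present on a
given day and weighted by empirical sink coefficients, give the generative
and vegetative sink strengths that drive dry-matter partitioning.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import InputError
from .params import ModelParameters
from .series import EnvironmentSeries

__all__ = [
    "LeafCohort",
    "FruitCluster",
    "cumulative_temperature",
    "leaf_relative_growth",
    "active_leaf_increments",
    "fruit_relative_growth",
    "cluster_increments",
    "generative_sink",
    "vegetative_sink",
]


@dataclass
class LeafCohort:
    """Phenology state of leaf cohort p (1-based emergence order)."""

    p: int
    emergence_ct: float  # degC d at which the cohort emerges (= leaf_interval * p)
    rlg_prev: float = 0.0


@dataclass
class FruitCluster:
    """Phenology and weight state of fruit cluster q (one inflorescence)."""

    q: int
    anthesis_date: dt.date
    tf: float = 0.0  # cumulative degC d since anthesis
    rfg_prev: float | None = None  # relative growth on the previous day
    df: float = 0.0  # cumulative cluster dry weight, g plant^-1
    dmf_history: list[float] = field(default_factory=list, repr=False)


def cumulative_temperature(env: EnvironmentSeries, n: int) -> float:
    """Cumulative daily mean temperature from transplanting through day n.

    The sum is inclusive of both day 0 (the transplant day) and day n.
    """
    if not 0 <= n < len(env):
        raise InputError(f"day index {n} outside series of length {len(env)}")
    return float(np.sum(env.temp_mean[: n + 1]))


def leaf_relative_growth(ct: float, p: int, params: ModelParameters | None = None):
    """Relative growth (0..1) of leaf cohort p at cumulative temperature ct.

    A logistic in x = ct - leaf_interval*p, with midpoint ``leaf_mid`` degree-
    days after the cohort's emergence threshold and scale ``leaf_scale``:
    RLG = 1 - 1 / (1 + exp((x - leaf_mid) / leaf_scale)).
    """
    params = params or ModelParameters()
    if p < 1:
        raise InputError("leaf index p must be >= 1")
    x = np.asarray(ct, dtype=float) - params.leaf_interval * p
    out = expit((x - params.leaf_mid) / params.leaf_scale)
    return float(out) if out.ndim == 0 else out


def fruit_relative_growth(tf, params: ModelParameters | None = None):
    """Relative growth (0..1) of a fruit cluster at post-anthesis degree-days tf.

    RFG = 1 / (1 + fruit_amp * exp(-fruit_rate * tf)); RFG(0) = 1/(1+fruit_amp),
    midpoint at ln(fruit_amp)/fruit_rate (~767 degC d with the default
    constants), saturating to 1.
    """
    params = params or ModelParameters()
    tf = np.asarray(tf, dtype=float)
    if np.any(tf < 0):
        raise InputError("post-anthesis cumulative temperature must be non-negative")
    out = expit(params.fruit_rate * tf - math.log(params.fruit_amp))
    return float(out) if out.ndim == 0 else out


def active_leaf_increments(
    ct_now: float, ct_prev: float, params: ModelParameters | None = None
) -> np.ndarray:
    """Daily relative-growth increment of every emerged leaf cohort.

    Cohort p has emerged once ``leaf_interval * p <= ct_now``; each emerged
    cohort contributes RLG_p(ct_now) - RLG_p(ct_prev), floored at 0. Cohorts
    not yet emerged contribute nothing (the logistic's small pre-emergence
    tail is excluded from the vegetative sink).
    """
    params = params or ModelParameters()
    if ct_now < ct_prev:
        raise InputError("cumulative temperature must be non-decreasing")
    n_leaves = int(math.floor(ct_now / params.leaf_interval))
    if params.max_leaves is not None:
        n_leaves = min(n_leaves, params.max_leaves)
    if n_leaves < 1:
        return np.empty(0)
    p = np.arange(1, n_leaves + 1)
    now = expit((ct_now - params.leaf_interval * p - params.leaf_mid) / params.leaf_scale)
    prev = expit((ct_prev - params.leaf_interval * p - params.leaf_mid) / params.leaf_scale)
    return np.maximum(now - prev, 0.0)


def cluster_increments(
    clusters: list[FruitCluster],
    tf_now: list[float] | np.ndarray,
    params: ModelParameters | None = None,
) -> np.ndarray:
    """Daily potential dry-weight increment (g) of each fruit cluster.

    dRFG_q = cluster_potential_dw * (RFG(tf_now) - RFG(tf_prev)), floored at
    0. A cluster whose anthesis has not yet occurred (``tf_now`` <= 0 and no
    stored state) contributes 0. Does not mutate the cluster objects.
    """
    params = params or ModelParameters()
    out = np.zeros(len(clusters))
    for i, (c, tf) in enumerate(zip(clusters, tf_now)):
        if tf < c.tf:
            raise InputError(f"cluster {c.q}: post-anthesis degree-days decreased")
        if tf <= 0 and c.rfg_prev is None:
            continue  # pre-anthesis
        rfg_prev = c.rfg_prev if c.rfg_prev is not None else fruit_relative_growth(c.tf, params)
        rfg_now = fruit_relative_growth(tf, params)
        out[i] = params.cluster_potential_dw * max(rfg_now - rfg_prev, 0.0)
    return out


def generative_sink(drfg, params: ModelParameters | None = None) -> float:
    """Generative sink strength: GS = fruit_sink * sum of cluster increments (g)."""
    params = params or ModelParameters()
    drfg = np.asarray(drfg, dtype=float)
    if np.any(drfg < 0):
        raise InputError("cluster increments must be non-negative")
    return float(params.fruit_sink * drfg.sum()) if drfg.size else 0.0


def vegetative_sink(drlg, params: ModelParameters | None = None) -> float:
    """Vegetative sink strength: VS = veg_adjust * leaf_sink * sum of leaf increments (g).

    The leaf sink coefficient is scaled up by ``veg_adjust`` so that leaves
    stand in for the whole vegetative compartment (crown and peduncles
    included).
    """
    params = params or ModelParameters()
    drlg = np.asarray(drlg, dtype=float)
    if np.any(drlg < 0):
        raise InputError("leaf increments must be non-negative")
    return float(params.veg_adjust * params.leaf_sink * drlg.sum()) if drlg.size else 0.0
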