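"""Model parameters.

The simulator is driven by a small set of fixed physiological coefficients:
light interception and conversion (``par_fraction``, ``k``, ``lue``), fruit
fresh/dry conversion (``dmc``), stand geometry (``pd``), the degree-day
logistic constants describing the potential growth of individual leaves and
fruit clusters, and the sink-strength coefficients that weight those
potential growth increments when daily assimilate is partitioned.

Defaults are the calibration for June-bearing 'Benihoppe' grown in forcing
culture (transplant mid-September, harvest December-April).
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator


class ModelParameters(BaseModel):
    """Fixed coefficients of the yield model.

    Units are noted per field; all coefficients must be strictly positive,
    fractions must lie in (0, 1).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    #: Fraction of global solar radiation that is photosynthetically active.
    par_fraction: float = Field(default=0.5, gt=0.0, lt=1.0)
    #: Beer-Lambert canopy light-extinction coefficient (dimensionless).
    k: float = Field(default=0.85, gt=0.0, le=2.0)
    #: Light-use efficiency, g dry matter per MJ intercepted PAR.
    lue: float = Field(default=2.75, gt=0.0)
    #: Fruit dry-matter content, g dry weight per g fresh weight.
    dmc: float = Field(default=0.10, gt=0.0, lt=1.0)
    #: Above-ground dry matter at transplanting, g m^-2.
    tdm0: float = Field(default=19.9, gt=0.0)
    #: Plant density, plants m^-2.
    pd: float = Field(default=7.05, gt=0.0)
    #: Cumulative temperature between successive leaf emergences, degC d.
    leaf_interval: float = Field(default=160.0, gt=0.0)
    #: Midpoint offset of the leaf relative-growth logistic, degC d.
    leaf_mid: float = Field(default=218.86, gt=0.0)
    #: Scale of the leaf relative-growth logistic, degC d.
    leaf_scale: float = Field(default=74.61, gt=0.0)
    #: Pre-exponential constant of the fruit-cluster logistic (dimensionless).
    fruit_amp: float = Field(default=4615.91, gt=0.0)
    #: Rate constant of the fruit-cluster logistic, (degC d)^-1.
    fruit_rate: float = Field(default=0.011, gt=0.0)
    #: Potential final dry weight of one fruit cluster, g (250 g fresh at DMC 0.10).
    cluster_potential_dw: float = Field(default=25.0, gt=0.0)
    #: Generative sink coefficient: remaining fruit DW / plant DW (dimensionless).
    fruit_sink: float = Field(default=0.24, gt=0.0)
    #: Leaf sink coefficient: remaining leaf DW / plant DW (dimensionless).
    leaf_sink: float = Field(default=0.07, gt=0.0)
    #: Vegetative adjustment: reciprocal of leaf DW / vegetative DW (dimensionless).
    veg_adjust: float = Field(default=1.3, gt=0.0)
    #: Optional cap on the number of leaf cohorts tracked (guards absurd inputs).
    max_leaves: int | None = Field(default=None)

    @model_validator(mode="after")
    def _check_max_leaves(self) -> "ModelParameters":
        if self.max_leaves is not None and self.max_leaves < 1:
            raise ValueError("max_leaves must be a positive integer or None")
        return self

    def replace(self, **overrides) -> "ModelParameters":
        """Return a copy with the given fields overridden (validated)."""
        return self.model_copy(update=overrides) if not overrides else ModelParameters(
            **{**self.model_dump(), **overrides}
        )
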