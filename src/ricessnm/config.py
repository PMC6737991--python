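"""Engine calibration constants and rule parameters.

Every number that drives a fertilizer prescription lives in
:class:`EngineConfig`, so a recommendation is fully auditable from one
record: the target-yield rule, the fertilizer-N calibration line, the
split fractions, the P input-output balance coefficients, the K
yield-gain coefficients, phenology offsets and the zinc policy.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class EngineConfig(BaseModel):
    """Calibration constants for the nutrient-management engine.

    Defaults reproduce the engine as deployed for Odisha: fertilizer N
    rises linearly from 57 kg/ha at a 3 Mg/ha target yield to 123 kg/ha
    at 6 Mg/ha; P comes from an input-output balance assuming 15% of
    above-ground residue biomass is retained and 70% of plant P is in
    grain; K covers a 15% yield gain at a recovery efficiency of
    0.44 kg K taken up per kg K applied; K is all basal up to 33 kg/ha;
    zinc sulfate is a flat 25 kg/ha policy.
    """

    model_config = ConfigDict(frozen=True)

    # target-yield rule
    ty_uplift: float = Field(0.5, description="Mg/ha added to the farmer's historical yield")
    ty_min: float = Field(3.0, description="lower bound on target yield, Mg/ha")
    ty_max: float = Field(6.5, description="upper bound on target yield, Mg/ha")
    late_penalty_per_week: float = Field(
        0.25, description="Mg/ha target-yield reduction per week of transplanting delay"
    )

    # fertilizer-N calibration: (target yield Mg/ha, N kg/ha) anchor points
    n_calibration_anchors: tuple[tuple[float, float], ...] = ((3.0, 57.0), (6.0, 123.0))
    n_split_fractions: tuple[float, float, float] = (0.30, 0.30, 0.40)

    # fertilizer-P input-output balance
    rie_p: float = Field(2.6, description="kg P taken up per Mg of grain produced")
    grain_p_fraction: float = Field(0.70, description="share of total plant P in harvested grain")
    residue_biomass_fraction: float = Field(
        0.15, description="default share of above-ground biomass retained after harvest"
    )
    straw_p_fraction: float = Field(
        0.30, description="share of total plant P in straw (1 - grain_p_fraction)"
    )

    # fertilizer-K yield-gain rule
    k_yield_gain_fraction: float = Field(0.15, description="yield gain attributed to applied K")
    rie_k: float = Field(14.5, description="kg K taken up per Mg of grain produced")
    k_recovery_efficiency: float = Field(
        0.44, description="kg K taken up per kg fertilizer K applied"
    )
    k_basal_threshold: float = Field(
        33.0, description="kg K/ha at or below which all K is applied basal"
    )

    # phenology
    pi_offset_days: int = Field(
        60, description="days before maturity at which panicle initiation occurs"
    )
    basal_window_map: tuple[tuple[float, float], ...] = ((100.0, 5.0), (160.0, 21.0))
    basal_deadline_min: int = 5
    basal_deadline_max: int = 21

    # zinc policy
    zinc_sulfate_rate: float = Field(25.0, description="kg/ha zinc sulfate applied basal")

    @model_validator(mode="after")
    def _check(self) -> "EngineConfig":
        if not self.ty_min < self.ty_max:
            raise ValueError("ty_min must be < ty_max")
        if abs(sum(self.n_split_fractions) - 1.0) > 1e-9:
            raise ValueError("n_split_fractions must sum to 1")
        if any(f < 0 for f in self.n_split_fractions):
            raise ValueError("n_split_fractions must be non-negative")
        anchors = self.n_calibration_anchors
        if len(anchors) < 2:
            raise ValueError("need at least two N calibration anchors")
        for (t0, n0), (t1, n1) in zip(anchors, anchors[1:]):
            if not (t1 > t0 and n1 > n0):
                raise ValueError("N calibration anchors must be strictly increasing")
        for name in (
            "ty_uplift", "late_penalty_per_week", "rie_p", "grain_p_fraction",
            "residue_biomass_fraction", "straw_p_fraction", "k_yield_gain_fraction",
            "rie_k", "k_basal_threshold", "zinc_sulfate_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_recovery_efficiency <= 0:
            raise ValueError("k_recovery_efficiency must be positive")
        return self


class PriceSet(BaseModel):
    """Farmgate price of unmilled rice and the exchange rate.

    ``paddy_price`` is US$ per kg of unmilled rice (0.21 for most
    seasons, 0.22 for kharif 2015 in the deployment this engine
    mirrors). ``exchange_rate`` is INR per US$ and is carried for
    reporting only; all arithmetic is in US$.
    """

    model_config = ConfigDict(frozen=True)

    paddy_price: float = Field(0.21, gt=0, description="US$ per kg unmilled rice")
    exchange_rate: float = Field(65.0, gt=0, description="INR per US$")


PADDY_PRICE_BY_SEASON_YEAR: dict[tuple[str, str], float] = {
    ("rabi", "2013-2014"): 0.21,
    ("kharif", "2014"): 0.21,
    ("rabi", "2014-2015"): 0.21,
    ("kharif", "2015"): 0.22,
}


def price_set_for(season: str, year: str) -> PriceSet:
    """Season/year-specific paddy price; defaults to 0.21 US$/kg."""
    return PriceSet(paddy_price=PADDY_PRICE_BY_SEASON_YEAR.get((season, year), 0.21))
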