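"""The farmer interview: the engine's sole field-specific input."""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Season(str, Enum):
    KHARIF = "kharif"  # monsoon (wet) season
    RABI = "rabi"      # winter (dry) season


class WaterRegime(str, Enum):
    IRRIGATED = "irrigated"
    RAINFED = "rainfed"


#: The six agro-climatic zones of the Odisha deployment.
AGRO_CLIMATIC_ZONES = (
    "east_south_eastern_coastal_plain",
    "mid_central_table_land",
    "north_central_plateau",
    "north_eastern_coastal_plain",
    "north_western_plateau",
    "western_central_table_land",
)


class FarmerInterview(BaseModel):
    """One field's pre-season questionnaire answers.

    The engine needs nothing else: variety growth duration and seedling
    age drive the split schedule, historical yield drives the target
    yield, previous-crop yield and residue retention drive the P
    credit, and the product list constrains the allocation.

    Attributes
    ----------
    growth_duration_days:
        Variety duration from germination to maturity.
    seedling_age_days:
        Age of seedlings at transplanting.
    transplant_delay_days:
        Days transplanting slipped beyond the critical date; lowers the
        target yield.
    historical_yield_GYR:
        Grain yield (Mg/ha at 14% moisture) the farmer reports having
        obtained in previous years with the same or a similar variety.
    variety_yield_ceiling:
        Optional cap on the target yield for low-yielding varieties.
    previous_crop_yield:
        Grain yield of the previous crop, Mg/ha (0 if no previous crop).
    residue_retained_fraction:
        Share of the previous crop's above-ground residue left in the
        field.
    """

    model_config = ConfigDict(frozen=True)

    field_id: str
    district: str = ""
    acz: str = AGRO_CLIMATIC_ZONES[0]
    season: Season = Season.KHARIF
    year: str = ""
    water_regime: WaterRegime = WaterRegime.IRRIGATED
    variety_name: str = ""
    growth_duration_days: int = Field(ge=90, le=180)
    seedling_age_days: int = Field(ge=10, le=45)
    transplant_delay_days: float = Field(0.0, ge=0)
    historical_yield_GYR: float = Field(gt=0)
    variety_yield_ceiling: Optional[float] = None
    previous_crop_yield: float = Field(0.0, ge=0)
    residue_retained_fraction: float = Field(0.15, ge=0, le=1)
    selected_products: tuple[str, ...] = ("urea", "DAP", "MOP")
    farmer_applies_zinc: bool = False

    @model_validator(mode="after")
    def _check(self) -> "FarmerInterview":
        if self.acz not in AGRO_CLIMATIC_ZONES:
            raise ValueError(f"unknown agro-climatic zone: {self.acz!r}")
        if self.seedling_age_days >= self.growth_duration_days:
            raise ValueError("seedling age must be less than growth duration")
        if self.variety_yield_ceiling is not None and self.variety_yield_ceiling <= 0:
            raise ValueError("variety_yield_ceiling must be positive when given")
        return self
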