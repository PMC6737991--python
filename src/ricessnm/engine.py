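"""Field-specific N/P/K prescriptions with split schedules.

The engine turns one farmer interview into a nutrient prescription:

1. a target yield — historical yield plus a fixed uplift, capped by the
   variety ceiling, penalised for late transplanting, and clamped to
   the calibrated 3.0-6.5 Mg/ha range;
2. a fertilizer-N rate from a piecewise-linear calibration through
   (target yield, N rate) anchor points, split across early vegetative,
   mid-tillering and panicle-initiation stages;
3. a fertilizer-P rate from a nutrient input-output balance (crop P
   uptake minus the P credit from retained residues), applied basal;
4. a fertilizer-K rate from a yield-gain rule (extra K uptake for the
   yield gain attributed to K, divided by the recovery efficiency of
   fertilizer K), all basal at or below a threshold and otherwise split
   50/50 between basal and panicle initiation.

All rates are elemental kg/ha and are kept as continuous values;
rounding happens only at presentation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .config import EngineConfig
from .interview import FarmerInterview

STAGE_BASAL = "basal"
STAGE_MID_TILLERING = "mid_tillering"
STAGE_PANICLE_INITIATION = "panicle_initiation"


class SchedulingError(ValueError):
    """Variety too short (or seedlings too old) to fit the split schedule."""


class SplitApplication(BaseModel):
    """One nutrient application: growth stage, timing and amount."""

    model_config = ConfigDict(frozen=True)

    stage: str
    dat: int  # days after transplanting
    amount: float  # kg/ha elemental


class NutrientPrescription(BaseModel):
    """Elemental N/P/K rates plus their split schedules for one field."""

    model_config = ConfigDict(frozen=True)

    field_id: str
    target_yield_GYT: float
    fn: float
    fp: float
    fk: float
    n_splits: tuple[SplitApplication, ...]
    k_splits: tuple[SplitApplication, ...]
    p_split: SplitApplication

    @model_validator(mode="after")
    def _check(self) -> "NutrientPrescription":
        if min(self.fn, self.fp, self.fk) < 0:
            raise ValueError("nutrient rates must be non-negative")
        if abs(sum(s.amount for s in self.n_splits) - self.fn) > 1e-6:
            raise ValueError("N splits do not sum to the N rate")
        if abs(sum(s.amount for s in self.k_splits) - self.fk) > 1e-6:
            raise ValueError("K splits do not sum to the K rate")
        return self


def set_target_yield(interview: FarmerInterview, cfg: EngineConfig) -> float:
    """Target yield (Mg/ha) for one field.

    The historical yield reported by the farmer is raised by
    ``cfg.ty_uplift``, capped at the variety yield ceiling when one is
    known, reduced by ``cfg.late_penalty_per_week`` per week of
    transplanting delay, and clamped to ``[ty_min, ty_max]``.
    """
    gyr = interview.historical_yield_GYR
    if gyr <= 0:
        raise ValueError("historical yield must be positive")
    ty = gyr + cfg.ty_uplift
    if interview.variety_yield_ceiling is not None:
        ty = min(ty, interview.variety_yield_ceiling)
    ty -= cfg.late_penalty_per_week * (interview.transplant_delay_days / 7.0)
    return float(np.clip(ty, cfg.ty_min, cfg.ty_max))


def n_rate(target_yield: float, cfg: EngineConfig) -> float:
    """Fertilizer-N rate (kg/ha) from the calibration curve.

    Piecewise-linear interpolation through the anchor points, with the
    terminal segments extrapolated linearly out to the target-yield
    bounds. With the default two anchors this is the single line
    N = 57 + 22 * (TY - 3).
    """
    if not (cfg.ty_min <= target_yield <= cfg.ty_max):
        raise ValueError(
            f"target yield {target_yield} outside [{cfg.ty_min}, {cfg.ty_max}]"
        )
    anchors = cfg.n_calibration_anchors
    ty = np.asarray([a[0] for a in anchors])
    nn = np.asarray([a[1] for a in anchors])
    if target_yield <= ty[0]:
        slope = (nn[1] - nn[0]) / (ty[1] - ty[0])
        return float(nn[0] + slope * (target_yield - ty[0]))
    if target_yield >= ty[-1]:
        slope = (nn[-1] - nn[-2]) / (ty[-1] - ty[-2])
        return float(nn[-1] + slope * (target_yield - ty[-1]))
    return float(np.interp(target_yield, ty, nn))


def stage_schedule(
    growth_duration_days: int, seedling_age_days: int, cfg: EngineConfig
) -> tuple[int, int, int]:
    """Timing (days after transplanting) of the three N applications.

    Panicle initiation is placed ``pi_offset_days`` before maturity,
    counted from sowing, so in DAT it is
    ``duration - pi_offset - seedling_age``: a day more in the nursery
    is a day less in the field. Mid-tillering is halfway to panicle
    initiation. The basal deadline widens linearly with variety
    duration between the configured endpoints (5 DAT for a 100-day
    variety up to 21 DAT for a 160-day variety) and is clamped to that
    window.
    """
    pi_dat = growth_duration_days - cfg.pi_offset_days - seedling_age_days
    (d0, b0), (d1, b1) = cfg.basal_window_map[0], cfg.basal_window_map[-1]
    basal = b0 + (b1 - b0) * (growth_duration_days - d0) / (d1 - d0)
    basal = int(np.clip(round(basal), cfg.basal_deadline_min, cfg.basal_deadline_max))
    if pi_dat <= basal:
        raise SchedulingError(
            f"panicle initiation at {pi_dat} DAT does not follow the basal "
            f"deadline ({basal} DAT); variety too short for {seedling_age_days}-day seedlings"
        )
    mt_dat = round(pi_dat / 2)
    if not (basal < mt_dat < pi_dat):
        raise SchedulingError(
            f"stages not strictly ordered: basal {basal}, mid-tillering {mt_dat}, "
            f"panicle initiation {pi_dat} DAT"
        )
    return basal, mt_dat, pi_dat


def n_split_amounts(fn: float, cfg: EngineConfig) -> tuple[float, float, float]:
    """Three stage amounts for fertilizer N; the last absorbs rounding."""
    if fn < 0:
        raise ValueError("fertilizer N rate must be non-negative")
    f1, f2, _ = cfg.n_split_fractions
    a1, a2 = fn * f1, fn * f2
    return a1, a2, fn - a1 - a2


def p_rate(
    target_yield: float,
    previous_crop_yield: float,
    residue_retained_fraction: float,
    cfg: EngineConfig,
) -> float:
    """Fertilizer-P rate (kg/ha) from the input-output balance.

    P demand is the P taken up by the mature crop at the target yield
    (``rie_p * TY``). The credit is the P returned in retained residue:
    total plant P of the previous crop times the straw share of plant P
    times the fraction of residue retained. The rate never goes below
    zero.
    """
    if previous_crop_yield < 0:
        raise ValueError("previous crop yield must be non-negative")
    demand = cfg.rie_p * target_yield
    credit = residue_retained_fraction * cfg.straw_p_fraction * cfg.rie_p * previous_crop_yield
    return max(0.0, demand - credit)


def k_rate(target_yield: float, cfg: EngineConfig) -> float:
    """Fertilizer-K rate (kg/ha) from the yield-gain rule.

    The yield gain attributed to applied K (a fixed fraction of the
    target yield) implies extra K uptake of ``gain * rie_k``; dividing
    by the recovery efficiency of fertilizer K gives the rate to apply.
    """
    if cfg.k_recovery_efficiency <= 0:
        raise ValueError("k_recovery_efficiency must be positive")
    gain = cfg.k_yield_gain_fraction * target_yield
    return gain * cfg.rie_k / cfg.k_recovery_efficiency


def k_split_amounts(fk: float, cfg: EngineConfig) -> tuple[float, ...]:
    """All K basal at or below the threshold; 50/50 basal and panicle
    initiation above it. The threshold is inclusive."""
    if fk < 0:
        raise ValueError("fertilizer K rate must be non-negative")
    if fk <= cfg.k_basal_threshold:
        return (fk,)
    return (fk / 2.0, fk / 2.0)


def build_prescription(
    interview: FarmerInterview, cfg: Optional[EngineConfig] = None
) -> NutrientPrescription:
    """Compose the full field-specific prescription for one interview."""
    cfg = cfg or EngineConfig()
    ty = set_target_yield(interview, cfg)
    fn = n_rate(ty, cfg)
    fp = p_rate(ty, interview.previous_crop_yield, interview.residue_retained_fraction, cfg)
    fk = k_rate(ty, cfg)
    basal, mt, pi = stage_schedule(
        interview.growth_duration_days, interview.seedling_age_days, cfg
    )
    n_amounts = n_split_amounts(fn, cfg)
    n_splits = tuple(
        SplitApplication(stage=s, dat=d, amount=a)
        for s, d, a in zip(
            (STAGE_BASAL, STAGE_MID_TILLERING, STAGE_PANICLE_INITIATION),
            (basal, mt, pi),
            n_amounts,
        )
    )
    k_amounts = k_split_amounts(fk, cfg)
    if len(k_amounts) == 1:
        k_splits = (SplitApplication(stage=STAGE_BASAL, dat=basal, amount=k_amounts[0]),)
    else:
        k_splits = (
            SplitApplication(stage=STAGE_BASAL, dat=basal, amount=k_amounts[0]),
            SplitApplication(stage=STAGE_PANICLE_INITIATION, dat=pi, amount=k_amounts[1]),
        )
    return NutrientPrescription(
        field_id=interview.field_id,
        target_yield_GYT=ty,
        fn=fn,
        fp=fp,
        fk=fk,
        n_splits=n_splits,
        k_splits=k_splits,
        p_split=SplitApplication(stage=STAGE_BASAL, dat=basal, amount=fp),
    )
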