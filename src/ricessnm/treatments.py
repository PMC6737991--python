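"""The three comparison treatments and per-trial economics.

Every on-farm trial splits one field into three plots:

* **RCM** — the field-specific prescription computed by the engine from
  the farmer interview, allocated to the farmer's products.
* **BFR** — the blanket recommendation: 80 kg N, 17 kg P, 33 kg K per
  ha for every field, N split 20/50/30 across basal, tillering and
  panicle initiation, P basal, K 50/50 basal and panicle initiation.
* **FFP** — the farmer's own fertilizer practice, recorded verbatim in
  a pre-season interview (fixed before the farmer saw any
  recommendation).

Zinc sulfate at the flat policy rate goes on every RCM and BFR plot;
FFP gets it only when the farmer said they use it.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .config import EngineConfig, PriceSet
from .economics import (
    EconomicsResult,
    added_net_benefit,
    gross_return_above_fertilizer_cost,
)
from .engine import (
    STAGE_BASAL,
    STAGE_MID_TILLERING,
    STAGE_PANICLE_INITIATION,
    NutrientPrescription,
    SplitApplication,
    build_prescription,
    stage_schedule,
)
from .interview import FarmerInterview
from .products import (
    Application,
    FertilizerProduct,
    ProductAllocation,
    allocate_products,
    delivered_nutrients,
    total_fertilizer_cost,
)

TREATMENTS = ("RCM", "FFP", "BFR")

BFR_N_RATE = 80.0   # kg N/ha
BFR_P_RATE = 17.0   # kg P/ha
BFR_K_RATE = 33.0   # kg K/ha
BFR_N_SPLIT_FRACTIONS = (0.20, 0.50, 0.30)

#: Reporting bins for N timing, in days after transplanting.
STAGE_BINS = ((20, "early (<=20 DAT)"), (35, "tillering (21-35 DAT)"))


def stage_bin(dat: int) -> str:
    """Bin an application day into the three reporting windows."""
    for upper, label in STAGE_BINS:
        if dat <= upper:
            return label
    return "late (>35 DAT)"


class TreatmentPlan(BaseModel):
    """A dated schedule of product applications for one plot."""

    model_config = ConfigDict(frozen=True)

    label: str
    applications: tuple[Application, ...]
    total_n: float
    total_p: float
    total_k: float
    zinc_sulfate: float  # kg product/ha
    tfc: float           # US$/ha

    @model_validator(mode="after")
    def _check(self) -> "TreatmentPlan":
        if self.label not in TREATMENTS:
            raise ValueError(f"label must be one of {TREATMENTS}")
        dats = [a.dat for a in self.applications]
        if dats != sorted(dats):
            raise ValueError("applications must be in non-decreasing DAT order")
        return self


class TrialRecord(BaseModel):
    """One field trial: the interview, three plans and their yields."""

    model_config = ConfigDict(frozen=True)

    interview: FarmerInterview
    plans: dict[str, TreatmentPlan]
    yields: dict[str, float]  # Mg/ha per treatment
    prices: PriceSet

    @model_validator(mode="after")
    def _check(self) -> "TrialRecord":
        for t in TREATMENTS:
            if t not in self.plans:
                raise ValueError(f"missing plan for treatment {t}")
        for t, y in self.yields.items():
            if y < 0:
                raise ValueError(f"negative yield for {t}")
        return self


def _zinc_amount(applications: Sequence[Application]) -> float:
    return sum(a.amount for a in applications if "zinc" in a.product.lower())


def _plan_from_allocation(
    label: str,
    allocation: ProductAllocation,
    products: Sequence[FertilizerProduct],
) -> TreatmentPlan:
    apps = tuple(sorted(allocation.applications, key=lambda a: a.dat))
    return TreatmentPlan(
        label=label,
        applications=apps,
        total_n=allocation.delivered_n,
        total_p=allocation.delivered_p,
        total_k=allocation.delivered_k,
        zinc_sulfate=_zinc_amount(apps),
        tfc=total_fertilizer_cost(allocation, products),
    )


def build_rcm_plan(
    interview: FarmerInterview,
    products: Sequence[FertilizerProduct],
    cfg: Optional[EngineConfig] = None,
) -> TreatmentPlan:
    """Field-specific plan: engine prescription allocated to products."""
    cfg = cfg or EngineConfig()
    prescription = build_prescription(interview, cfg)
    allocation = allocate_products(prescription, products, cfg, include_zinc=True)
    return _plan_from_allocation("RCM", allocation, products)


def build_bfr_plan(
    interview: FarmerInterview,
    products: Sequence[FertilizerProduct],
    cfg: Optional[EngineConfig] = None,
) -> TreatmentPlan:
    """Blanket plan: fixed 80/17/33 with the blanket split pattern.

    The rates and split fractions never depend on the interview; only
    the calendar (DAT of each stage) follows the variety and seedling
    age, as it does for every treatment.
    """
    cfg = cfg or EngineConfig()
    basal, mt, pi = stage_schedule(
        interview.growth_duration_days, interview.seedling_age_days, cfg
    )
    f1, f2, f3 = BFR_N_SPLIT_FRACTIONS
    prescription = NutrientPrescription(
        field_id=interview.field_id,
        target_yield_GYT=(cfg.ty_min + cfg.ty_max) / 2,  # unused by allocation
        fn=BFR_N_RATE,
        fp=BFR_P_RATE,
        fk=BFR_K_RATE,
        n_splits=(
            SplitApplication(stage=STAGE_BASAL, dat=basal, amount=BFR_N_RATE * f1),
            SplitApplication(stage=STAGE_MID_TILLERING, dat=mt, amount=BFR_N_RATE * f2),
            SplitApplication(
                stage=STAGE_PANICLE_INITIATION, dat=pi, amount=BFR_N_RATE * f3
            ),
        ),
        k_splits=(
            SplitApplication(stage=STAGE_BASAL, dat=basal, amount=BFR_K_RATE / 2),
            SplitApplication(
                stage=STAGE_PANICLE_INITIATION, dat=pi, amount=BFR_K_RATE / 2
            ),
        ),
        p_split=SplitApplication(stage=STAGE_BASAL, dat=basal, amount=BFR_P_RATE),
    )
    allocation = allocate_products(prescription, products, cfg, include_zinc=True)
    return _plan_from_allocation("BFR", allocation, products)


def build_ffp_plan(
    planned_practice: Sequence[tuple[int, str, float]],
    farmer_applies_zinc: bool,
    products: Sequence[FertilizerProduct],
    zinc_rate: float = 25.0,
) -> TreatmentPlan:
    """Farmer's plan, mirrored verbatim from the pre-season interview.

    ``planned_practice`` is a list of (DAT, product name, kg product/ha)
    as stated by the farmer. Timings stay as raw DAT; the stage label
    is only the reporting bin. Zinc sulfate is added basal only when
    the farmer reported using it.
    """
    if not planned_practice:
        raise ValueError("planned practice is empty")
    by_name = {p.name: p for p in products}
    apps = []
    for dat, name, amount in planned_practice:
        if name not in by_name:
            raise ValueError(f"unknown product {name!r} in farmer practice")
        apps.append(Application(stage=stage_bin(dat), dat=dat, product=name, amount=amount))
    if farmer_applies_zinc and zinc_rate > 0:
        zinc = next((p for p in products if "zinc" in p.name.lower()), None)
        if zinc is None:
            raise ValueError("farmer applies zinc but no zinc product in the table")
        first_dat = min(a.dat for a in apps)
        apps.append(
            Application(stage=stage_bin(first_dat), dat=first_dat, product=zinc.name,
                        amount=zinc_rate)
        )
    apps = tuple(sorted(apps, key=lambda a: a.dat))
    n, p, k = delivered_nutrients(apps, products)
    return TreatmentPlan(
        label="FFP",
        applications=apps,
        total_n=n,
        total_p=p,
        total_k=k,
        zinc_sulfate=_zinc_amount(apps),
        tfc=total_fertilizer_cost(apps, products),
    )


def evaluate_trial(trial: TrialRecord) -> dict:
    """Per-treatment economics and pairwise added-net-benefit contrasts."""
    results: dict[str, EconomicsResult] = {}
    for t in TREATMENTS:
        if t not in trial.yields:
            raise ValueError(f"missing yield for treatment {t}")
        plan = trial.plans[t]
        results[t] = gross_return_above_fertilizer_cost(
            trial.yields[t], trial.prices.paddy_price, plan.tfc, fn_applied=plan.total_n
        )
    contrasts = {
        "RCM-FFP": added_net_benefit(results["RCM"].grf, results["FFP"].grf),
        "RCM-BFR": added_net_benefit(results["RCM"].grf, results["BFR"].grf),
        "BFR-FFP": added_net_benefit(results["BFR"].grf, results["FFP"].grf),
    }
    return {"economics": results, "anb": contrasts}


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Long table: one row per field-treatment with rates, cost, yield,
    economics and the trial's ANB contrasts."""
    rows = []
    for trial in trials:
        ev = evaluate_trial(trial)
        iv = trial.interview
        for t in TREATMENTS:
            plan, econ = trial.plans[t], ev["economics"][t]
            rows.append(
                {
                    "field_id": iv.field_id,
                    "season": iv.season.value,
                    "year": iv.year,
                    "acz": iv.acz,
                    "water_regime": iv.water_regime.value,
                    "growth_duration_days": iv.growth_duration_days,
                    "treatment": t,
                    "n_rate_kg_per_ha": plan.total_n,
                    "p_rate_kg_per_ha": plan.total_p,
                    "k_rate_kg_per_ha": plan.total_k,
                    "zinc_sulfate_kg_per_ha": plan.zinc_sulfate,
                    "tfc_usd_per_ha": plan.tfc,
                    "grain_yield_mg_per_ha": econ.grain_yield,
                    "gross_return_usd_per_ha": econ.gross_return,
                    "grf_usd_per_ha": econ.grf,
                    "pfp_kg_per_kg": econ.pfp,
                    "anb_rcm_ffp_usd_per_ha": ev["anb"]["RCM-FFP"],
                    "anb_rcm_bfr_usd_per_ha": ev["anb"]["RCM-BFR"],
                    "anb_bfr_ffp_usd_per_ha": ev["anb"]["BFR-FFP"],
                }
            )
    return pd.DataFrame(rows)


def summarize_cohort(
    trials: Sequence[TrialRecord],
    by: Sequence[str] = ("season", "year"),
    anb_thresholds: Sequence[float] = (0.0, 25.0),
) -> dict[str, pd.DataFrame]:
    """Grouped cohort summary.

    Returns treatment-level group means of rates, cost, yield and PFP;
    group means of the three ANB contrasts; and exceedance
    probabilities of the RCM-FFP and RCM-BFR contrasts at the given
    thresholds.
    """
    if not trials:
        raise ValueError("no trials to summarize")
    frame = trials_to_frame(trials)
    by = list(by)
    value_cols = [
        "n_rate_kg_per_ha", "p_rate_kg_per_ha", "k_rate_kg_per_ha",
        "tfc_usd_per_ha", "grain_yield_mg_per_ha", "pfp_kg_per_kg",
    ]
    means = (
        frame.groupby(by + ["treatment"], observed=True)[value_cols].mean().reset_index()
    )
    per_trial = frame[frame["treatment"] == "RCM"]
    contrast_cols = [
        "anb_rcm_ffp_usd_per_ha", "anb_rcm_bfr_usd_per_ha", "anb_bfr_ffp_usd_per_ha",
    ]
    contrasts = per_trial.groupby(by, observed=True)[contrast_cols].mean().reset_index()
    exceed_rows = []
    for key, grp in per_trial.groupby(by, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        for contrast, col in (
            ("RCM-FFP", "anb_rcm_ffp_usd_per_ha"),
            ("RCM-BFR", "anb_rcm_bfr_usd_per_ha"),
        ):
            for t in anb_thresholds:
                exceed_rows.append(
                    dict(zip(by, key))
                    | {
                        "contrast": contrast,
                        "threshold_usd_per_ha": t,
                        "p_exceed": float((grp[col] >= t).mean()),
                    }
                )
    return {
        "treatment_means": means,
        "anb_means": contrasts,
        "exceedance": pd.DataFrame(exceed_rows),
    }
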