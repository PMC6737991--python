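"""Synthetic farmer cohort and yield-response simulator.

Generates farmer interviews, farmers' fertilizer practices and
simulated plot yields with the structure of the Odisha on-farm trial
cohort: 209 trials spread over six agro-climatic zones and two seasons,
historical yields from a truncated normal on 1.7-6.3 Mg/ha, 24
varieties whose duration class depends on season (long-duration
varieties in kharif only, short-duration mostly in rabi), and farmer
N/P/K rates drawn season by season so kharif N use sits well below rabi
N use.

The yield response is a linear-plateau model: yield rises with
effective fertilizer N at a field-specific agronomic efficiency until
it hits the field's potential, with a penalty for poorly timed N
(basal-heavy or post-panicle-initiation applications), a penalty on
zinc-responsive soils left without zinc, and additive Gaussian noise.
Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .config import EngineConfig, price_set_for
from .engine import SchedulingError, stage_schedule
from .interview import AGRO_CLIMATIC_ZONES, FarmerInterview, Season, WaterRegime
from .products import FertilizerProduct, grade_to_elemental
from .treatments import TreatmentPlan, TrialRecord, build_bfr_plan, build_ffp_plan, build_rcm_plan

#: (name, duration days) for the default variety pool, spanning the
#: short (<=120 d), medium (121-140 d) and long (>140 d) classes.
DEFAULT_VARIETIES: tuple[tuple[str, int], ...] = (
    ("Khandagiri", 105), ("Lalitagiri", 105), ("MTU-1010", 110), ("Sidhant", 110),
    ("Parijat", 110), ("Naveen", 115), ("Sahabhagi", 115), ("Jogesh", 118),
    ("Lalat", 125), ("Manaswini", 128), ("Konark", 130), ("MTU-1001", 130),
    ("Gajapati", 132), ("Surendra", 135), ("Tapaswini", 135), ("Hiranmayee", 138),
    ("Swarna", 145), ("Kanchan", 145), ("Pratikshya", 148), ("Pooja", 150),
    ("Ramachandi", 152), ("Ranidhan", 155), ("Mahanadi", 158), ("CR-1018", 160),
)

DISTRICTS = (
    "Puri", "Cuttack", "Bhadrak", "Balasore", "Mayurbhanj",
    "Keonjhar", "Sundargarh", "Bolangir", "Kalahandi", "Dhenkanal",
)


class CohortSpec(BaseModel):
    """Shape of the synthetic cohort.

    FFP nutrient totals are drawn uniformly from season-specific
    sub-ranges of the observed ranges, chosen so the season means land
    near the reported farmer practice (N about 75 kg/ha in kharif and
    98 in rabi, P about 20-26, K about 43-46) while every draw stays
    inside the observed 0-64 kg P/ha and 0-156 kg K/ha envelopes.
    """

    model_config = ConfigDict(frozen=True)

    n_trials: int = Field(209, gt=0)
    season_mix: dict[str, float] = {"kharif": 108 / 209, "rabi": 101 / 209}
    year_mix: dict[str, dict[str, float]] = {
        "kharif": {"2014": 84 / 108, "2015": 24 / 108},
        "rabi": {"2013-2014": 39 / 101, "2014-2015": 62 / 101},
    }
    acz_mix: dict[str, float] = {
        zone: w / 209.0
        for zone, w in zip(AGRO_CLIMATIC_ZONES, (66, 10, 58, 54, 11, 10))
    }
    kharif_rainfed_probability: float = 60 / 108  # all rabi trials are irrigated

    gyr_mean: float = 4.4
    gyr_sd: float = 0.7
    gyr_bounds: tuple[float, float] = (1.7, 6.3)

    variety_table: tuple[tuple[str, int], ...] = DEFAULT_VARIETIES
    seedling_age_range: tuple[int, int] = (18, 30)
    late_transplant_probability: float = 0.12
    late_transplant_delay_range: tuple[float, float] = (15.0, 35.0)

    # farmer practice: uniform totals per season, kg/ha. The N range is
    # the urea-N the farmer plans; the N in the farmer's DAP rides on
    # top, so delivered N averages about 75 kg/ha in kharif and 98 in
    # rabi.
    ffp_n_range: dict[str, tuple[float, float]] = {
        "kharif": (10.0, 104.0),
        "rabi": (14.0, 135.0),
    }
    ffp_p_range: dict[str, tuple[float, float]] = {
        "kharif": (0.0, 40.0),
        "rabi": (0.0, 52.0),
    }
    ffp_k_range: dict[str, tuple[float, float]] = {
        "kharif": (0.0, 86.0),
        "rabi": (0.0, 92.0),
    }
    ffp_split_count_probs: tuple[float, float, float] = (0.05, 0.20, 0.75)  # 1, 2, 3 apps
    ffp_zinc_probability: float = 0.05

    # yield-response model
    ae_range: tuple[float, float] = (0.010, 0.025)  # Mg grain per kg N
    headroom_range: tuple[float, float] = (0.5, 2.5)  # potential - GY_R, Mg/ha
    zinc_responsive_probability: float = 0.3
    zinc_penalty: float = 0.4  # Mg/ha
    noise_sd: float = 0.3  # Mg/ha

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        for name in ("season_mix", "acz_mix"):
            if abs(sum(getattr(self, name).values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1")
        for mix in self.year_mix.values():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("year_mix weights must sum to 1 per season")
        if abs(sum(self.ffp_split_count_probs) - 1.0) > 1e-9:
            raise ValueError("ffp_split_count_probs must sum to 1")
        lo, hi = self.gyr_bounds
        if not lo < hi:
            raise ValueError("gyr_bounds must be ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        return self


class ResponseModel(BaseModel):
    """Field-specific linear-plateau yield response to fertilizer N."""

    model_config = ConfigDict(frozen=True)

    base_yield_no_n: float = Field(ge=0, description="Mg/ha with no fertilizer N")
    potential_yield: float = Field(gt=0, description="Mg/ha plateau")
    agronomic_efficiency: float = Field(gt=0, description="Mg grain per kg N")
    pi_dat: int = Field(description="panicle initiation, days after transplanting")
    zinc_responsive: bool = False
    zinc_penalty: float = Field(0.0, ge=0, description="Mg/ha lost without zinc")
    noise_sd: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "ResponseModel":
        if self.potential_yield < self.base_yield_no_n:
            raise ValueError("potential yield must be at least the base yield")
        return self


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_interviews(spec: CohortSpec, rng: Optional[np.random.Generator] = None) -> list[FarmerInterview]:
    """Draw ``spec.n_trials`` farmer interviews.

    Long-duration varieties are drawn only in kharif and
    short-duration varieties only in rabi (medium appears in both),
    matching the seasonal variety pattern of eastern India. The
    previous crop is taken to be the same rice crop, so the
    previous-crop yield equals the reported historical yield.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_trials
    seasons = rng.choice(list(spec.season_mix), p=list(spec.season_mix.values()), size=n)
    aczs = rng.choice(list(spec.acz_mix), p=list(spec.acz_mix.values()), size=n)
    gyr = _truncnorm_rvs(spec.gyr_mean, spec.gyr_sd, *spec.gyr_bounds, n, rng)

    short = [v for v in spec.variety_table if v[1] <= 120]
    medium = [v for v in spec.variety_table if 120 < v[1] <= 140]
    long_ = [v for v in spec.variety_table if v[1] > 140]

    interviews = []
    for i in range(n):
        season = seasons[i]
        year_mix = spec.year_mix[season]
        year = rng.choice(list(year_mix), p=list(year_mix.values()))
        if season == "kharif":
            pool = medium + long_
            water = (
                WaterRegime.RAINFED
                if rng.random() < spec.kharif_rainfed_probability
                else WaterRegime.IRRIGATED
            )
        else:
            pool = short + medium
            water = WaterRegime.IRRIGATED
        name, duration = pool[rng.integers(len(pool))]
        lo, hi = spec.seedling_age_range
        age = int(rng.integers(lo, hi + 1))
        # keep panicle initiation comfortably after the basal window
        age = min(age, duration - 73)
        delay = 0.0
        if rng.random() < spec.late_transplant_probability:
            delay = float(rng.uniform(*spec.late_transplant_delay_range))
        interviews.append(
            FarmerInterview(
                field_id=f"F{i:04d}",
                district=DISTRICTS[rng.integers(len(DISTRICTS))],
                acz=aczs[i],
                season=Season(season),
                year=str(year),
                water_regime=water,
                variety_name=name,
                growth_duration_days=duration,
                seedling_age_days=age,
                transplant_delay_days=delay,
                historical_yield_GYR=float(gyr[i]),
                previous_crop_yield=float(gyr[i]),
                residue_retained_fraction=0.15,
                farmer_applies_zinc=bool(rng.random() < spec.ffp_zinc_probability),
            )
        )
    return interviews


def sample_ffp_practice(
    interview: FarmerInterview,
    spec: CohortSpec,
    rng: np.random.Generator,
    products: Sequence[FertilizerProduct],
) -> list[tuple[int, str, float]]:
    """Draw one farmer's planned practice: (DAT, product, kg/ha) list.

    Urea-N goes on in 1-3 applications (probabilities 5/20/75%) with
    the largest share in the first application at or before 20 DAT. P
    goes on basally as DAP — whose own N rides on top of the planned
    urea, as it does for real farmers — and K basally as muriate of
    potash.
    """
    season = interview.season.value
    urea_n = float(rng.uniform(*spec.ffp_n_range[season]))
    p_total = float(rng.uniform(*spec.ffp_p_range[season]))
    k_total = float(rng.uniform(*spec.ffp_k_range[season]))

    by_name = {p.name: p for p in products}
    urea_frac = grade_to_elemental(by_name["urea"])[0]
    dap_p_frac = grade_to_elemental(by_name["DAP"])[1]
    mop_k_frac = grade_to_elemental(by_name["MOP"])[2]

    n_apps = 1 + int(rng.choice(3, p=list(spec.ffp_split_count_probs)))
    first_dat = int(rng.integers(5, 15))
    if n_apps == 1:
        fractions, dats = (1.0,), (first_dat,)
    elif n_apps == 2:
        fractions, dats = (0.60, 0.40), (first_dat, int(rng.integers(25, 36)))
    else:
        fractions, dats = (
            (0.45, 0.30, 0.25),
            (first_dat, int(rng.integers(25, 33)), int(rng.integers(36, 50))),
        )

    practice: list[tuple[int, str, float]] = []
    if p_total > 0:
        practice.append((first_dat, "DAP", p_total / dap_p_frac))
    if k_total > 0:
        practice.append((first_dat, "MOP", k_total / mop_k_frac))
    for frac, dat in zip(fractions, dats):
        practice.append((dat, "urea", urea_n * frac / urea_frac))
    practice.sort(key=lambda x: x[0])
    return practice


def compute_timing_factor(plan: TreatmentPlan, pi_dat: int) -> float:
    """Effectiveness multiplier for the N in a plan.

    N applied more than ten days after panicle initiation counts only
    half, and a plan putting more than half its N in the first
    application loses a further 15%. The result is in (0, 1].
    """
    n_by_app = [
        (app.dat, app.amount * _product_n_fraction(app.product))
        for app in plan.applications
    ]
    total = sum(a for _, a in n_by_app)
    if total <= 0:
        return 1.0
    late = sum(a for dat, a in n_by_app if dat > pi_dat + 10) / total
    first_dat = min(dat for dat, _ in n_by_app)
    basal_frac = sum(a for dat, a in n_by_app if dat == first_dat) / total
    factor = 1.0 - 0.5 * late
    if basal_frac > 0.5:
        factor *= 0.85
    return max(factor, 1e-6)


_N_FRACTIONS: dict[str, float] = {}


def _product_n_fraction(name: str) -> float:
    if not _N_FRACTIONS:
        from .products import default_products

        _N_FRACTIONS.update(
            {p.name: grade_to_elemental(p)[0] for p in default_products()}
        )
    return _N_FRACTIONS.get(name, 0.0)


def simulate_yield(
    plan: TreatmentPlan,
    model: ResponseModel,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """One plot's grain yield (Mg/ha) under the linear-plateau response.

    ``yield = clip(base + AE * FN * timing - zinc_penalty * [responsive
    and no zinc] + noise, 0, potential)``.
    """
    timing = compute_timing_factor(plan, model.pi_dat)
    y = model.base_yield_no_n + model.agronomic_efficiency * plan.total_n * timing
    if model.zinc_responsive and plan.zinc_sulfate <= 0:
        y -= model.zinc_penalty
    if model.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        y += float(rng.normal(0.0, model.noise_sd))
    return float(np.clip(y, 0.0, model.potential_yield))


def sample_response_model(
    interview: FarmerInterview,
    spec: CohortSpec,
    rng: np.random.Generator,
    cfg: Optional[EngineConfig] = None,
) -> ResponseModel:
    """Draw the field's yield response, anchored to its history.

    The no-N base yield is the historical yield minus what a typical
    farmer N dose would have contributed at this field's agronomic
    efficiency, and the plateau sits a sampled headroom above the
    historical yield, so the generated history is consistent with the
    response surface.
    """
    cfg = cfg or EngineConfig()
    ae = float(rng.uniform(*spec.ae_range))
    typical_n = 75.0 if interview.season == Season.KHARIF else 98.0
    base = max(0.3, interview.historical_yield_GYR - ae * typical_n)
    potential = interview.historical_yield_GYR + float(rng.uniform(*spec.headroom_range))
    _, _, pi = stage_schedule(interview.growth_duration_days, interview.seedling_age_days, cfg)
    return ResponseModel(
        base_yield_no_n=base,
        potential_yield=potential,
        agronomic_efficiency=ae,
        pi_dat=pi,
        zinc_responsive=bool(rng.random() < spec.zinc_responsive_probability),
        zinc_penalty=spec.zinc_penalty,
        noise_sd=spec.noise_sd,
    )


def generate_trials(
    spec: CohortSpec,
    products: Sequence[FertilizerProduct],
    cfg: Optional[EngineConfig] = None,
) -> list[TrialRecord]:
    """Generate a complete synthetic trial cohort.

    For each sampled interview: the engine's field-specific plan, the
    blanket plan and a sampled farmer practice are built, and the three
    plot yields are simulated from the same field response model.
    """
    cfg = cfg or EngineConfig()
    rng = np.random.default_rng(spec.seed)
    trials = []
    for interview in sample_interviews(spec, rng):
        rcm = build_rcm_plan(interview, products, cfg)
        bfr = build_bfr_plan(interview, products, cfg)
        practice = sample_ffp_practice(interview, spec, rng, products)
        ffp = build_ffp_plan(practice, interview.farmer_applies_zinc, products)
        model = sample_response_model(interview, spec, rng, cfg)
        yields = {
            label: simulate_yield(plan, model, rng)
            for label, plan in (("RCM", rcm), ("FFP", ffp), ("BFR", bfr))
        }
        trials.append(
            TrialRecord(
                interview=interview,
                plans={"RCM": rcm, "FFP": ffp, "BFR": bfr},
                yields=yields,
                prices=price_set_for(interview.season.value, interview.year),
            )
        )
    return trials
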