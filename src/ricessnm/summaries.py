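"""Canonical engine-level summaries used in validation and reporting.

These are whole-rule summaries — sweeps of the target-yield and
K-split rules, the blanket plan's delivered nutrients, and the zinc
share of fertilizer cost over a synthetic cohort — computed entirely
from the package's own operations.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import EngineConfig
from .engine import build_prescription, k_split_amounts, set_target_yield
from .interview import FarmerInterview
from .products import FertilizerProduct, allocate_products, total_fertilizer_cost
from .treatments import build_bfr_plan


def target_yield_sweep(
    cfg: Optional[EngineConfig] = None,
    lo: float = 0.5,
    hi: float = 10.0,
    step: float = 0.1,
) -> tuple[float, float, int]:
    """(min, max, n) of the target yield over a sweep of historical yields."""
    cfg = cfg or EngineConfig()
    gyr_values = np.arange(lo, hi + step / 2, step)
    targets = [
        set_target_yield(
            FarmerInterview(
                field_id="sweep",
                growth_duration_days=135,
                seedling_age_days=25,
                historical_yield_GYR=float(g),
            ),
            cfg,
        )
        for g in gyr_values
    ]
    return min(targets), max(targets), len(targets)


def largest_all_basal_k(cfg: Optional[EngineConfig] = None, max_rate: int = 100) -> int:
    """Largest integer K rate (kg/ha) scheduled as a single basal dose."""
    cfg = cfg or EngineConfig()
    return max(fk for fk in range(1, max_rate + 1) if len(k_split_amounts(float(fk), cfg)) == 1)


def bfr_delivered_npk(
    products: Sequence[FertilizerProduct], cfg: Optional[EngineConfig] = None
) -> tuple[float, float, float]:
    """Elemental N/P/K delivered by the blanket plan, recomputed from
    the allocated product amounts."""
    cfg = cfg or EngineConfig()
    iv = FarmerInterview(
        field_id="bfr",
        growth_duration_days=135,
        seedling_age_days=25,
        historical_yield_GYR=4.5,
    )
    plan = build_bfr_plan(iv, products, cfg)
    return plan.total_n, plan.total_p, plan.total_k


def zinc_cost_share(
    products: Sequence[FertilizerProduct],
    cfg: Optional[EngineConfig] = None,
    n_fields: int = 209,
    seed: int = 0,
) -> float:
    """Mean zinc-sulfate share of total fertilizer cost, in percent.

    Draws ``n_fields`` interviews with historical yield from the
    truncated Normal(4.4, 0.7) on [1.7, 6.3], previous-crop yield equal
    to the historical yield and no transplanting delay; runs the engine
    and the product allocation on each; and averages zinc sulfate's
    percentage of the total fertilizer cost across fields.
    """
    cfg = cfg or EngineConfig()
    rng = np.random.default_rng(seed)
    a, b = (1.7 - 4.4) / 0.7, (6.3 - 4.4) / 0.7
    gyr = stats.truncnorm.rvs(a, b, loc=4.4, scale=0.7, size=n_fields, random_state=rng)
    zinc = next(p for p in products if "zinc" in p.name.lower())
    shares = []
    for i, g in enumerate(gyr):
        iv = FarmerInterview(
            field_id=f"Z{i:04d}",
            growth_duration_days=135,
            seedling_age_days=25,
            historical_yield_GYR=float(g),
            previous_crop_yield=float(g),
        )
        rx = build_prescription(iv, cfg)
        alloc = allocate_products(rx, products, cfg, include_zinc=True)
        tfc = total_fertilizer_cost(alloc, products)
        zinc_cost = cfg.zinc_sulfate_rate * zinc.price
        shares.append(100.0 * zinc_cost / tfc)
    return float(np.mean(shares))
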