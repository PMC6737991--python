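"""Partial-budget economics of a fertilizer treatment.

Gross return is grain yield times the farmgate price of unmilled rice;
gross return above fertilizer cost (GRF) subtracts the total fertilizer
cost (TFC); added net benefit (ANB) is the GRF difference between two
treatments on the same field; partial factor productivity of N
(PFP = 1000 * GY / FN) is kg grain per kg fertilizer N. Exceedance
curves give, for a set of per-field ANB values, the probability of
obtaining at least a given benefit.

The farmgate price is US$ per kilogram of unmilled rice, so with yield
in Mg/ha the gross return is 1000 * yield * price US$/ha.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator


class EconomicsResult(BaseModel):
    """Partial-budget metrics for one field-treatment."""

    model_config = ConfigDict(frozen=True)

    grain_yield: float  # Mg/ha at 14% moisture
    fn_applied: float   # kg N/ha
    tfc: float          # US$/ha
    gross_return: float # US$/ha
    grf: float          # US$/ha
    pfp: Optional[float] = None  # kg grain per kg N; undefined when FN = 0

    @model_validator(mode="after")
    def _check(self) -> "EconomicsResult":
        if abs(self.grf - (self.gross_return - self.tfc)) > 1e-9:
            raise ValueError("GRF must equal gross return minus TFC")
        return self


def gross_return_above_fertilizer_cost(
    grain_yield: float, paddy_price: float, tfc: float, fn_applied: float = 0.0
) -> EconomicsResult:
    """GRF for one field-treatment.

    ``gross_return = 1000 * yield * price`` (yield Mg/ha, price US$/kg)
    and ``grf = gross_return - tfc``.
    """
    if grain_yield < 0 or tfc < 0 or paddy_price < 0:
        raise ValueError("yield, price and TFC must be non-negative")
    gross = 1000.0 * grain_yield * paddy_price
    return EconomicsResult(
        grain_yield=grain_yield,
        fn_applied=fn_applied,
        tfc=tfc,
        gross_return=gross,
        grf=gross - tfc,
        pfp=partial_factor_productivity(grain_yield, fn_applied) if fn_applied > 0 else None,
    )


def added_net_benefit(grf_a: float, grf_b: float) -> float:
    """ANB of treatment a over treatment b: the difference in GRF."""
    return grf_a - grf_b


def partial_factor_productivity(grain_yield: float, fn: float) -> float:
    """PFP = 1000 * GY / FN, kg grain per kg fertilizer N."""
    if fn <= 0:
        raise ValueError("PFP is undefined when no fertilizer N was applied")
    return 1000.0 * grain_yield / fn


def exceedance_curve(
    anb_values: Sequence[float], thresholds: Sequence[float]
) -> np.ndarray:
    """P(ANB >= t) for each threshold t (inclusive comparison).

    The empirical exceedance probability is a non-increasing,
    right-continuous step function of the threshold with values in
    [0, 1].
    """
    values = np.asarray(anb_values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    t = np.asarray(thresholds, dtype=float)
    return (values[None, :] >= t[:, None]).mean(axis=1)
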