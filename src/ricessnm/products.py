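"""Fertilizer products: grade conversion, allocation and costing.

Fertilizer grades are quoted as N-P2O5-K2O mass percentages while
prescriptions are elemental, so grades are converted with the standard
stoichiometric factors P = 0.4364 * P2O5 and K = 0.8301 * K2O.

Allocation is a deterministic priority rule rather than least-cost
blending: zinc sulfate first (flat policy rate), then the P demand from
the product richest in P, then the K schedule from the product richest
in K, then urea-type N to fill what the P and K carriers did not
already deliver. This mirrors how the recommendations are actually
composed in the field (urea + DAP + MOP dominate) and makes every
kilogram explainable.
"""

from __future__ import annotations

import importlib.resources
import warnings
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import EngineConfig
from .engine import STAGE_BASAL, NutrientPrescription, SplitApplication

P2O5_TO_P = 0.4364  # 2*30.974 / 141.94
K2O_TO_K = 0.8301   # 2*39.098 / 94.196


class FertilizerProduct(BaseModel):
    """One fertilizer source: grade (N-P2O5-K2O %) and price."""

    model_config = ConfigDict(frozen=True)

    name: str
    grade_n: float = Field(0.0, ge=0, le=100)
    grade_p2o5: float = Field(0.0, ge=0, le=100)
    grade_k2o: float = Field(0.0, ge=0, le=100)
    price: float = Field(0.0, ge=0, description="US$ per kg")

    @model_validator(mode="after")
    def _check(self) -> "FertilizerProduct":
        if self.grade_n + self.grade_p2o5 + self.grade_k2o > 100:
            raise ValueError("grade percentages sum to more than 100")
        return self


def grade_to_elemental(product: FertilizerProduct) -> tuple[float, float, float]:
    """Elemental (N, P, K) mass fractions of a product."""
    return (
        product.grade_n / 100.0,
        P2O5_TO_P * product.grade_p2o5 / 100.0,
        K2O_TO_K * product.grade_k2o / 100.0,
    )


class Application(BaseModel):
    """One product application in a plan."""

    model_config = ConfigDict(frozen=True)

    stage: str
    dat: int
    product: str
    amount: float = Field(ge=0, description="kg product per ha")


class ProductAllocation(BaseModel):
    """Product applications realizing a prescription, with bookkeeping.

    ``unmet_*`` is the prescription minus what the chosen products
    deliver; it is positive when no product could supply a nutrient and
    negative when a compound carrier over-delivers.
    """

    model_config = ConfigDict(frozen=True)

    applications: tuple[Application, ...]
    delivered_n: float
    delivered_p: float
    delivered_k: float
    unmet_n: float
    unmet_p: float
    unmet_k: float


def _is_zinc(product: FertilizerProduct) -> bool:
    return "zinc" in product.name.lower()


def _npk_products(products: Sequence[FertilizerProduct]) -> list[FertilizerProduct]:
    return [p for p in products if not _is_zinc(p)]


def allocate_products(
    prescription: NutrientPrescription,
    products: Sequence[FertilizerProduct],
    cfg: Optional[EngineConfig] = None,
    include_zinc: bool = True,
    zinc_rate: Optional[float] = None,
) -> ProductAllocation:
    """Allocate a prescription to products by the priority rule.

    Order: (1) zinc sulfate basal at the policy rate when the policy is
    on and a zinc product is listed; (2) the basal P demand from the
    highest-P-fraction product; (3) each K application from the
    highest-K-fraction product; (4) the N these carriers deliver is
    credited against the N splits in stage order (basal first); (5) the
    residual N of each split comes from the highest-N single-nutrient
    product. Residual demand no product can supply is reported as
    unmet, never dropped. Ties break by list order.
    """
    if not products:
        raise ValueError("product list is empty")
    cfg = cfg or EngineConfig()

    applications: list[Application] = []

    if include_zinc:
        rate = cfg.zinc_sulfate_rate if zinc_rate is None else zinc_rate
        zinc = next((p for p in products if _is_zinc(p)), None)
        if zinc is not None and rate > 0:
            basal_dat = prescription.p_split.dat
            applications.append(
                Application(stage=STAGE_BASAL, dat=basal_dat, product=zinc.name, amount=rate)
            )

    npk = _npk_products(products)
    fracs = {p.name: grade_to_elemental(p) for p in npk}

    # N carried into each split by the P and K sources, keyed by split index
    n_credit_total = 0.0

    # (2) P basal
    if prescription.fp > 1e-12:
        p_source = max(npk, key=lambda p: fracs[p.name][1], default=None)
        if p_source is not None and fracs[p_source.name][1] > 0:
            amount = prescription.fp / fracs[p_source.name][1]
            applications.append(
                Application(
                    stage=prescription.p_split.stage,
                    dat=prescription.p_split.dat,
                    product=p_source.name,
                    amount=amount,
                )
            )
            n_credit_total += amount * fracs[p_source.name][0]

    # (3) K per split
    if prescription.fk > 1e-12:
        k_source = max(npk, key=lambda p: fracs[p.name][2], default=None)
        if k_source is not None and fracs[k_source.name][2] > 0:
            for split in prescription.k_splits:
                if split.amount <= 1e-12:
                    continue
                amount = split.amount / fracs[k_source.name][2]
                applications.append(
                    Application(
                        stage=split.stage, dat=split.dat, product=k_source.name, amount=amount
                    )
                )
                n_credit_total += amount * fracs[k_source.name][0]

    # (4)+(5) residual N per split from the best single-nutrient N source
    n_only = [
        p for p in npk if fracs[p.name][0] > 0 and fracs[p.name][1] == 0 and fracs[p.name][2] == 0
    ]
    n_source = max(n_only, key=lambda p: fracs[p.name][0], default=None)
    credit = n_credit_total
    for split in prescription.n_splits:
        need = split.amount
        take = min(credit, need)
        need -= take
        credit -= take
        if need <= 1e-12:
            continue
        if n_source is not None:
            applications.append(
                Application(
                    stage=split.stage,
                    dat=split.dat,
                    product=n_source.name,
                    amount=need / fracs[n_source.name][0],
                )
            )

    delivered = delivered_nutrients(applications, products)
    alloc = ProductAllocation(
        applications=tuple(applications),
        delivered_n=delivered[0],
        delivered_p=delivered[1],
        delivered_k=delivered[2],
        unmet_n=prescription.fn - delivered[0],
        unmet_p=prescription.fp - delivered[1],
        unmet_k=prescription.fk - delivered[2],
    )
    if (
        max(alloc.unmet_n, alloc.unmet_p, alloc.unmet_k) > 1e-6
        and prescription.fn + prescription.fp + prescription.fk > 0
    ):
        warnings.warn(
            "allocation left nutrient demand unmet: "
            f"N {alloc.unmet_n:.2f}, P {alloc.unmet_p:.2f}, K {alloc.unmet_k:.2f} kg/ha",
            stacklevel=2,
        )
    return alloc


def delivered_nutrients(
    applications: Sequence[Application], products: Sequence[FertilizerProduct]
) -> tuple[float, float, float]:
    """Recompute elemental N/P/K delivered by a list of applications."""
    by_name = {p.name: p for p in products}
    n = p = k = 0.0
    for app in applications:
        if app.product not in by_name:
            raise KeyError(f"unknown product {app.product!r}")
        fn, fp, fk = grade_to_elemental(by_name[app.product])
        n += app.amount * fn
        p += app.amount * fp
        k += app.amount * fk
    return n, p, k


def total_fertilizer_cost(
    allocation: ProductAllocation | Sequence[Application],
    products: Sequence[FertilizerProduct],
) -> float:
    """Total fertilizer cost (TFC), US$/ha: sum of amount * price."""
    apps = (
        allocation.applications
        if isinstance(allocation, ProductAllocation)
        else tuple(allocation)
    )
    by_name = {p.name: p for p in products}
    total = 0.0
    for app in apps:
        if app.product not in by_name:
            raise ValueError(f"no price known for product {app.product!r}")
        total += app.amount * by_name[app.product].price
    return total


def default_product_table() -> pd.DataFrame:
    """The packaged eight-product table (grades and farmgate prices)."""
    resource = importlib.resources.files("ricessnm").joinpath("data/products.csv")
    with resource.open() as fh:
        return pd.read_csv(fh, comment="#")


def products_from_table(table: pd.DataFrame) -> list[FertilizerProduct]:
    """Build product records from a flat table."""
    return [
        FertilizerProduct(
            name=row["name"],
            grade_n=row["grade_n"],
            grade_p2o5=row["grade_p2o5"],
            grade_k2o=row["grade_k2o"],
            price=row["price_usd_per_kg"],
        )
        for _, row in table.iterrows()
    ]


def default_products() -> list[FertilizerProduct]:
    """Packaged products as records."""
    return products_from_table(default_product_table())
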