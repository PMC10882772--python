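"""Use phase: secondary-product cohorts with Weibull service lives.

Primary products are sorted into consumer end uses by national consumption
shares. A vintage of product carbon is a cohort with a Weibull clock: the
carbon remaining in use ``x`` years after market entry is

    S(x) = C * exp(-(x / lambda)^k)

with shape ``k`` (2.63 by default) and scale ``lambda`` derived from the
product's estimated lifespan mode,

    lambda = mode / (1 - 1/k)^(1/k),

so the annualized transition out of use peaks at the mode. New single- and
multi-family housing carbon transitions per application (floors, walls,
doors, ...) with application-specific modes; every other category
transitions with the secondary product's own mode.

At year 0 a construction waste deduction (5.6%) applies to construction
categories and a manufacturing waste deduction (8%) to manufactured goods;
the deducted carbon leaves use immediately and is never recycled.
"""

from __future__ import annotations

import dataclasses
import math

import pandas as pd

from . import categories as cat
from .params import AllocationTable, ParameterError, ParameterSet


def weibull_scale(mode: float, shape_k: float) -> float:
    """Scale lambda from the lifespan mode: mode / (1 - 1/k)^(1/k)."""
    if mode <= 0:
        raise ParameterError(f"mode must be positive, got {mode}")
    if shape_k <= 1:
        raise ParameterError(f"shape k must exceed 1 (mode undefined), got {shape_k}")
    return mode / (1.0 - 1.0 / shape_k) ** (1.0 / shape_k)


def survival(carbon: float, x: float, scale_lambda: float, shape_k: float) -> float:
    """Carbon still in use after ``x`` years: C * exp(-(x/lambda)^k)."""
    if x < 0:
        raise ParameterError("age must be non-negative")
    return carbon * math.exp(-((x / scale_lambda) ** shape_k))


@dataclasses.dataclass
class UseCohort:
    """A vintage of secondary-product carbon with its Weibull clock.

    ``cycles_remaining`` counts how many more times outflows of this cohort
    may be recycled as the same product.
    """

    product: str
    vintage: int
    carbon: float                    # tC currently in use
    mode: float                      # years, lifespan estimate
    shape_k: float
    application: str | None = None   # housing sub-cohort label
    cycles_remaining: int = 0
    initial_carbon: float = dataclasses.field(default=0.0)
    scale_lambda: float = dataclasses.field(default=0.0)

    def __post_init__(self) -> None:
        if self.carbon < 0:
            raise ParameterError("cohort carbon must be non-negative")
        if self.initial_carbon == 0.0:
            self.initial_carbon = self.carbon
        if self.scale_lambda == 0.0:
            self.scale_lambda = weibull_scale(self.mode, self.shape_k)

    def survival_at(self, age: float) -> float:
        return survival(self.initial_carbon, age, self.scale_lambda, self.shape_k)


@dataclasses.dataclass(frozen=True)
class Outflow:
    """Carbon leaving use in a given year, with its origin."""

    year: int
    product: str
    carbon: float
    origin: str = "lifespan"   # lifespan | construction_waste | manufacturing_waste
    cycles_remaining: int = 0


def allocate_secondary(primary: pd.Series, params: ParameterSet,
                       vintage: int = 0) -> list[UseCohort]:
    """Sort a primary-product vector (tC) into use cohorts.

    Housing carbon is split into application sub-cohorts with
    application-specific modes. Cohort carbon sums to the primary carbon
    allocated to use (pellets/burned are not use products and must not
    appear in ``primary``).
    """
    end_use = params.table("end_use")
    k = params.value("weibull_shape_k")
    lifespans = params.rate("lifespans")
    happ = params.table("housing_applications")
    hmodes = params.rate("housing_application_modes")
    cycles = _initial_cycles(params)

    unknown = set(primary.index) - set(cat.USE_PRIMARY_PRODUCTS)
    if unknown:
        raise ParameterError(f"unknown primary product(s) {sorted(unknown)}")

    totals = pd.Series(0.0, index=list(cat.SECONDARY_PRODUCTS))
    for prod, carbon in primary.items():
        if carbon == 0.0:
            continue
        totals = totals.add(end_use.row(prod) * carbon, fill_value=0.0)

    cohorts: list[UseCohort] = []
    for sec, carbon in totals.items():
        if carbon <= 0.0:
            continue
        if sec in cat.HOUSING_CATEGORIES:
            for app, share in happ.row(sec).items():
                if share <= 0.0:
                    continue
                cohorts.append(UseCohort(
                    sec, vintage, carbon * share,
                    hmodes.value(app, "mode"), k, application=app,
                ))
        else:
            cohorts.append(UseCohort(
                sec, vintage, carbon, lifespans.value(sec, "mode"), k,
                cycles_remaining=cycles.get(sec, 0),
            ))
    return cohorts


def _initial_cycles(params: ParameterSet) -> dict[str, int]:
    pallets = int(params.value("pallet_recycle_times"))
    paper = int(params.value("paper_recycle_times"))
    out = {"shipping_pallets": pallets}
    out.update({p: paper for p in cat.PAPER_PRODUCTS})
    return out


def apply_waste_deductions(cohorts: list[UseCohort], params: ParameterSet
                           ) -> tuple[list[UseCohort], list[Outflow]]:
    """Year-0 construction (5.6%) and manufacturing (8%) waste deductions.

    Deducted carbon leaves use at the cohort's vintage year and is flagged
    non-recyclable. Cohorts are returned reduced; unaffected categories are
    returned unchanged.
    """
    cw = params.value("construction_waste")
    mw = params.value("manufacturing_waste")
    reduced: list[UseCohort] = []
    outflows: list[Outflow] = []
    for c in cohorts:
        if c.product in cat.CONSTRUCTION_WASTE_PRODUCTS:
            frac, origin = cw, "construction_waste"
        elif c.product in cat.MANUFACTURING_WASTE_PRODUCTS:
            frac, origin = mw, "manufacturing_waste"
        else:
            reduced.append(c)
            continue
        waste = c.carbon * frac
        kept = c.carbon - waste
        reduced.append(UseCohort(
            c.product, c.vintage, kept, c.mode, c.shape_k,
            application=c.application, cycles_remaining=c.cycles_remaining,
        ))
        if waste > 0:
            outflows.append(Outflow(c.vintage, c.product, waste, origin,
                                    cycles_remaining=0))
    return reduced, outflows


def step_transitions(cohorts: list[UseCohort], year: int) -> list[Outflow]:
    """Annual survival-difference outflows; decrements cohort carbon in place.

    For a cohort of age ``a = year - vintage`` the outflow is
    ``C0 * (S(a-1) - S(a))``, which sums to the full cohort carbon as the
    age grows (the annualized Weibull density integrates to 1).
    """
    outflows: list[Outflow] = []
    for c in cohorts:
        age = year - c.vintage
        if age < 1 or c.carbon <= 0.0:
            continue
        remaining = c.survival_at(age)
        leaving = c.carbon - remaining
        if leaving <= 0.0:
            continue
        c.carbon = remaining
        outflows.append(Outflow(year, c.product, leaving, "lifespan",
                                cycles_remaining=c.cycles_remaining))
    return outflows
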