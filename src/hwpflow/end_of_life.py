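"""End of life: recycling, downcycling, landfilling, decay and methane.

Carbon leaving use is routed by a per-product allocation row into recycling
(same product, fresh clock, one fewer cycle), downcycling (landscaping,
animal bedding, posts & pilings, furniture, other manufacturing — the
destination category's lifespan applies), landfilling (municipal solid
waste or construction & demolition streams, as wood or paper material) or
immediate biogenic CO2 emission. Outflows that can no longer be recycled
(waste deductions, exhausted cycles) have their recycle share reallocated
proportionally across the landfill and emitted shares.

Landfilled carbon splits into a decayable part ``C_i * DOC_f`` that decays
first-order with a material half-life, and a permanent part
``C_i * (1 - DOC_f)``:

    stored(x) = C_i * DOC_f * exp(-x ln2 / half_life) + C_i * (1 - DOC_f)

Of each year's decayed carbon a fraction F forms methane; recovered (R)
and oxidized (OX) methane is booked as biogenic CO2, the rest is emitted
as biogenic CH4. The decay clock starts in the landfilling year (zero lag).
"""

from __future__ import annotations

import dataclasses
import math

import pandas as pd

from . import categories as cat
from .params import ParameterError, ParameterSet
from .use_phase import Outflow, UseCohort


@dataclasses.dataclass(frozen=True)
class MethaneParams:
    """Landfill gas parameters (all portions in [0, 1])."""

    F: float          # fraction of decayed C forming CH4
    R: float          # fraction of CH4 recovered
    OX: float         # fraction of non-recovered CH4 oxidized
    GWP_CH4: float

    def __post_init__(self) -> None:
        for name in ("F", "R", "OX"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"methane parameter {name}={v} outside [0, 1]")
        if self.GWP_CH4 <= 0:
            raise ParameterError("GWP_CH4 must be positive")

    @classmethod
    def from_params(cls, params: ParameterSet) -> "MethaneParams":
        return cls(params.value("ch4_fraction_f"), params.value("ch4_recovery_r"),
                   params.value("ch4_oxidation_ox"), params.value("gwp_ch4"))


@dataclasses.dataclass
class LandfillCohort:
    """Decayable and permanent carbon landfilled in one year."""

    stream: str            # "msw" or "cd"
    material: str          # "wood" or "paper"
    vintage: int
    decayable: float       # C_i * DOC_f
    permanent: float       # C_i * (1 - DOC_f)
    half_life: float

    def stored_at(self, x: float) -> float:
        """tC stored ``x`` years after landfilling (first-order decay)."""
        if x < 0:
            raise ParameterError("age must be non-negative")
        return self.decayable * math.exp(-x * math.log(2.0) / self.half_life) + self.permanent

    def decayed_between(self, x0: float, x1: float) -> float:
        return self.stored_at(x0) - self.stored_at(x1)


def landfill_stored(c_i: float, doc_f: float, half_life: float, x: float) -> float:
    """Carbon stored in a landfill ``x`` years after disposal of ``c_i`` tC."""
    cohort = LandfillCohort("msw", "wood", 0, c_i * doc_f, c_i * (1 - doc_f), half_life)
    return cohort.stored_at(x)


@dataclasses.dataclass
class RoutedOutflow:
    """Destinations of one routed outflow; carbon fully assigned."""

    recycled: UseCohort | None
    downcycled: list[UseCohort]
    landfilled: list[LandfillCohort]
    emitted: float

    def total(self) -> float:
        t = self.emitted + (self.recycled.carbon if self.recycled else 0.0)
        t += sum(c.carbon for c in self.downcycled)
        t += sum(c.decayable + c.permanent for c in self.landfilled)
        return t


def _material_of(product: str) -> str:
    return "paper" if product in cat.PAPER_PRODUCTS else "wood"


class RoutingContext:
    """Plain-dict snapshot of the routing inputs (hot-path cache).

    Routing is evaluated once per outflow per year; pulling the allocation
    rows, lifespans and landfill scalars out of pandas keeps the annual
    loop cheap without changing any semantics.
    """

    def __init__(self, params: ParameterSet) -> None:
        wr = params.table("waste_routing").data
        self.shares = {p: row.to_dict() for p, row in wr.iterrows()}
        self.lifespans = params.rate("lifespans").data["mode"].to_dict()
        self.shape_k = params.value("weibull_shape_k")
        self.doc_f = {
            (m, s): params.value(f"doc_f_{m}_{s}")
            for m in cat.LANDFILL_MATERIALS for s in cat.LANDFILL_STREAMS
        }
        self.half_life = {m: params.value(f"half_life_{m}")
                          for m in cat.LANDFILL_MATERIALS}


def route_outflow(outflow: Outflow,
                  params: ParameterSet | RoutingContext) -> RoutedOutflow:
    """Assign an outflow's carbon to recycling/downcycling/landfill/emission.

    If the outflow cannot be recycled (product not recyclable, no cycles
    remaining, or waste-deduction origin) the recycle share is reallocated
    proportionally across the landfill and emitted shares.
    """
    if outflow.carbon < 0:
        raise ParameterError("outflow carbon must be non-negative")
    ctx = params if isinstance(params, RoutingContext) else RoutingContext(params)
    try:
        shares = dict(ctx.shares[outflow.product])
    except KeyError:
        raise ParameterError(f"no waste routing for product {outflow.product!r}")

    recyclable = (
        outflow.product in cat.RECYCLABLE_PRODUCTS
        and outflow.cycles_remaining > 0
        and outflow.origin == "lifespan"
    )
    if not recyclable and shares.get("recycle", 0.0) > 0.0:
        rec = shares.pop("recycle")
        sinks = ("landfill_msw", "landfill_cd", "emitted")
        pool = sum(shares[s] for s in sinks)
        if pool > 0:
            for s in sinks:
                shares[s] += rec * shares[s] / pool
        else:
            shares["emitted"] = shares.get("emitted", 0.0) + rec
        shares["recycle"] = 0.0

    c = outflow.carbon
    k = ctx.shape_k

    recycled = None
    if shares.get("recycle", 0.0) > 0.0:
        recycled = UseCohort(
            outflow.product, outflow.year, c * shares["recycle"],
            ctx.lifespans[outflow.product], k,
            cycles_remaining=outflow.cycles_remaining - 1,
        )

    downcycled = []
    for dest in cat.DOWNCYCLE_DESTINATIONS:
        share = shares.get("downcycle_" + dest, 0.0)
        if share > 0.0:
            downcycled.append(UseCohort(
                dest, outflow.year, c * share, ctx.lifespans[dest], k,
            ))

    material = _material_of(outflow.product)
    landfilled = []
    for stream in cat.LANDFILL_STREAMS:
        share = shares.get(f"landfill_{stream}", 0.0)
        if share > 0.0:
            doc_f = ctx.doc_f[(material, stream)]
            half_life = ctx.half_life[material]
            amt = c * share
            landfilled.append(LandfillCohort(
                stream, material, outflow.year,
                amt * doc_f, amt * (1 - doc_f), half_life,
            ))

    return RoutedOutflow(recycled, downcycled, landfilled, c * shares.get("emitted", 0.0))


def methane_partition(decayed_c: float, mp: MethaneParams) -> tuple[float, float]:
    """Split a year's decayed landfill carbon into (CH4-C, CO2-C) emitted.

    CH4-C = decayed * F * (1-R) * (1-OX); the recovered and oxidized
    methane carbon is booked as CO2, so carbon is conserved.
    """
    if decayed_c < 0:
        raise ParameterError("decayed carbon must be non-negative")
    ch4_c = decayed_c * mp.F * (1.0 - mp.R) * (1.0 - mp.OX)
    return ch4_c, decayed_c - ch4_c


def to_co2e(carbon: float, gas: str, gwp_ch4: float = 28.0) -> float:
    """tC -> tCO2e: CO2 via 44/12; CH4 via 16/12 times its GWP."""
    if carbon < 0:
        raise ParameterError("carbon must be non-negative")
    if gas == "CO2":
        return carbon * cat.CO2_PER_C
    if gas == "CH4":
        return carbon * cat.CH4_PER_C * gwp_ch4
    raise ParameterError(f"unknown gas {gas!r}")
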