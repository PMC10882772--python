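"""Annual carbon ledger: simulation orchestration, discounting, Bern model.

``simulate`` runs the full chain — harvest, milling, use, end of life —
and returns a :class:`Trajectory`, the annual ledger of carbon in use (by
secondary product), carbon in landfills (by stream), biogenic CO2 and CH4
pulses, and fossil-fuel pulses over years 0..horizon. Year 0 is market
entry: it carries the year-0 combustion of pellets and burned residue, the
fossil-fuel pulses, and the routed waste-deduction outflows.

The flow model is linear in its inputs, so multi-year harvest series are
superposed cohorts, and per-100-tonne unit runs decompose any result by
log type.

Reporting conventions: storage sums discount annual stock levels, emission
sums discount annual pulses, both over years 0..120 inclusive at the
configured rate (3% by default); emission totals are reported as negative
numbers with gas labels kept internally as magnitudes.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from . import categories as cat
from .end_of_life import (LandfillCohort, MethaneParams, RoutingContext,
                          methane_partition, route_outflow, to_co2e)
from .harvest import HarvestInput, to_carbon_input
from .milling import fossil_fuel_emissions, primary_product_vector
from .params import ParameterError, ParameterSet
from .use_phase import (Outflow, UseCohort, allocate_secondary,
                        apply_waste_deductions, step_transitions)

#: Relative survival below which a cohort's remainder is flushed out of use
#: (routed like any other outflow). Keeps long-horizon runs bounded without
#: losing mass.
FLUSH_SURVIVAL = 1e-12


@dataclasses.dataclass
class Trajectory:
    """Annual storage and emission ledger over years 0..horizon.

    Pulses are stored as magnitudes (tC for biogenic carbon, tCO2e for
    fossil fuel); reporting applies signs.
    """

    in_use: pd.DataFrame          # years x secondary products, tC
    landfill: pd.DataFrame        # years x streams (msw, cd), tC stored
    co2_products_c: np.ndarray    # tC pulses: burned + emitted product carbon
    co2_landfill_c: np.ndarray    # tC pulses from landfill decay booked as CO2
    ch4_c: np.ndarray             # tC pulses emitted as CH4
    ff_co2e: np.ndarray           # tCO2e fossil pulses
    input_c: np.ndarray           # tC entering per year (logs incl. burned)
    gwp_ch4: float

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.in_use.index)

    @property
    def in_use_total(self) -> pd.Series:
        return self.in_use.sum(axis=1)

    @property
    def landfill_total(self) -> pd.Series:
        return self.landfill.sum(axis=1)

    @property
    def storage_total(self) -> pd.Series:
        return self.in_use_total + self.landfill_total

    @property
    def co2_pulse_co2e(self) -> np.ndarray:
        """Biogenic CO2 pulses (products + landfills), tCO2e."""
        return (self.co2_products_c + self.co2_landfill_c) * cat.CO2_PER_C

    @property
    def ch4_pulse_co2e(self) -> np.ndarray:
        return self.ch4_c * cat.CH4_PER_C * self.gwp_ch4

    @property
    def total_emissions_co2e(self) -> np.ndarray:
        """All emission pulses (biogenic CO2 + CH4 + fossil), tCO2e."""
        return self.co2_pulse_co2e + self.ch4_pulse_co2e + self.ff_co2e

    def mass_balance_residual(self) -> np.ndarray:
        """Relative conservation residual per year (0 where no input yet)."""
        cum_in = np.cumsum(self.input_c)
        cum_out = np.cumsum(self.co2_products_c + self.co2_landfill_c + self.ch4_c)
        stored = self.storage_total.to_numpy()
        resid = np.zeros_like(cum_in)
        mask = cum_in > 0
        resid[mask] = np.abs(cum_in - stored - cum_out)[mask] / cum_in[mask]
        return resid

    def in_use_by_sector(self) -> pd.DataFrame:
        cols = {}
        for sector in cat.SECTORS:
            prods = [p for p, s in cat.SECTOR_OF_PRODUCT.items() if s == sector]
            cols[sector] = self.in_use[prods].sum(axis=1)
        return pd.DataFrame(cols)


def discount_series(pulses, r: float) -> float:
    """Present value at year 0: sum of pulses(x) / (1+r)^x."""
    if r < 0:
        raise ParameterError("discount rate must be non-negative")
    v = np.asarray(pulses, dtype=float)
    x = np.arange(len(v))
    return float(np.sum(v / (1.0 + r) ** x))


# Impulse-response coefficients of the revised Bern carbon-cycle model
# (IPCC AR5): the airborne fraction of a CO2 pulse t years after emission.
BERN_A0 = 0.2173
BERN_A = (0.2240, 0.2824, 0.2763)
BERN_TAU = (394.4, 36.54, 4.304)


def bern_retention(t) -> float | np.ndarray:
    """Fraction of a CO2 pulse remaining airborne after ``t`` years."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ParameterError("time must be non-negative")
    out = BERN_A0 + sum(a * np.exp(-t / tau) for a, tau in zip(BERN_A, BERN_TAU))
    return float(out) if out.ndim == 0 else out


def net_storage_with_ff(ex_situ: pd.Series, ff_pulses: pd.Series) -> pd.Series:
    """Deduct the airborne remainder of fossil pulses from ex-situ storage.

    adjusted(t) = ex_situ(t) - sum_h ff(h) * bern_retention(t-h) * 12/44,
    with ff in tCO2e and storage in tC, series aligned on years.
    """
    years = ex_situ.index.to_numpy()
    adj = ex_situ.to_numpy(dtype=float).copy()
    for h, pulse in ff_pulses.items():
        if pulse == 0.0:
            continue
        mask = years >= h
        adj[mask] -= pulse * bern_retention(years[mask] - h) * (12.0 / 44.0)
    return pd.Series(adj, index=ex_situ.index)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _Inflow:
    year: int
    use_primary: pd.Series        # tC entering use, by primary product
    burned_c: float               # pellets + burned, emitted as CO2 at year
    ff: pd.DataFrame | None       # tCO2e per product x stage
    input_c: float                # total log carbon of this inflow


def _cohort_key(c: UseCohort):
    return (c.product, c.application, c.vintage, c.cycles_remaining)


class _LandfillPool:
    """Aggregated landfill state per (stream, material).

    First-order decay is memoryless, so cohorts merge exactly into one
    decayable pool per material/stream with a shared half-life.
    """

    def __init__(self) -> None:
        self.decayable: dict[tuple[str, str], float] = {}
        self.permanent: dict[tuple[str, str], float] = {}
        self.half_life: dict[tuple[str, str], float] = {}

    def add(self, c: LandfillCohort) -> None:
        key = (c.stream, c.material)
        self.decayable[key] = self.decayable.get(key, 0.0) + c.decayable
        self.permanent[key] = self.permanent.get(key, 0.0) + c.permanent
        self.half_life[key] = c.half_life

    def decay_one_year(self) -> dict[tuple[str, str], float]:
        """Advance one year; return decayed tC per (stream, material)."""
        out = {}
        for key, d in self.decayable.items():
            f = 2.0 ** (-1.0 / self.half_life[key])
            decayed = d * (1.0 - f)
            self.decayable[key] = d * f
            out[key] = decayed
        return out

    def stored(self, stream: str) -> float:
        return sum(
            self.decayable.get((stream, m), 0.0) + self.permanent.get((stream, m), 0.0)
            for m in cat.LANDFILL_MATERIALS
        )


def _engine(inflows: list[_Inflow], params: ParameterSet, horizon: int) -> Trajectory:
    years = np.arange(horizon + 1)
    in_use = pd.DataFrame(0.0, index=years, columns=list(cat.SECONDARY_PRODUCTS))
    landfill = pd.DataFrame(0.0, index=years, columns=list(cat.LANDFILL_STREAMS))
    co2_products = np.zeros(horizon + 1)
    co2_landfill = np.zeros(horizon + 1)
    ch4 = np.zeros(horizon + 1)
    ff_arr = np.zeros(horizon + 1)
    input_arr = np.zeros(horizon + 1)

    mp = MethaneParams.from_params(params)
    cd_ch4 = bool(params.value("cd_generates_ch4"))
    inflow_by_year: dict[int, list[_Inflow]] = {}
    for f in inflows:
        if not (0 <= f.year <= horizon):
            raise ParameterError(f"inflow year {f.year} outside horizon 0..{horizon}")
        inflow_by_year.setdefault(f.year, []).append(f)

    cohorts: dict[tuple, UseCohort] = {}
    pools = _LandfillPool()
    ctx = RoutingContext(params)

    def add_cohort(c: UseCohort) -> None:
        key = _cohort_key(c)
        if key in cohorts:
            cohorts[key].carbon += c.carbon
            cohorts[key].initial_carbon += c.initial_carbon
        else:
            cohorts[key] = c

    for t in years:
        t = int(t)
        outflows: list[Outflow] = []

        # 1. survival transitions of existing cohorts
        outflows.extend(step_transitions(list(cohorts.values()), t))
        # flush cohorts whose survival has become negligible
        for key in [k for k, c in cohorts.items()
                    if c.initial_carbon > 0
                    and c.carbon / c.initial_carbon < FLUSH_SURVIVAL]:
            c = cohorts.pop(key)
            if c.carbon > 0:
                outflows.append(Outflow(t, c.product, c.carbon, "lifespan",
                                        cycles_remaining=c.cycles_remaining))

        # 2. landfill decay of the existing pools
        for (stream, material), decayed in pools.decay_one_year().items():
            if decayed <= 0.0:
                continue
            if stream == "msw" or cd_ch4:
                ch4_c, co2_c = methane_partition(decayed, mp)
            else:
                ch4_c, co2_c = 0.0, decayed
            ch4[t] += ch4_c
            co2_landfill[t] += co2_c

        # 3. new harvests entering the market this year
        for f in inflow_by_year.get(t, []):
            input_arr[t] += f.input_c
            co2_products[t] += f.burned_c
            if f.ff is not None:
                ff_arr[t] += float(f.ff.to_numpy().sum())
            new = allocate_secondary(f.use_primary, params, vintage=t)
            new, waste = apply_waste_deductions(new, params)
            for c in new:
                add_cohort(c)
            outflows.extend(waste)

        # 4. route all of this year's outflows
        for o in outflows:
            routed = route_outflow(o, ctx)
            if routed.recycled is not None:
                add_cohort(routed.recycled)
            for c in routed.downcycled:
                add_cohort(c)
            for lc in routed.landfilled:
                pools.add(lc)
            co2_products[t] += routed.emitted

        # 5. end-of-year stocks
        if cohorts:
            by_product: dict[str, float] = {}
            for c in cohorts.values():
                by_product[c.product] = by_product.get(c.product, 0.0) + c.carbon
            for p, v in by_product.items():
                in_use.loc[t, p] = v
        for stream in cat.LANDFILL_STREAMS:
            landfill.loc[t, stream] = pools.stored(stream)

    return Trajectory(in_use, landfill, co2_products, co2_landfill, ch4,
                      ff_arr, input_arr, params.value("gwp_ch4"))


def _harvest_inflow(harvest: HarvestInput, params: ParameterSet) -> _Inflow:
    carbon = to_carbon_input(harvest, params)
    primary = primary_product_vector(carbon, params)
    totals = primary.sum(axis=0)
    ff = fossil_fuel_emissions(totals, params.rate("ff_factors"))
    burned = float(totals["pellets"] + totals["burned"])
    use_primary = totals[list(cat.USE_PRIMARY_PRODUCTS)]
    return _Inflow(harvest.year, use_primary, burned, ff, float(carbon.carbon.sum()))


def simulate(harvests: HarvestInput | list[HarvestInput], params: ParameterSet,
             horizon: int = 120) -> Trajectory:
    """Run the full pipeline for one or more harvest-year inputs."""
    if isinstance(harvests, HarvestInput):
        harvests = [harvests]
    inflows = [_harvest_inflow(h, params) for h in harvests]
    return _engine(inflows, params, horizon)


def simulate_primary(primary: pd.Series, params: ParameterSet,
                     horizon: int = 120, year: int = 0) -> Trajectory:
    """Inject a primary-product vector (tC) directly into the use phase.

    Used for per-primary-product persistence runs; no milling or fossil
    fuel accounting is applied.
    """
    use_primary = primary.reindex(list(cat.USE_PRIMARY_PRODUCTS), fill_value=0.0)
    burned = float(primary.get("pellets", 0.0) + primary.get("burned", 0.0))
    inflow = _Inflow(year, use_primary, burned, None,
                     float(use_primary.sum()) + burned)
    return _engine([inflow], params, horizon)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def sector_table(traj: Trajectory, r: float = 0.03) -> pd.DataFrame:
    """Stored carbon in use by sector plus landfills (stock snapshots and
    discounted 120-year stock sums)."""
    sectors = traj.in_use_by_sector()
    horizon = int(traj.years[-1])
    rows = {}
    for sector in cat.SECTORS:
        s = sectors[sector]
        rows[sector] = {
            "year_0": s.iloc[0],
            "year_10": s.loc[min(10, horizon)],
            f"year_{horizon}": s.iloc[-1],
            "discounted_sum": discount_series(s.to_numpy(), r),
        }
    lf = traj.landfill_total
    rows["landfills"] = {
        "year_0": lf.iloc[0],
        "year_10": lf.loc[min(10, horizon)],
        f"year_{horizon}": lf.iloc[-1],
        "discounted_sum": discount_series(lf.to_numpy(), r),
    }
    return pd.DataFrame(rows).T


def log_type_table(params: ParameterSet, r: float = 0.03, horizon: int = 120,
                   tonnes: float = 100.0) -> pd.DataFrame:
    """Per-100-green-tonne storage and emission sums by log type.

    Storage is the discounted sum of annual stocks (tC); emissions are
    discounted pulse sums reported as negatives (tCO2e), split into
    biogenic CO2, biogenic CH4, and the grand total including fossil fuel.
    """
    from .fixtures import unit_harvest  # local import to avoid cycle

    rows = {}
    for lt in cat.LOG_TYPES:
        q = unit_harvest(lt, tonnes)
        h = HarvestInput(0, "log_type",
                         q.set_index("category")["quantity"])
        traj = simulate(h, params, horizon)
        storage = discount_series(traj.storage_total.to_numpy(), r)
        co2 = discount_series(traj.co2_pulse_co2e, r)
        ch4 = discount_series(traj.ch4_pulse_co2e, r)
        ff = discount_series(traj.ff_co2e, r)
        rows[lt] = {
            "total_storage_tC": storage,
            "co2_biogenic_tCO2e": -co2,
            "ch4_biogenic_tCO2e": -ch4,
            "total_emissions_tCO2e": -(co2 + ch4 + ff),
        }
    return pd.DataFrame(rows).T.reindex(cat.LOG_TYPES)


def persistence_table(params: ParameterSet, year: int = 100,
                      horizon: int = 120) -> pd.DataFrame:
    """Portion of each primary product's carbon still in use / landfills.

    Unit runs of 100 tC per primary product; landscaping and bedding are
    reported as one combined row.
    """
    groups: dict[str, tuple[str, ...]] = {
        p: (p,) for p in cat.USE_PRIMARY_PRODUCTS
        if p not in ("landscaping", "bedding")
    }
    groups["landscaping_and_bedding"] = ("landscaping", "bedding")
    rows = {}
    for label, prods in groups.items():
        vec = pd.Series(0.0, index=list(cat.PRIMARY_PRODUCTS))
        for p in prods:
            vec[p] = 100.0 / len(prods)
        traj = simulate_primary(vec, params, horizon)
        rows[label] = {
            "in_use": traj.in_use_total.loc[year] / 100.0,
            "in_landfills": traj.landfill_total.loc[year] / 100.0,
            "total": traj.storage_total.loc[year] / 100.0,
        }
    return pd.DataFrame(rows).T


def summary(traj: Trajectory, r: float = 0.03) -> dict[str, float]:
    """Headline quantities of a trajectory (stocks in tC, pulses in tCO2e)."""
    horizon = int(traj.years[-1])
    return {
        "storage_year_0_tC": float(traj.storage_total.iloc[0]),
        "storage_year_10_tC": float(traj.storage_total.loc[min(10, horizon)]),
        f"storage_year_{horizon}_tC": float(traj.storage_total.iloc[-1]),
        "storage_in_use_discounted_tC": discount_series(traj.in_use_total.to_numpy(), r),
        "storage_landfill_discounted_tC": discount_series(traj.landfill_total.to_numpy(), r),
        "storage_total_discounted_tC": discount_series(traj.storage_total.to_numpy(), r),
        "ff_year_0_tCO2e": float(traj.ff_co2e[0]),
        "biogenic_co2_year_0_tCO2e": float(traj.co2_pulse_co2e[0]),
        "co2_products_discounted_tCO2e": -discount_series(
            traj.co2_products_c * cat.CO2_PER_C, r),
        "co2_landfills_discounted_tCO2e": -discount_series(
            traj.co2_landfill_c * cat.CO2_PER_C, r),
        "ch4_discounted_tCO2e": -discount_series(traj.ch4_pulse_co2e, r),
        "ff_discounted_tCO2e": -discount_series(traj.ff_co2e, r),
        "total_emissions_discounted_tCO2e": -discount_series(
            traj.total_emissions_co2e, r),
        "max_mass_balance_residual": float(traj.mass_balance_residual().max()),
    }
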