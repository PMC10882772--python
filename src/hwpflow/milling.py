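"""Milling: log carbon -> primary products, residue allocation, fossil fuels.

Each log type is milled into one characteristic primary product (pulp logs
-> pulp & paper, CNS/saw/large saw -> lumber, veneer -> plywood, poles ->
poles, composite -> OSB, bioenergy -> pellets) at a type-specific mill
efficiency; the remainder is residue in three classes (bark, coarse, fine).
Residue is reallocated to pellets, burning, landscaping, bedding, fiber
production (pulp & paper or non-structural panels) or a miscellaneous
sink. A share of lumber/panel carbon is then assembled into engineered
wood. Pellets and "burned" are year-0 biogenic combustion sinks.

Fossil-fuel emissions of procurement, transportation and production are
booked per tC of each primary product, at year 0 of the harvest, in tCO2e.
"""

from __future__ import annotations

import pandas as pd

from . import categories as cat
from .harvest import CarbonInput
from .params import AllocationTable, ParameterError, ParameterSet, RateTable

#: Characteristic primary product of each log type.
PRIMARY_OF_LOG = {
    "pulp": "pulp_paper",
    "cns": "lumber",
    "saw": "lumber",
    "large_saw": "lumber",
    "veneer": "plywood",
    "pole": "poles",
    "composite": "osb",
    "bioenergy": "pellets",
}


def size_adjust_saw_efficiency(base: float) -> tuple[float, float, float]:
    """Sawmill efficiency by log size from the 33-47 cm base value.

    Smaller logs (CNS and small saw) run 0.05 lower, larger logs 0.1
    higher; results are clipped to (0, 1].
    """
    clip = lambda e: min(max(e, 1e-9), 1.0)
    return (clip(base - 0.05), clip(base), clip(base + 0.10))


def mill_efficiencies(params: ParameterSet) -> pd.Series:
    """Per-log-type mill efficiency vector from the registry scalars."""
    small, mid, large = size_adjust_saw_efficiency(
        params.value("sawmill_efficiency_base")
    )
    eff = pd.Series({
        "pulp": params.value("pulp_mill_efficiency"),
        "cns": small,
        "saw": mid,
        "large_saw": large,
        "veneer": params.value("veneer_mill_efficiency"),
        "pole": params.value("pole_mill_efficiency"),
        "composite": params.value("composite_mill_efficiency"),
        "bioenergy": params.value("bioenergy_mill_efficiency"),
    }).reindex(cat.LOG_TYPES)
    if ((eff <= 0) | (eff > 1)).any():
        bad = eff.index[(eff <= 0) | (eff > 1)][0]
        raise ParameterError(f"mill efficiency for {bad!r} outside (0, 1]")
    return eff


def mill(log_carbon: CarbonInput, efficiencies: pd.Series,
         residue_shares: AllocationTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split log carbon into primary product and residue classes.

    Returns ``(primary, residue)``: ``primary`` is tC per (log type ->
    primary product) as a log-type x primary-product frame; ``residue`` is
    tC per log type x residue class. Mass is conserved per log type.
    """
    logc = log_carbon.carbon.reindex(cat.LOG_TYPES, fill_value=0.0)
    eff = efficiencies.reindex(cat.LOG_TYPES)
    if ((eff <= 0) | (eff > 1)).any():
        raise ParameterError("mill efficiency outside (0, 1]")
    primary = pd.DataFrame(0.0, index=list(cat.LOG_TYPES),
                           columns=list(cat.PRIMARY_PRODUCTS))
    for lt in cat.LOG_TYPES:
        primary.loc[lt, PRIMARY_OF_LOG[lt]] = logc[lt] * eff[lt]
    residue = residue_shares.data.reindex(cat.LOG_TYPES).mul(
        logc * (1.0 - eff), axis=0
    )
    return primary, residue


def allocate_residue(residue: pd.Series, residue_use: AllocationTable,
                     fiber_split: AllocationTable) -> pd.Series:
    """Assign residue (tC by class) to primary-product sinks; conserved.

    Fiber-bound residue is further split between pulp & paper and
    non-structural panels.
    """
    additions = pd.Series(0.0, index=list(cat.PRIMARY_PRODUCTS))
    fs = fiber_split.data.loc["fiber"]
    for klass, amount in residue.items():
        uses = residue_use.row(klass) * amount
        additions["pellets"] += uses["pellets"]
        additions["burned"] += uses["burned"]
        additions["landscaping"] += uses["landscaping"]
        additions["bedding"] += uses["bedding"]
        additions["miscellaneous"] += uses["miscellaneous"]
        additions["pulp_paper"] += uses["fiber"] * fs["pulp_paper"]
        additions["nonstructural_panels"] += uses["fiber"] * fs["nonstructural_panels"]
    return additions


def assemble_engineered_wood(primary: pd.Series, share: AllocationTable) -> pd.Series:
    """Move the configured share of lumber/panel carbon into engineered wood."""
    out = primary.copy()
    for src in share.data.index:
        moved = out[src] * share.portion(src, "engineered_wood")
        out[src] -= moved
        out["engineered_wood"] += moved
    return out


def primary_product_vector(log_carbon: CarbonInput, params: ParameterSet) -> pd.DataFrame:
    """Full milling pass: per-log-type primary-product carbon (tC).

    Rows are log types, columns primary products; row sums equal the log
    carbon (burned and pellets are tracked sinks).
    """
    eff = mill_efficiencies(params)
    primary, residue = mill(log_carbon, eff, params.table("mill_residue_shares"))
    ru, fs = params.table("residue_use"), params.table("fiber_split")
    ew = params.table("engineered_wood_share")
    rows = {}
    for lt in cat.LOG_TYPES:
        vec = primary.loc[lt] + allocate_residue(residue.loc[lt], ru, fs)
        rows[lt] = assemble_engineered_wood(vec, ew)
    return pd.DataFrame(rows).T.reindex(cat.LOG_TYPES)


def fossil_fuel_emissions(primary: pd.Series, factors: RateTable) -> pd.DataFrame:
    """Fossil-fuel ledger: tCO2e per primary product x stage, booked year 0."""
    if factors.units != "tCO2e per tC product":
        raise ParameterError(
            f"fossil-fuel factors must be in 'tCO2e per tC product', got {factors.units!r}"
        )
    f = factors.data.reindex(list(cat.PRIMARY_PRODUCTS), fill_value=0.0)
    p = primary.reindex(list(cat.PRIMARY_PRODUCTS), fill_value=0.0)
    return f.mul(p, axis=0)
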