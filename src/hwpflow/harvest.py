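"""Harvest inputs: green tonnes by size class or log type, converted to carbon.

Inputs arrive either by diameter class (13-22, 23-32, 33-47, 48+ cm) or by
the eight log types. Size-class inputs are sorted into log types with
regional cull factors (an allocation table whose rows conserve mass), and
green weight is converted to carbon with a dry fraction and a carbon
fraction. Volume inputs are first converted to green weight with a
configurable green density, so there is a single canonical mass path.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import categories as cat
from .params import AllocationTable, ParameterError, ParameterSet


@dataclasses.dataclass(frozen=True)
class HarvestInput:
    """Green tonnes per category for one harvest year.

    ``year`` 0 is the market entry of this harvest's products.
    """

    year: int
    basis: str                      # "log_type" or "size_class"
    quantities: pd.Series           # green tonnes per category

    def __post_init__(self) -> None:
        if self.basis not in ("log_type", "size_class"):
            raise ParameterError(f"unknown harvest basis {self.basis!r}")
        expected = cat.LOG_TYPES if self.basis == "log_type" else cat.SIZE_CLASSES
        unknown = set(self.quantities.index) - set(expected)
        if unknown:
            raise ParameterError(f"unknown harvest categories {sorted(unknown)}")
        if (self.quantities < 0).any():
            raise ParameterError("harvest quantities must be non-negative")


@dataclasses.dataclass(frozen=True)
class CarbonInput:
    """tC per log type for one harvest year."""

    year: int
    carbon: pd.Series


def apply_cull_factors(size_class_tonnes: pd.Series, cull: AllocationTable) -> pd.Series:
    """Sort size-class tonnage into log types; column sums conserve mass."""
    if (size_class_tonnes < 0).any():
        raise ParameterError("harvest quantities must be non-negative")
    q = size_class_tonnes.reindex(cull.data.index, fill_value=0.0)
    out = cull.data.mul(q, axis=0).sum(axis=0)
    return out.reindex(cat.LOG_TYPES, fill_value=0.0)


def split_saw_pool(saw_pool_tonnes: float, split: tuple[float, float, float]) -> tuple[float, float, float]:
    """Split a combined saw pool into (CNS, saw, large saw) tonnages."""
    if abs(sum(split) - 1.0) > 1e-9:
        raise ParameterError(f"saw-pool split {split} does not sum to 1")
    return tuple(saw_pool_tonnes * s for s in split)


def green_to_carbon(tonnes: float | pd.Series, dry_fraction: float,
                    carbon_fraction: float) -> float | pd.Series:
    """Green tonnes -> tC via dry-matter and carbon fractions."""
    for name, f in (("dry_fraction", dry_fraction), ("carbon_fraction", carbon_fraction)):
        if not (0.0 < f <= 1.0):
            raise ParameterError(f"{name} must be in (0, 1], got {f}")
    return tonnes * dry_fraction * carbon_fraction


def volume_to_green(volume_m3: float | pd.Series, green_density: float) -> float | pd.Series:
    """m3 -> green tonnes via a configurable green density (t/m3)."""
    if green_density <= 0:
        raise ParameterError("green density must be positive")
    return volume_m3 * green_density


def to_carbon_input(harvest: HarvestInput, params: ParameterSet) -> CarbonInput:
    """Resolve a harvest to tC by log type (cull-sorting size-class inputs)."""
    if harvest.basis == "size_class":
        tonnes = apply_cull_factors(harvest.quantities, params.table("cull_factors"))
    else:
        tonnes = harvest.quantities.reindex(cat.LOG_TYPES, fill_value=0.0)
    carbon = green_to_carbon(
        tonnes, params.value("dry_fraction"), params.value("carbon_fraction")
    )
    return CarbonInput(harvest.year, carbon)
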