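"""Typed parameter registry: scalars, allocation tables and rate tables.

The simulator is driven by a "workbook": one CSV per table plus one YAML
file of scalar parameters. Allocation tables hold portions and every row
must close to 1 (rows that the data leave open must carry an explicit
``emitted`` column rather than an implicit remainder, so the mass balance
stays auditable). Rate tables (fossil-fuel factors, lifespans) carry plain
numbers with units and are not row-normalized.

Scalar parameters carry units, optional sampling bounds and a certainty
tier; the sensitivity module derives default bounds from the tier when none
are given (±10% for high certainty, ±20% for moderate/low).
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ROW_SUM_TOL = 1e-9

CERTAINTY_TIERS = ("high", "moderate", "low")

#: Default relative half-width of sensitivity bounds by certainty tier.
CERTAINTY_BOUNDS = {"high": 0.10, "moderate": 0.20, "low": 0.20}


class ParameterError(ValueError):
    """Raised when a workbook fails validation."""


@dataclasses.dataclass(frozen=True)
class Parameter:
    """A named scalar with units, optional bounds and a certainty tier."""

    name: str
    value: float
    units: str = ""
    bounds: tuple[float, float] | None = None
    certainty: str = "moderate"

    def __post_init__(self) -> None:
        if self.certainty not in CERTAINTY_TIERS:
            raise ParameterError(
                f"parameter {self.name!r}: unknown certainty {self.certainty!r}"
            )
        if self.bounds is not None:
            lo, hi = self.bounds
            if not (lo <= self.value <= hi):
                raise ParameterError(
                    f"parameter {self.name!r}: value {self.value} outside "
                    f"bounds [{lo}, {hi}]"
                )
        if self.units == "portion" and not (0.0 <= self.value <= 1.0):
            raise ParameterError(
                f"parameter {self.name!r}: portion {self.value} outside [0, 1]"
            )
        if self.units == "years" and self.value <= 0:
            raise ParameterError(
                f"parameter {self.name!r}: lifespan must be positive"
            )

    def sampling_bounds(self) -> tuple[float, float]:
        """Bounds for sensitivity sampling.

        Explicit bounds win; otherwise the certainty tier sets a relative
        half-width around the default value. Portions are clipped to [0, 1].
        """
        if self.bounds is not None:
            return self.bounds
        half = CERTAINTY_BOUNDS[self.certainty]
        lo = self.value * (1 - half)
        hi = self.value * (1 + half)
        if self.units == "portion":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        return (lo, hi)


@dataclasses.dataclass(frozen=True)
class AllocationTable:
    """Portions mapping source categories (rows) to destinations (columns).

    Every row sums to 1 within ``ROW_SUM_TOL``.
    """

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if (df.to_numpy() < -ROW_SUM_TOL).any():
            raise ParameterError(f"table {self.name!r}: negative portion")
        if ((df.to_numpy() < 0) | (df.to_numpy() > 1 + 1e-12)).any():
            raise ParameterError(f"table {self.name!r}: portion outside [0, 1]")
        sums = df.sum(axis=1)
        bad = sums[(sums - 1.0).abs() > ROW_SUM_TOL]
        if len(bad):
            label = bad.index[0]
            raise ParameterError(
                f"table {self.name!r}: row {label!r} sums to {bad.iloc[0]:.12f}, not 1"
            )

    def row(self, label: str) -> pd.Series:
        return self.data.loc[label]

    def portion(self, row: str, col: str) -> float:
        return float(self.data.loc[row, col])


@dataclasses.dataclass(frozen=True)
class RateTable:
    """Plain numeric table (factors, lifespans); no row-sum constraint."""

    name: str
    data: pd.DataFrame
    units: str = ""

    def value(self, row: str, col: str) -> float:
        return float(self.data.loc[row, col])


# Tables every simulation stage needs; load fails if one is absent.
REQUIRED_ALLOCATION_TABLES = (
    "cull_factors",
    "mill_residue_shares",
    "residue_use",
    "fiber_split",
    "engineered_wood_share",
    "end_use",
    "housing_applications",
    "waste_routing",
)
REQUIRED_RATE_TABLES = (
    "ff_factors",
    "lifespans",
    "housing_application_modes",
)

# Unit whitelist per rate table. The fossil-fuel tables in the source data
# mix "per tC product" and "per tCO2e in product"; the registry stores one
# internal unit and converts the other at load time (x 44/12).
FF_UNIT_INTERNAL = "tCO2e per tC product"
FF_UNIT_PER_CO2E = "tCO2e per tCO2e product"
RATE_TABLE_UNITS = {
    "ff_factors": (FF_UNIT_INTERNAL, FF_UNIT_PER_CO2E),
    "lifespans": ("years",),
    "housing_application_modes": ("years",),
}


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """The full registry: scalars, allocation tables, rate tables."""

    scalars: dict[str, Parameter]
    tables: dict[str, AllocationTable]
    rates: dict[str, RateTable]
    provenance: dict[str, str] = dataclasses.field(default_factory=dict)

    # -- access helpers -------------------------------------------------
    def value(self, name: str) -> float:
        try:
            return self.scalars[name].value
        except KeyError:
            raise ParameterError(f"unknown scalar parameter {name!r}") from None

    def table(self, name: str) -> AllocationTable:
        try:
            return self.tables[name]
        except KeyError:
            raise ParameterError(f"missing allocation table {name!r}") from None

    def rate(self, name: str) -> RateTable:
        try:
            return self.rates[name]
        except KeyError:
            raise ParameterError(f"missing rate table {name!r}") from None

    def lifespan(self, product: str) -> float:
        return self.rate("lifespans").value(product, "mode")

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for name in REQUIRED_ALLOCATION_TABLES:
            if name not in self.tables:
                raise ParameterError(f"missing required table {name!r}")
        for name in REQUIRED_RATE_TABLES:
            if name not in self.rates:
                raise ParameterError(f"missing required table {name!r}")
        ls = self.rates["lifespans"].data
        if (ls["mode"] <= 0).any():
            bad = ls.index[ls["mode"] <= 0][0]
            raise ParameterError(f"lifespans: non-positive mode for {bad!r}")
        if self.value("weibull_shape_k") <= 1:
            raise ParameterError("weibull_shape_k must exceed 1 (mode undefined)")

    # -- functional update ----------------------------------------------
    def with_overrides(self, overrides: dict[str, float]) -> "ParameterSet":
        return apply_overrides(self, overrides)


def apply_overrides(base: ParameterSet, overrides: dict[str, float]) -> ParameterSet:
    """Return a new set with named values replaced; ``base`` is unchanged.

    Scalar overrides use the parameter name. Table cells are addressed as
    ``"table.row.column"`` (e.g. ``"lifespans.corrugated_boxes.mode"`` or
    ``"waste_routing.corrugated_boxes.recycle"``). Overriding a cell of an
    allocation table re-normalizes the *other* cells of that row
    proportionally so the row still closes to 1.

    Raises
    ------
    ParameterError
        If a name does not exist in ``base`` or the new value violates the
        parameter's range contract.
    """
    scalars = dict(base.scalars)
    tables = dict(base.tables)
    rates = dict(base.rates)
    for name, value in overrides.items():
        if name in scalars:
            old = scalars[name]
            bounds = old.bounds
            if bounds is not None and not (bounds[0] <= value <= bounds[1]):
                bounds = None  # overrides may move outside sampling bounds
            scalars[name] = Parameter(
                old.name, float(value), old.units, bounds, old.certainty
            )
            continue
        parts = name.split(".")
        if len(parts) == 3 and parts[0] in tables:
            tname, row, col = parts
            df = tables[tname].data.copy()
            if row not in df.index or col not in df.columns:
                raise ParameterError(f"unknown override name {name!r}")
            if not (0.0 <= value <= 1.0):
                raise ParameterError(
                    f"override {name!r}: portion {value} outside [0, 1]"
                )
            delta = float(value) - float(df.loc[row, col])
            df.loc[row, col] = float(value)
            # closure: absorb into the explicit "emitted" remainder when the
            # row has one and it stays non-negative; otherwise re-normalize
            # the other cells proportionally.
            if (
                col != "emitted"
                and "emitted" in df.columns
                and df.loc[row, "emitted"] - delta >= -ROW_SUM_TOL
            ):
                df.loc[row, "emitted"] = max(df.loc[row, "emitted"] - delta, 0.0)
            else:
                rest = [c for c in df.columns if c != col]
                rest_sum = float(df.loc[row, rest].sum())
                remainder = 1.0 - float(value)
                if rest_sum > 0:
                    df.loc[row, rest] *= remainder / rest_sum
                elif rest:
                    df.loc[row, rest] = remainder / len(rest)
            tables[tname] = AllocationTable(tname, df)
            continue
        if len(parts) == 3 and parts[0] in rates:
            tname, row, col = parts
            rt = rates[tname]
            df = rt.data.copy()
            if row not in df.index or col not in df.columns:
                raise ParameterError(f"unknown override name {name!r}")
            if tname in ("lifespans", "housing_application_modes") and value <= 0:
                raise ParameterError(f"override {name!r}: lifespan must be positive")
            df.loc[row, col] = float(value)
            rates[tname] = RateTable(tname, df, rt.units)
            continue
        raise ParameterError(f"unknown override name {name!r}")
    out = ParameterSet(scalars, tables, rates, dict(base.provenance))
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Workbook I/O
# ---------------------------------------------------------------------------

def load_parameter_set(workbook_path: str | Path, config_path: str | Path | None = None) -> ParameterSet:
    """Load a workbook directory (CSV tables + YAML scalars) into a registry.

    ``workbook_path`` is a directory containing one ``<table>.csv`` per
    table (first column = row labels) and, unless ``config_path`` is given,
    a ``scalars.yaml``. Fossil-fuel rows expressed per tCO2e in product are
    converted to the internal per-tC unit at load time.
    """
    workbook = Path(workbook_path)
    if not workbook.is_dir():
        raise ParameterError(f"workbook directory not found: {workbook}")
    config = Path(config_path) if config_path else workbook / "scalars.yaml"
    if not config.exists():
        raise ParameterError(f"scalar config not found: {config}")

    with open(config) as fh:
        raw = yaml.safe_load(fh) or {}
    scalars: dict[str, Parameter] = {}
    for name, entry in raw.get("parameters", {}).items():
        if isinstance(entry, dict):
            bounds = entry.get("bounds")
            scalars[name] = Parameter(
                name,
                float(entry["value"]),
                entry.get("units", ""),
                tuple(float(b) for b in bounds) if bounds else None,
                entry.get("certainty", "moderate"),
            )
        else:
            scalars[name] = Parameter(name, float(entry))

    tables: dict[str, AllocationTable] = {}
    rates: dict[str, RateTable] = {}
    for csv in sorted(workbook.glob("*.csv")):
        name = csv.stem
        if name not in REQUIRED_ALLOCATION_TABLES and name not in REQUIRED_RATE_TABLES:
            raise ParameterError(f"unknown table {name!r} in workbook")
        df = pd.read_csv(csv, index_col=0, float_precision="round_trip")
        if name in REQUIRED_RATE_TABLES:
            rates[name] = _load_rate_table(name, df)
        else:
            tables[name] = AllocationTable(name, df.astype(float))

    ps = ParameterSet(scalars, tables, rates, {"workbook": str(workbook)})
    ps.validate()
    return ps


def _load_rate_table(name: str, df: pd.DataFrame) -> RateTable:
    allowed = RATE_TABLE_UNITS.get(name)
    if "units" in df.columns:
        units_col = df["units"]
        df = df.drop(columns=["units"]).astype(float)
        if allowed is not None:
            bad = set(units_col) - set(allowed)
            if bad:
                raise ParameterError(
                    f"table {name!r}: unit(s) {sorted(bad)} not in whitelist {allowed}"
                )
        if name == "ff_factors":
            # convert per-tCO2e rows to the internal per-tC unit
            scale = units_col.map(
                lambda u: 44.0 / 12.0 if u == FF_UNIT_PER_CO2E else 1.0
            )
            df = df.mul(scale, axis=0)
        return RateTable(name, df, FF_UNIT_INTERNAL if name == "ff_factors" else allowed[0])
    units = allowed[0] if allowed else ""
    return RateTable(name, df.astype(float), units)


def save_parameter_set(ps: ParameterSet, workbook_path: str | Path) -> None:
    """Write a registry back out as a workbook directory (round-trippable)."""
    workbook = Path(workbook_path)
    workbook.mkdir(parents=True, exist_ok=True)
    payload = {
        "parameters": {
            p.name: {
                "value": p.value,
                "units": p.units,
                **({"bounds": list(p.bounds)} if p.bounds else {}),
                "certainty": p.certainty,
            }
            for p in ps.scalars.values()
        }
    }
    with open(workbook / "scalars.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    for name, tbl in ps.tables.items():
        # %.17g keeps float round-trips bit-exact
        tbl.data.to_csv(workbook / f"{name}.csv", float_format="%.17g")
    for name, rt in ps.rates.items():
        df = rt.data.copy()
        if name == "ff_factors":
            df["units"] = FF_UNIT_INTERNAL
        df.to_csv(workbook / f"{name}.csv", float_format="%.17g")


def registry_equal(a: ParameterSet, b: ParameterSet) -> bool:
    """Bitwise equality of two registries (used by determinism tests)."""
    if set(a.scalars) != set(b.scalars):
        return False
    for k in a.scalars:
        pa, pb = a.scalars[k], b.scalars[k]
        if (pa.value, pa.units, pa.bounds, pa.certainty) != (
            pb.value,
            pb.units,
            pb.bounds,
            pb.certainty,
        ):
            return False
    if set(a.tables) != set(b.tables) or set(a.rates) != set(b.rates):
        return False
    for k in a.tables:
        if not a.tables[k].data.equals(b.tables[k].data):
            return False
    for k in a.rates:
        if not a.rates[k].data.equals(b.rates[k].data):
            return False
    return True
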