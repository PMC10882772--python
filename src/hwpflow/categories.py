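"""Canonical category names used throughout the carbon-flow model.

All stages communicate through these identifiers: harvested logs are sorted
into log types, milled into primary products, consumed as secondary
products, and disposed of into landfill streams. Keeping the vocabularies in
one module makes the allocation tables auditable: every table row/column
label must come from these lists.
"""

from __future__ import annotations

# Diameter classes for size-based harvest inputs (cm at breast height).
SIZE_CLASSES: tuple[str, ...] = ("13-22", "23-32", "33-47", "48+")

# The eight merchantable log types.
LOG_TYPES: tuple[str, ...] = (
    "pulp",
    "cns",
    "saw",
    "large_saw",
    "veneer",
    "pole",
    "composite",
    "bioenergy",
)

# Mill outputs. "burned" is a tracked sink emitted as biogenic CO2 in year 0;
# pellets are likewise burned in year 0 of the harvest.
PRIMARY_PRODUCTS: tuple[str, ...] = (
    "lumber",
    "plywood",
    "osb",
    "nonstructural_panels",
    "engineered_wood",
    "poles",
    "pulp_paper",
    "landscaping",
    "bedding",
    "miscellaneous",
    "pellets",
    "burned",
)

# Primary products that enter the use phase (everything but the two year-0
# combustion sinks).
USE_PRIMARY_PRODUCTS: tuple[str, ...] = tuple(
    p for p in PRIMARY_PRODUCTS if p not in ("pellets", "burned")
)

# Consumer end uses. Housing categories are modelled per application
# (floors, walls, ...) rather than as whole homes.
SECONDARY_PRODUCTS: tuple[str, ...] = (
    "new_single_family",
    "new_multi_family",
    "new_manufactured",
    "single_family_upkeep",
    "multi_family_upkeep",
    "manufactured_upkeep",
    "new_buildings",
    "other_structures",
    "other_construction",
    "shipping_pallets",
    "other_shipping",
    "utility_poles",
    "posts_pilings",
    "animal_bedding",
    "landscaping",
    "corrugated_boxes",
    "sanitary_products",
    "packaging_cartonboard",
    "disposable_food",
    "misc_paper",
    "furniture",
    "other_manufacturing",
    "miscellaneous",
)

# Sub-cohort applications for new single/multi-family housing.
HOUSING_CATEGORIES: tuple[str, ...] = ("new_single_family", "new_multi_family")
HOUSING_APPLICATIONS: tuple[str, ...] = ("floors", "walls", "doors", "roof", "other")

# Paper-material end uses (landfill decay uses paper parameters; the rest
# decay as solid wood).
PAPER_PRODUCTS: tuple[str, ...] = (
    "corrugated_boxes",
    "sanitary_products",
    "packaging_cartonboard",
    "disposable_food",
    "misc_paper",
)

# Products whose outflows may be recycled (as the same product, a limited
# number of times).
RECYCLABLE_PRODUCTS: tuple[str, ...] = ("shipping_pallets",) + PAPER_PRODUCTS

# Year-0 waste deduction membership.
CONSTRUCTION_WASTE_PRODUCTS: tuple[str, ...] = (
    "new_single_family",
    "new_multi_family",
    "new_manufactured",
    "single_family_upkeep",
    "multi_family_upkeep",
    "manufactured_upkeep",
    "new_buildings",
    "other_structures",
    "other_construction",
)
MANUFACTURING_WASTE_PRODUCTS: tuple[str, ...] = (
    "shipping_pallets",
    "other_shipping",
    "posts_pilings",
    "furniture",
    "other_manufacturing",
    "miscellaneous",
)

# End-of-life downcycling destinations (each is itself a secondary product;
# downcycled carbon re-enters use with the destination's lifespan).
DOWNCYCLE_DESTINATIONS: tuple[str, ...] = (
    "landscaping",
    "animal_bedding",
    "posts_pilings",
    "furniture",
    "other_manufacturing",
)

MILL_RESIDUE_CLASSES: tuple[str, ...] = ("bark", "coarse", "fine")
RESIDUE_USES: tuple[str, ...] = (
    "pellets",
    "burned",
    "landscaping",
    "bedding",
    "fiber",
    "miscellaneous",
)
FIBER_DESTINATIONS: tuple[str, ...] = ("pulp_paper", "nonstructural_panels")

FF_STAGES: tuple[str, ...] = ("procurement", "transportation", "production")

LANDFILL_STREAMS: tuple[str, ...] = ("msw", "cd")
LANDFILL_MATERIALS: tuple[str, ...] = ("wood", "paper")

# Waste routing columns: rows of the waste_routing table must close to 1
# over these destinations.
WASTE_ROUTING_COLUMNS: tuple[str, ...] = (
    ("recycle",)
    + tuple("downcycle_" + d for d in DOWNCYCLE_DESTINATIONS)
    + ("landfill_msw", "landfill_cd", "emitted")
)

# Reporting sectors (storage-in-use table shape).
SECTOR_OF_PRODUCT: dict[str, str] = {
    "new_single_family": "residential_construction",
    "new_multi_family": "residential_construction",
    "new_manufactured": "residential_construction",
    "single_family_upkeep": "residential_construction",
    "multi_family_upkeep": "residential_construction",
    "manufactured_upkeep": "residential_construction",
    "new_buildings": "nonresidential_construction",
    "other_structures": "nonresidential_construction",
    "other_construction": "nonresidential_construction",
    "shipping_pallets": "shipping",
    "other_shipping": "shipping",
    "utility_poles": "other",
    "posts_pilings": "other",
    "animal_bedding": "other",
    "landscaping": "other",
    "corrugated_boxes": "pulp_and_paper",
    "sanitary_products": "pulp_and_paper",
    "packaging_cartonboard": "pulp_and_paper",
    "disposable_food": "pulp_and_paper",
    "misc_paper": "pulp_and_paper",
    "furniture": "manufacturing",
    "other_manufacturing": "manufacturing",
    "miscellaneous": "other",
}

SECTORS: tuple[str, ...] = (
    "residential_construction",
    "nonresidential_construction",
    "pulp_and_paper",
    "shipping",
    "manufacturing",
    "other",
)

# Molar mass ratios for gas conversions.
CO2_PER_C = 44.0 / 12.0
CH4_PER_C = 16.0 / 12.0
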