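# Methods

## Model structure and assumptions

`hwpflow` is a cohort-bookkeeping model. Carbon enters as harvested log
mass, is partitioned by allocation tables (rows close to 1, validated at
load to 1e-9), and thereafter only moves between four places: in-use
product cohorts, landfill pools, the atmosphere (biogenic CO2 or CH4),
and a permanent landfill fraction. Nothing else is created or destroyed,
so the primary correctness surface is conservation: the simulation
asserts a relative mass-balance residual below 1e-6 at every year, and in
practice achieves machine precision.

The flow model is linear in its inputs. Multi-year harvests are
superposed cohorts, and any aggregate result can be decomposed into
per-100-tonne unit runs by log type; the report tables exploit this.

Key stage assumptions:

* **Harvest.** Inputs are green tonnes by diameter class (13-22, 23-32,
  33-47, 48+ cm) or by log type; cull factors sort classes into types and
  conserve mass. Green weight converts to carbon with a dry fraction
  (default 0.5, green basis) and a carbon fraction (default 0.5); volume
  inputs convert first via a green density (default 1 t/m3). These
  conversion defaults are generic softwood values and are configurable —
  the exact specific-gravity/moisture chain for any particular species
  should be supplied with real data.
* **Milling.** Each log type yields one characteristic primary product at
  a type-specific efficiency; the remainder is bark/coarse/fine residue
  reallocated to pellets, burning, landscaping, bedding, fiber (pulp &
  paper or non-structural panels) or a miscellaneous sink. Sawmill
  efficiency is parameterized by the 33-47 cm base value (default 0.40,
  bounds 0.30-0.50), with -0.05 for smaller logs and +0.10 for large
  ones, clipped to (0, 1]. Pellets and burned residue are emitted as
  biogenic CO2 in year 0. Fossil-fuel factors are stored internally as
  tCO2e per tC of product for three stages (procurement, transportation,
  production); rows supplied per tCO2e in product are converted by 44/12
  at load. Bioenergy-log carbon incurs the pellet production factor.
* **Use.** Weibull shape k = 2.63 for all products; the scale is derived
  from each product's lifespan mode, so the annualized transition
  (survival difference on integer years, age counted from the cohort's
  vintage) peaks at the mode ±1 year of discretization. New single- and
  multi-family housing is modelled as application sub-cohorts (floors,
  walls, doors, roof, other) with application-specific modes; all other
  categories transition by the secondary product's own mode. Year-0 waste
  deductions (5.6% construction, 8% manufacturing) are applied before the
  first survival step and their outflows are never recycled.
* **End of life.** Routing rows close to 1 with an explicit `emitted`
  remainder. Pallets recycle up to 3 times and paper products up to 5
  (as the same product, with a fresh lifespan clock); exhausted or
  non-recyclable outflows reallocate the recycle share proportionally
  across the landfill and emitted shares. Downcycling destinations are
  landscaping, animal bedding, posts & pilings, furniture and other
  manufacturing, entering use with the destination's lifespan. Landfill
  decay is first order with a zero lag (the clock starts in the
  landfilling year; the first annualized decay increment falls in the
  following year). Methane is generated in MSW landfills only by default
  (configurable); recovered and oxidized methane carbon is booked as
  biogenic CO2, with no energy-capture distinction.
* **Accounting.** 120 years of annual outputs after market entry
  (year 0). Storage sums discount annual stock levels; emission sums
  discount annual pulses; both run over years 0..120 inclusive at 3% by
  default, and year-0 stock is included. Emission totals are reported as
  negatives; internal ledgers keep magnitudes with gas labels. The Bern
  impulse response (a0 = 0.2173; a = 0.224, 0.2824, 0.2763; tau = 394.4,
  36.54, 4.304 years) gives the airborne fraction of fossil pulses that
  rotation accounting deducts (as tC, x 12/44) from ex-situ storage.

## Parameters

Scalars carry units, optional sampling bounds and a certainty tier; tiers
map to default sensitivity bounds of ±10% (high) and ±20%
(moderate/low), with paper-product lifespans using -50%/+200%. Defaults
worth knowing:

| parameter | default | unit | note |
|---|---|---|---|
| weibull_shape_k | 2.63 | – | all products |
| construction_waste | 0.056 | portion | bounds 0–0.156 |
| manufacturing_waste | 0.08 | portion | |
| sawmill_efficiency_base | 0.40 | portion | bounds 0.30–0.50 |
| pulp_mill_efficiency | 0.89 | portion | bounds 0.79–0.99 |
| composite_mill_efficiency | 0.90 | portion | |
| doc_f_paper_msw | 0.59 | portion | midpoint of 0.25–0.93 |
| doc_f_wood_msw / _cd | 0.25 | portion | midpoint of 0–0.5 |
| half_life_paper | 15 | years | midpoint of 12–18 |
| half_life_wood | 35 | years | IPCC first-order default |
| ch4_fraction_f | 0.5 | portion | standard landfill-gas split |
| ch4_recovery_r | 0.6019 | portion | midpoint of 0.4019–0.8019 |
| ch4_oxidation_ox | 0.2221 | portion | midpoint of 0.0221–0.4221 |
| gwp_ch4 | 28 | – | 100-year GWP |
| landfill_lag_years | 0 | years | decay clock starts at disposal |

Landfill DOC_f, R and OX default to the midpoints of their sensitivity
bounds because only the bounds are published; F (0.5) and GWP (28) are
the package's own standard choices. The wood half-life (35 y) is the
IPCC first-order default; only the paper half-life bounds are published.
Recycling and landfilling rates for pallets and the five paper products
are reconstructed arithmetically from published scenario adjustments
(e.g. corrugated-box recycling 0.964/1.05 = 0.918).

## The synthetic workbook

`generate_fixture_set(seed)` emulates a complete parameter workbook. It
pins every value recoverable from running text (the table above, lumber
fossil factors, the 45/45/10 saw split, end-use anchors such as 31.7% of
lumber and 48.5% of OSB to new residential construction, 80% of
engineered wood, pulp-mill residue being exclusively bark) and draws the
remaining allocation cells from a seeded log-normal jitter around
plausible base values, then row-normalizes. What it does **not** emulate:
the true unpublished consumption, residue and cull tables; regional or
temporal variation; correlations between tables. Consequently, tests and
the acceptance script demonstrate the *machinery* — conservation,
equation values, published arithmetic, orderings that follow from the
published efficiencies and end uses (composite logs store the most
carbon per tonne, bioenergy logs store none, pulp logs emit the most
methane) — not the original study's exact totals, which require
transcribing the real workbook into the registry.

The BAU harvest is reconstructed from published scenario tonnages: the
saw pool from the small-log scenario (53,252,326/0.8, split 45/45/10),
pulp from the bioenergy scenario (39,724,441/0.61), veneer/pole/composite
unchanged, and bioenergy as the residual that makes the BAU total equal
the (tonnage-conserving) bioenergy scenario's total exactly.

## Sensitivity analysis

Morris screening with p = 10 levels, Δ = p/(2(p-1)) and r = 30 random
trajectories by default (each perturbs every parameter exactly once on
the grid). The objective is the signed sum of discounted emission pulses
(biogenic CO2 + CH4 + fossil, 3%), so **positive µ means increasing the
parameter avoids emissions**; `MorrisResult.flipped()` exposes the
opposite orientation. Table-cell parameters are addressed as
`table.row.column`; overriding an allocation cell closes the row through
the explicit `emitted` remainder when possible, else proportionally.
The examples and the acceptance script use reduced designs (r = 8) to
keep runtimes to seconds; the indices' signs are stable at that size.

## Numerical choices

* Annual discrete stepping; cohorts with the same (product, application,
  vintage, cycles) merge exactly, as do landfill pools per
  (stream, material) — first-order decay is memoryless.
* Cohorts whose survival falls below 1e-12 of their initial carbon are
  flushed through end-of-life routing, which bounds long-horizon runs
  without losing mass (single-cohort closure to year 3000 holds to
  1e-6 relative).
* Workbook round-trips are bit-exact (CSV written at 17 significant
  digits, parsed with round-trip float precision).
* Degenerate inputs: zero harvests, zero pools and empty overlays are
  identities; negative quantities, unnormalized rows, unknown categories
  and out-of-range portions fail fast with the offending name.

## Known limitations

* No market or substitution feedbacks; scenario overlays change physical
  flows only.
* Stand growth is an input; the bundled logistic growth curve is a test
  stand-in and claims no fidelity to any growth-and-yield model.
* Fossil fuel is tracked for procurement, transportation and production
  only — no post-mill transport, recycling energy, or construction.
* The paper-product recycling network is diagonal (a product recycles
  only as itself), and recycling rates are aggregate waste-stream rates.
* Emission pulses are aggregated as GWP-weighted CO2e; no dynamic
  radiative-forcing accounting.
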