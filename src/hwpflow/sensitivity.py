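"""Morris elementary-effects global sensitivity analysis.

One-at-a-time screening on a p-level grid in the unit hypercube: each of r
random trajectories perturbs every parameter exactly once by a step
delta = p / (2(p-1)), yielding r elementary effects per parameter,

    EE_i = (y(x + delta e_i) - y(x)) / (+-delta),

summarized as mu (mean), mu* (mean absolute value) and sigma (standard
deviation). mu ~ mu* signals a linear effect; sigma large relative to mu*
signals nonlinearity or interactions.

The model objective is the sum of all discounted emission pulses (biogenic
CO2 + CH4 + fossil fuel, 3% rate) from a business-as-usual harvest. The
objective is *signed* — emissions are negative — so a positive mu means
increasing the parameter yields fewer emissions (a climate benefit); the
result also exposes the flipped orientation (mu of the emission magnitude).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .accounting import discount_series, simulate
from .harvest import HarvestInput
from .params import ParameterError, ParameterSet


@dataclasses.dataclass(frozen=True)
class MorrisDesign:
    """An r-trajectory, p-level one-at-a-time design.

    ``points`` has shape (r*(k+1), k) in unit-scaled space; consecutive
    points within a trajectory differ in exactly one coordinate by
    +-delta. ``names`` and ``bounds`` map unit coordinates to parameter
    values.
    """

    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    levels: int
    trajectories: int
    delta: float
    points: np.ndarray
    seed: int

    def scaled_points(self) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return lo + self.points * (hi - lo)


@dataclasses.dataclass(frozen=True)
class MorrisResult:
    """Per-parameter mu, mu*, sigma (|mu| <= mu* and sigma >= 0 always)."""

    indices: pd.DataFrame   # columns mu, mu_star, sigma; index = names

    def ranked(self) -> pd.DataFrame:
        out = self.indices.sort_values("mu_star", ascending=False).copy()
        out["rank"] = np.arange(1, len(out) + 1)
        return out

    def flipped(self) -> pd.DataFrame:
        """The opposite sign orientation (mu of the emission magnitude)."""
        out = self.indices.copy()
        out["mu"] = -out["mu"]
        return out


def build_design(specs: dict[str, tuple[float, float]], p: int = 10,
                 r: int = 30, seed: int = 0) -> MorrisDesign:
    """Random Morris trajectories on the p-level grid.

    ``specs`` maps parameter names to (low, high) bounds. Produces
    r*(k+1) evaluation points; reproducible for a fixed seed.
    """
    if p < 2:
        raise ParameterError("number of levels p must be at least 2")
    names = tuple(specs)
    k = len(names)
    for n, (lo, hi) in specs.items():
        if not lo < hi:
            raise ParameterError(f"parameter {n!r}: bounds must satisfy low < high")
    rng = np.random.default_rng(seed)
    delta = p / (2.0 * (p - 1))
    # base grid levels that keep x and x+delta inside [0, 1]
    base_levels = np.arange(0, p // 2) / (p - 1)
    blocks = []
    for _ in range(r):
        x = rng.choice(base_levels, size=k)
        directions = np.ones(k)  # start upward from the lower half-grid
        order = rng.permutation(k)
        traj = [x.copy()]
        for idx in order:
            x = x.copy()
            x[idx] += directions[idx] * delta
            traj.append(x)
        # randomly mirror the whole trajectory so steps go both ways
        mirror = rng.random(k) < 0.5
        traj = np.array(traj)
        traj[:, mirror] = 1.0 - traj[:, mirror]
        blocks.append(traj)
    points = np.vstack(blocks)
    return MorrisDesign(names, tuple(specs.values()), p, r, delta, points, seed)


def elementary_effects(design: MorrisDesign, values: np.ndarray) -> dict[str, list[float]]:
    """Per-parameter elementary effects from objective values at the design
    points (one value per point, trajectory blocks of k+1)."""
    k = len(design.names)
    values = np.asarray(values, dtype=float)
    if len(values) != design.trajectories * (k + 1):
        raise ParameterError(
            f"expected {design.trajectories * (k + 1)} objective values, "
            f"got {len(values)}"
        )
    effects: dict[str, list[float]] = {n: [] for n in design.names}
    for b in range(design.trajectories):
        lo = b * (k + 1)
        block = design.points[lo:lo + k + 1]
        y = values[lo:lo + k + 1]
        for i in range(k):
            diff = block[i + 1] - block[i]
            (idx,) = np.nonzero(np.abs(diff) > 1e-12)
            step = diff[idx[0]]
            effects[design.names[idx[0]]].append((y[i + 1] - y[i]) / step)
    return effects


def morris_indices(effects: dict[str, list[float]]) -> MorrisResult:
    """Summarize effect lists into mu, mu*, sigma (sample s.d., ddof=1)."""
    rows = {}
    for name, ee in effects.items():
        if len(ee) < 2:
            raise ParameterError(f"parameter {name!r}: need at least 2 effects")
        arr = np.asarray(ee, dtype=float)
        rows[name] = {
            "mu": arr.mean(),
            "mu_star": np.abs(arr).mean(),
            "sigma": arr.std(ddof=1),
        }
    return MorrisResult(pd.DataFrame(rows).T)


# ---------------------------------------------------------------------------
# Model objective
# ---------------------------------------------------------------------------

def objective_discounted_emissions(overrides: dict[str, float],
                                   harvest: HarvestInput,
                                   base_params: ParameterSet,
                                   r: float = 0.03,
                                   horizon: int = 120) -> float:
    """Signed sum of discounted emission pulses for a parameter point.

    Runs the full simulation with ``overrides`` applied and returns
    -(discounted biogenic CO2 + CH4 + fossil fuel), in tCO2e: more
    emissions -> more negative.
    """
    params = base_params.with_overrides(overrides)
    traj = simulate(harvest, params, horizon)
    return -discount_series(traj.total_emissions_co2e, r)


#: Default sensitivity subset: influential parameters with published bounds.
DEFAULT_SENSITIVITY_PARAMS = (
    "doc_f_paper_msw",
    "ch4_recovery_r",
    "ch4_oxidation_ox",
    "sawmill_efficiency_base",
    "pulp_mill_efficiency",
    "doc_f_wood_msw",
    "doc_f_wood_cd",
    "half_life_paper",
    "construction_waste",
    "lifespans.corrugated_boxes.mode",
)


def sensitivity_specs(params: ParameterSet,
                      names: tuple[str, ...] = DEFAULT_SENSITIVITY_PARAMS
                      ) -> dict[str, tuple[float, float]]:
    """Bounds for the sensitivity subset.

    Scalar bounds come from the registry (explicit bounds, else certainty
    tier); table-cell entries use the -50%/+200% lifespan rule for paper
    lifespans and +-20% otherwise.
    """
    specs: dict[str, tuple[float, float]] = {}
    for name in names:
        if name in params.scalars:
            specs[name] = params.scalars[name].sampling_bounds()
            continue
        parts = name.split(".")
        if len(parts) == 3 and parts[0] == "lifespans":
            v = params.rate("lifespans").value(parts[1], parts[2])
            from . import categories as cat
            if parts[1] in cat.PAPER_PRODUCTS:
                specs[name] = (0.5 * v, 3.0 * v)
            else:
                specs[name] = (0.8 * v, 1.2 * v)
            continue
        raise ParameterError(f"cannot derive bounds for {name!r}")
    return specs


def run_morris(params: ParameterSet, harvest: HarvestInput,
               names: tuple[str, ...] = DEFAULT_SENSITIVITY_PARAMS,
               p: int = 10, r_traj: int = 30, seed: int = 0,
               discount_rate: float = 0.03, horizon: int = 120
               ) -> tuple[MorrisDesign, MorrisResult]:
    """Design, evaluate and summarize Morris screening on the full model."""
    specs = sensitivity_specs(params, names)
    design = build_design(specs, p=p, r=r_traj, seed=seed)
    values = np.empty(len(design.points))
    for i, point in enumerate(design.scaled_points()):
        overrides = dict(zip(design.names, point))
        values[i] = objective_discounted_emissions(
            overrides, harvest, params, r=discount_rate, horizon=horizon)
    return design, morris_indices(elementary_effects(design, values))
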