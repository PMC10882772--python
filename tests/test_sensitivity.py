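"""Morris screening: design contracts, analytic oracles, model signs."""

import statistics

import numpy as np
import pytest

import hwpflow as hf
from hwpflow.params import ParameterError
from hwpflow.sensitivity import sensitivity_specs

SPECS3 = {"a": (0.0, 1.0), "b": (2.0, 4.0), "c": (-1.0, 1.0)}


def reference_morris(design, values):
    """Independent elementary-effects computation (pure python).

    Walks each trajectory, finds the changed coordinate by comparison, and
    aggregates with the statistics module; shares only the design with the
    implementation under test.
    """
    k = len(design.names)
    per_param = {n: [] for n in design.names}
    for b in range(design.trajectories):
        rows = design.points[b * (k + 1):(b + 1) * (k + 1)]
        ys = values[b * (k + 1):(b + 1) * (k + 1)]
        for i in range(k):
            changed = [j for j in range(k) if rows[i + 1][j] != rows[i][j]]
            assert len(changed) == 1
            j = changed[0]
            step = rows[i + 1][j] - rows[i][j]
            per_param[design.names[j]].append((ys[i + 1] - ys[i]) / step)
    out = {}
    for n, ee in per_param.items():
        out[n] = (statistics.fmean(ee),
                  statistics.fmean(abs(e) for e in ee),
                  statistics.stdev(ee))
    return out


class TestDesign:
    def test_r_times_k_plus_one_points(self):
        d = hf.build_design(SPECS3, p=10, r=30, seed=0)
        assert d.points.shape == (30 * 4, 3)

    def test_same_seed_reproduces_design(self):
        d1 = hf.build_design(SPECS3, p=10, r=5, seed=42)
        d2 = hf.build_design(SPECS3, p=10, r=5, seed=42)
        assert np.array_equal(d1.points, d2.points)

    def test_all_coordinates_on_p_level_grid(self):
        p = 10
        d = hf.build_design(SPECS3, p=p, r=20, seed=1)
        grid = np.arange(p) / (p - 1)
        for value in d.points.ravel():
            assert np.isclose(grid, value).any()

    def test_each_trajectory_perturbs_every_parameter_once(self):
        d = hf.build_design(SPECS3, p=10, r=10, seed=3)
        k = len(d.names)
        for b in range(d.trajectories):
            rows = d.points[b * (k + 1):(b + 1) * (k + 1)]
            changed = set()
            for i in range(k):
                (idx,) = np.nonzero(rows[i + 1] != rows[i])
                assert len(idx) == 1
                changed.add(int(idx[0]))
            assert changed == set(range(k))

    def test_scaled_points_respect_bounds(self):
        d = hf.build_design(SPECS3, p=6, r=10, seed=9)
        pts = d.scaled_points()
        for j, (lo, hi) in enumerate(d.bounds):
            assert pts[:, j].min() >= lo - 1e-12
            assert pts[:, j].max() <= hi + 1e-12

    def test_fewer_than_two_levels_fatal(self):
        with pytest.raises(ParameterError):
            hf.build_design(SPECS3, p=1, r=2, seed=0)

    def test_inverted_bounds_fatal(self):
        with pytest.raises(ParameterError):
            hf.build_design({"a": (1.0, 0.0)}, p=4, r=2, seed=0)


class TestElementaryEffects:
    def _linear_values(self, design, coeffs):
        return design.points @ np.asarray(coeffs)

    def test_linear_objective_recovers_coefficients_with_zero_sigma(self):
        d = hf.build_design(SPECS3, p=10, r=12, seed=5)
        values = self._linear_values(d, [2.0, -3.0, 0.5])
        res = hf.morris_indices(hf.elementary_effects(d, values))
        assert res.indices.loc["a", "mu"] == pytest.approx(2.0, abs=1e-9)
        assert res.indices.loc["b", "mu"] == pytest.approx(-3.0, abs=1e-9)
        assert res.indices.loc["c", "mu"] == pytest.approx(0.5, abs=1e-9)
        assert (res.indices["sigma"] < 1e-9).all()
        assert np.allclose(res.indices["mu_star"], res.indices["mu"].abs())

    def test_constant_objective_gives_zero_effects(self):
        d = hf.build_design(SPECS3, p=10, r=6, seed=2)
        res = hf.morris_indices(hf.elementary_effects(d, np.ones(len(d.points))))
        assert (res.indices[["mu", "mu_star", "sigma"]].to_numpy() == 0).all()

    def test_interaction_term_produces_spread(self):
        d = hf.build_design({"u1": (0.0, 1.0), "u2": (0.0, 1.0)}, p=10, r=20, seed=7)
        values = d.points[:, 0] * d.points[:, 1]
        res = hf.morris_indices(hf.elementary_effects(d, values))
        assert res.indices.loc["u1", "sigma"] > 0

    def test_mismatched_value_count_fatal(self):
        d = hf.build_design(SPECS3, p=10, r=3, seed=0)
        with pytest.raises(ParameterError):
            hf.elementary_effects(d, np.ones(5))

    def test_agreement_with_independent_reference(self):
        d = hf.build_design(SPECS3, p=10, r=15, seed=11)
        rng = np.random.default_rng(0)
        # a nonlinear objective exercises mu != mu*
        values = (np.sin(3 * d.points[:, 0]) + d.points[:, 1] ** 2
                  - d.points[:, 0] * d.points[:, 2])
        mine = hf.morris_indices(hf.elementary_effects(d, values)).indices
        ref = reference_morris(d, values)
        for name, (mu, mu_star, sigma) in ref.items():
            assert mine.loc[name, "mu"] == pytest.approx(mu, abs=1e-9)
            assert mine.loc[name, "mu_star"] == pytest.approx(mu_star, abs=1e-9)
            assert mine.loc[name, "sigma"] == pytest.approx(sigma, abs=1e-9)

    def test_mu_star_bounds_mu_and_sigma_nonnegative(self):
        d = hf.build_design(SPECS3, p=10, r=10, seed=13)
        rng = np.random.default_rng(1)
        res = hf.morris_indices(
            hf.elementary_effects(d, rng.normal(size=len(d.points))))
        assert (res.indices["mu"].abs() <= res.indices["mu_star"] + 1e-12).all()
        assert (res.indices["sigma"] >= 0).all()


class TestModelObjective:
    def test_default_point_equals_bau_discounted_emissions(
            self, params, bau_harvest_input, bau_trajectory):
        obj = hf.objective_discounted_emissions({}, bau_harvest_input, params)
        expect = -hf.discount_series(bau_trajectory.total_emissions_co2e, 0.03)
        assert obj == pytest.approx(expect, rel=1e-12)

    def test_raising_ch4_recovery_lowers_emissions(self, params, bau_harvest_input):
        base = hf.objective_discounted_emissions({}, bau_harvest_input, params)
        more = hf.objective_discounted_emissions(
            {"ch4_recovery_r": 0.8019}, bau_harvest_input, params)
        assert more > base   # fewer emissions -> less negative objective

    def test_raising_paper_docf_raises_emissions(self, params, bau_harvest_input):
        base = hf.objective_discounted_emissions({}, bau_harvest_input, params)
        more = hf.objective_discounted_emissions(
            {"doc_f_paper_msw": 0.93}, bau_harvest_input, params)
        assert more < base

    def test_specs_use_published_bounds(self, params):
        specs = sensitivity_specs(params)
        assert specs["doc_f_paper_msw"] == (0.25, 0.93)
        assert specs["ch4_recovery_r"] == (0.4019, 0.8019)
        # paper lifespans follow the -50%/+200% rule
        assert specs["lifespans.corrugated_boxes.mode"] == (0.5, 3.0)
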