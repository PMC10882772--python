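"""Milling: efficiencies, residue allocation, fossil fuels, mass balance."""

import numpy as np
import pandas as pd
import pytest

import hwpflow as hf
from hwpflow import categories as cat
from hwpflow.harvest import CarbonInput
from hwpflow.milling import PRIMARY_OF_LOG
from hwpflow.params import ParameterError, RateTable


def _carbon(**kw):
    s = pd.Series(0.0, index=list(cat.LOG_TYPES))
    for k, v in kw.items():
        s[k] = v
    return CarbonInput(0, s)


class TestMill:
    def test_composite_90_percent_to_osb(self, params):
        eff = hf.mill_efficiencies(params)
        primary, residue = hf.mill(_carbon(composite=100.0), eff,
                                   params.table("mill_residue_shares"))
        assert primary.loc["composite", "osb"] == pytest.approx(90.0)
        assert residue.loc["composite"].sum() == pytest.approx(10.0)

    def test_saw_efficiency_splits_lumber_and_residue(self, params):
        eff = hf.mill_efficiencies(params)   # saw base 0.40
        primary, residue = hf.mill(_carbon(saw=100.0), eff,
                                   params.table("mill_residue_shares"))
        assert primary.loc["saw", "lumber"] == pytest.approx(40.0)
        assert residue.loc["saw"].sum() == pytest.approx(60.0)

    def test_full_efficiency_leaves_zero_residue(self, params):
        eff = hf.mill_efficiencies(params).copy()
        eff[:] = 1.0
        _, residue = hf.mill(_carbon(saw=100.0), eff,
                             params.table("mill_residue_shares"))
        assert residue.to_numpy().sum() == pytest.approx(0.0)

    def test_mass_conserved_per_log_type(self, params):
        logc = _carbon(pulp=10, cns=20, saw=30, composite=5, veneer=7)
        primary, residue = hf.mill(logc, hf.mill_efficiencies(params),
                                   params.table("mill_residue_shares"))
        total = primary.sum(axis=1) + residue.sum(axis=1)
        assert np.allclose(total.to_numpy(), logc.carbon.to_numpy(), atol=1e-12)

    def test_efficiency_out_of_range_fatal(self, params):
        eff = hf.mill_efficiencies(params).copy()
        eff["saw"] = 1.5
        with pytest.raises(ParameterError):
            hf.mill(_carbon(saw=1.0), eff, params.table("mill_residue_shares"))


class TestSizeAdjustedSawEfficiency:
    @pytest.mark.parametrize("base,expected", [
        (0.40, (0.35, 0.40, 0.50)),
        (0.30, (0.25, 0.30, 0.40)),
    ])
    def test_small_minus_005_large_plus_01(self, base, expected):
        assert hf.size_adjust_saw_efficiency(base) == pytest.approx(expected)

    def test_clipped_to_unit_interval(self):
        small, mid, large = hf.size_adjust_saw_efficiency(0.95)
        assert large == 1.0
        assert 0 < small < mid <= 1


class TestResidueAllocation:
    def test_all_burned_routes_everything_to_burned(self, params):
        ru = params.table("residue_use").data.copy()
        ru[:] = 0.0
        ru["burned"] = 1.0
        from hwpflow.params import AllocationTable
        table = AllocationTable("residue_use", ru)
        residue = pd.Series({"bark": 3.0, "coarse": 5.0, "fine": 2.0})
        out = hf.allocate_residue(residue, table, params.table("fiber_split"))
        assert out["burned"] == pytest.approx(10.0)
        assert out.drop("burned").sum() == pytest.approx(0.0)

    def test_fiber_share_splits_by_fiber_table(self, params):
        # a pure-fiber residue class with the fixture 0.8/0.2 fiber split
        from hwpflow.params import AllocationTable
        ru = params.table("residue_use").data.copy()
        ru[:] = 0.0
        ru.loc["coarse", "fiber"] = 0.5
        ru.loc["coarse", "burned"] = 0.5
        ru.loc[["bark", "fine"], "burned"] = 1.0
        table = AllocationTable("residue_use", ru)
        out = hf.allocate_residue(pd.Series({"bark": 0.0, "coarse": 1.0, "fine": 0.0}),
                                  table, params.table("fiber_split"))
        assert out["pulp_paper"] == pytest.approx(0.5 * 0.8)
        assert out["nonstructural_panels"] == pytest.approx(0.5 * 0.2)

    def test_residue_mass_fully_assigned(self, params):
        residue = pd.Series({"bark": 1.7, "coarse": 2.9, "fine": 0.4})
        out = hf.allocate_residue(residue, params.table("residue_use"),
                                  params.table("fiber_split"))
        assert out.sum() == pytest.approx(residue.sum(), abs=1e-9)


class TestPrimaryProductVector:
    def test_row_sums_equal_log_carbon(self, params):
        logc = _carbon(pulp=11, cns=22, saw=33, large_saw=4, veneer=5,
                       pole=6, composite=7, bioenergy=8)
        vec = hf.primary_product_vector(logc, params)
        assert np.allclose(vec.sum(axis=1).to_numpy(), logc.carbon.to_numpy(),
                           atol=1e-9)

    def test_each_log_type_feeds_its_characteristic_product(self, params):
        for lt, prod in PRIMARY_OF_LOG.items():
            vec = hf.primary_product_vector(_carbon(**{lt: 100.0}), params)
            row = vec.loc[lt]
            # engineered wood may siphon a share from lumber/panels
            assert row[prod] + row["engineered_wood"] >= 100.0 * 0.3 or prod == "pulp_paper"
            assert row.sum() == pytest.approx(100.0)

    def test_higher_efficiency_increases_primary_reduces_burned(self, params):
        low = hf.apply_overrides(params, {"sawmill_efficiency_base": 0.35})
        high = hf.apply_overrides(params, {"sawmill_efficiency_base": 0.45})
        vec_lo = hf.primary_product_vector(_carbon(saw=100.0), low).loc["saw"]
        vec_hi = hf.primary_product_vector(_carbon(saw=100.0), high).loc["saw"]
        assert vec_hi["lumber"] > vec_lo["lumber"]
        assert vec_hi["burned"] < vec_lo["burned"]


class TestFossilFuel:
    def test_pellet_production_factor(self, params):
        primary = pd.Series({"pellets": 100.0})
        ledger = hf.fossil_fuel_emissions(primary, params.rate("ff_factors"))
        assert ledger.loc["pellets", "production"] == pytest.approx(31.79)

    def test_pulp_paper_total_factor(self, params):
        primary = pd.Series({"pulp_paper": 100.0})
        ledger = hf.fossil_fuel_emissions(primary, params.rate("ff_factors"))
        assert ledger.loc["pulp_paper"].sum() == pytest.approx(189.92)

    def test_empty_vector_gives_zero_ledger(self, params):
        ledger = hf.fossil_fuel_emissions(pd.Series(dtype=float),
                                          params.rate("ff_factors"))
        assert ledger.to_numpy().sum() == 0.0

    def test_unit_mismatch_is_fatal(self, params):
        wrong = RateTable("ff_factors", params.rate("ff_factors").data,
                          units="tCO2e per tCO2e product")
        with pytest.raises(ParameterError, match="tC product"):
            hf.fossil_fuel_emissions(pd.Series({"pellets": 1.0}), wrong)

    def test_per_co2e_units_converted_at_load(self, params, tmp_path):
        # a row stored per tCO2e in product must load as 44/12 x per tC
        hf.save_parameter_set(params, tmp_path / "wb")
        p = tmp_path / "wb" / "ff_factors.csv"
        df = pd.read_csv(p, index_col=0)
        df.loc["poles", "units"] = "tCO2e per tCO2e product"
        df.to_csv(p)
        reloaded = hf.load_parameter_set(tmp_path / "wb")
        orig = params.rate("ff_factors").data.loc["poles"]
        conv = reloaded.rate("ff_factors").data.loc["poles"]
        assert np.allclose(conv.to_numpy(), orig.to_numpy() * 44.0 / 12.0)
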