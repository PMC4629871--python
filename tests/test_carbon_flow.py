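"""Headspace gas accounting, ATP-based biomass, and carbon-budget closure."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isaflux import (
    ALPHA_ISA,
    AtpCalibration,
    HeadspaceRecord,
    ValidationError,
    balance_fermentation,
    biomass_from_atp,
    biomass_yield,
    carbon_split,
    compute_budget,
    headspace_moles,
    predicted_products,
)
from isaflux.carbon_flow import (
    biomass_carbon_from_dry_weight,
    dry_weight_from_biomass_carbon,
)

STANDARD = dict(pressure=101325.0, volume=0.075, temperature=293.15)


class TestHeadspaceMoles:
    def test_absent_gas_is_zero(self):
        rec = HeadspaceRecord(0, mole_fractions={"h2": 0.0, "n2": 1.0}, **STANDARD)
        assert headspace_moles(rec, "h2") == 0.0

    def test_pure_gas_matches_pv_over_rt(self):
        # n = PV/RT = 101325 * 75e-6 / (8.314 * 293.15) = 3.118 mmol
        rec = HeadspaceRecord(0, mole_fractions={"n2": 1.0}, **STANDARD)
        assert headspace_moles(rec, "n2") == pytest.approx(3.118, abs=5e-4)

    def test_hydrogen_at_a_third_of_the_headspace(self):
        rec = HeadspaceRecord(0, mole_fractions={"h2": 0.321, "n2": 0.679}, **STANDARD)
        assert headspace_moles(rec, "h2") == pytest.approx(1.00, abs=5e-3)

    def test_unknown_gas_rejected(self):
        rec = HeadspaceRecord(0, mole_fractions={"n2": 1.0}, **STANDARD)
        with pytest.raises(ValidationError, match="ch4"):
            headspace_moles(rec, "ch4")

    @given(
        scale_p=st.floats(min_value=0.1, max_value=10),
        y=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_pressure_and_mole_fraction(self, scale_p, y):
        base = HeadspaceRecord(0, mole_fractions={"h2": 1.0}, **STANDARD)
        scaled = HeadspaceRecord(
            0, pressure=STANDARD["pressure"] * scale_p,
            volume=STANDARD["volume"], temperature=STANDARD["temperature"],
            mole_fractions={"h2": y},
        )
        expected = headspace_moles(base, "h2") * scale_p * y
        assert headspace_moles(scaled, "h2") == pytest.approx(expected, rel=1e-12)

    def test_halving_temperature_doubles_moles(self):
        hot = HeadspaceRecord(0, mole_fractions={"n2": 1.0}, **STANDARD)
        cold = HeadspaceRecord(
            0, pressure=STANDARD["pressure"], volume=STANDARD["volume"],
            temperature=STANDARD["temperature"] / 2, mole_fractions={"n2": 1.0},
        )
        assert headspace_moles(cold, "n2") == pytest.approx(
            2 * headspace_moles(hot, "n2"), rel=1e-12
        )


class TestBiomassFromAtp:
    def test_identity_style_calibration(self):
        cal = AtpCalibration(slope=1.0, intercept=2.0)
        est = biomass_from_atp(1000.0, cal, volume=0.25)
        assert est.cfu_per_ml == pytest.approx(1e5)

    def test_dry_weight_from_cell_count_and_mass_per_cfu(self):
        # 1e9 CFU total at 2.8e-10 mg/CFU -> 0.28 mg
        cal = AtpCalibration(slope=1.0, intercept=2.0, mass_per_cfu=2.8e-10)
        # 1e9 CFU in 250 mL = 4e6 CFU/mL, i.e. RLU = 4e4 under this line
        est = biomass_from_atp(4e4, cal, volume=0.25)
        assert est.dry_weight == pytest.approx(0.28, rel=1e-9)

    def test_reading_at_calibration_bound_carries_no_warning(self, recwarn):
        cal = AtpCalibration(slope=1.0, intercept=2.0, valid_range=(10.0, 1e6))
        biomass_from_atp(10.0, cal, volume=0.25)
        assert len(recwarn) == 0

    def test_reading_outside_range_warns_but_extrapolates(self):
        cal = AtpCalibration(slope=1.0, intercept=2.0, valid_range=(10.0, 1e6))
        with pytest.warns(UserWarning, match="outside calibrated range"):
            est = biomass_from_atp(1.0, cal, volume=0.25)
        assert est.cfu_per_ml == pytest.approx(100.0)

    def test_nonpositive_rlu_rejected(self):
        cal = AtpCalibration(slope=1.0, intercept=2.0)
        with pytest.raises(ValidationError):
            biomass_from_atp(0.0, cal, volume=0.25)

    def test_dry_weight_carbon_round_trip(self):
        assert dry_weight_from_biomass_carbon(
            biomass_carbon_from_dry_weight(3.7)
        ) == pytest.approx(3.7, rel=1e-12)


class TestCarbonBudget:
    def test_printed_fraction_closure(self):
        # sinks fixed at 23.7 / 12.1 / 0.5 percent of 100 mmol C degraded
        budget = compute_budget(
            {ALPHA_ISA: 100 / 6}, acetate_c=23.7, inorganic_c=12.1, biomass_c=0.5
        )
        assert budget.f_eps == pytest.approx(0.637)
        total = budget.f_acetate + budget.f_carbonate + budget.f_biomass + budget.f_eps
        assert total == 1.0
        assert budget.feasible

    def test_no_products_routes_everything_to_eps(self):
        budget = compute_budget({ALPHA_ISA: 1.0}, acetate_c=0, inorganic_c=0, biomass_c=0)
        assert budget.f_eps == 1.0

    def test_full_fermentation_reproduces_the_stoichiometric_split(self):
        # cross-module oracle: sinks from predicted_products of the balanced
        # reaction must reproduce carbon_split exactly
        rxn = balance_fermentation(ALPHA_ISA)
        products = predicted_products(rxn, 1.0)
        budget = compute_budget(
            {ALPHA_ISA: 1.0},
            acetate_c=products["acetate"] * 2,
            inorganic_c=products["bicarbonate"],
            biomass_c=0.0,
        )
        f_ace, f_carb = carbon_split(rxn)
        assert budget.f_acetate == pytest.approx(float(f_ace), rel=1e-12)
        assert budget.f_carbonate == pytest.approx(float(f_carb), rel=1e-12)
        assert budget.f_eps == pytest.approx(0.0, abs=1e-12)

    def test_estimated_inorganic_mode_is_half_acetate_carbon(self):
        budget = compute_budget({ALPHA_ISA: 1.0}, acetate_c=2.0, inorganic_c=None, biomass_c=0)
        assert budget.f_carbonate == pytest.approx(budget.f_acetate / 2)
        assert "estimated" in budget.inorganic_mode

    def test_oversubscribed_budget_is_flagged_not_clipped(self):
        budget = compute_budget({ALPHA_ISA: 1.0}, acetate_c=7.0, inorganic_c=0.0, biomass_c=0.0)
        assert not budget.feasible
        assert budget.f_eps < 0  # reported as-is

    def test_zero_degraded_carbon_is_an_error(self):
        with pytest.raises(ValidationError, match="budget undefined"):
            compute_budget({ALPHA_ISA: 0.0}, acetate_c=0, inorganic_c=0, biomass_c=0)

    def test_negative_sink_is_an_error(self):
        with pytest.raises(ValidationError, match="negative"):
            compute_budget({ALPHA_ISA: 1.0}, acetate_c=-1, inorganic_c=0, biomass_c=0)


class TestBiomassYield:
    @pytest.mark.parametrize(
        "dw,substrate,expected",
        [(1.2, 100.0, 0.012), (0.0, 50.0, 0.0), (5.0, 5.0, 1.0)],
    )
    def test_ratio(self, dw, substrate, expected):
        assert biomass_yield(dw, substrate) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            biomass_yield(1.0, 0.0)
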