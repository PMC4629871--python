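"""Synthetic microcosm generator: conservation, stoichiometric coupling,
control behaviour and determinism."""

import numpy as np
import pytest

from isaflux import CycleSchedule, SimulationConfig, paper_preset, simulate


def single_pool_config(**overrides) -> SimulationConfig:
    params = dict(
        rate_constants={"alpha_ISA": 0.05},
        initial_concentrations={"alpha_ISA": 8.0, "acetate": 0.0},
        schedule=CycleSchedule(feed_times=(0.0, 14.0), waste_fraction=0.1,
                               reactor_volume=0.25,
                               feed_composition={"alpha_ISA": 30.0}),
        noise_cv=0.0,
        seed=0,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def conservation_violations(ledger, rel_tol=1e-9) -> int:
    total = ledger["total_c"].to_numpy()
    events = ledger["event"].to_numpy()
    bad = 0
    for i in range(1, len(total)):
        if events[i] != "post_feed":
            if abs(total[i] - total[i - 1]) > rel_tol * total[i - 1]:
                bad += 1
    return bad


class TestConservation:
    @pytest.mark.parametrize("dt", [0.1, 0.5, 1.0])
    def test_total_carbon_constant_between_feed_events(self, dt):
        out = simulate(paper_preset(noise_cv=0.0, dt=dt, seed=0))
        assert conservation_violations(out.ledger) == 0

    def test_feed_event_removes_exactly_the_waste_fraction_of_floc_pools(self):
        out = simulate(single_pool_config(phi_eps=0.3, phi_biomass=0.01))
        led = out.ledger
        pre = led[led["event"] == "pre_feed"].iloc[0]
        post = led[led["event"] == "post_feed"].iloc[0]
        assert post["eps_c"] == pytest.approx(0.9 * pre["eps_c"], rel=1e-12)
        assert post["biomass_c"] == pytest.approx(0.9 * pre["biomass_c"], rel=1e-12)
        assert post["inorganic_c"] == pytest.approx(0.9 * pre["inorganic_c"], rel=1e-12)


class TestStoichiometricCoupling:
    def test_full_fermentation_yields_two_acetate_per_isa_at_every_step(self):
        out = simulate(single_pool_config())
        led = out.ledger[out.ledger["event"] == "step"]
        first_cycle = led[led["time_d"] < 14.0]
        isa_mmol = first_cycle["alpha_ISA_c"].to_numpy() / 6
        acetate_mmol = first_cycle["acetate_c"].to_numpy() / 2
        degraded = isa_mmol[0] - isa_mmol
        produced = acetate_mmol - acetate_mmol[0]
        np.testing.assert_allclose(produced, 2 * degraded, rtol=1e-9, atol=1e-12)

    def test_eps_diversion_reduces_products_proportionally(self):
        full = simulate(single_pool_config())
        diverted = simulate(single_pool_config(phi_eps=0.5))
        a_full = full.ledger["acetate_c"].iloc[-1]
        a_div = diverted.ledger["acetate_c"].iloc[-1]
        assert a_div == pytest.approx(0.5 * a_full, rel=1e-9)

    def test_h2_recovery_scales_headspace_hydrogen_only(self):
        full = simulate(single_pool_config())
        half = simulate(single_pool_config(h2_recovery=0.5))
        assert half.ledger["h2_mmol"].iloc[-1] == pytest.approx(
            0.5 * full.ledger["h2_mmol"].iloc[-1], rel=1e-9
        )
        assert half.ledger["acetate_c"].iloc[-1] == pytest.approx(
            full.ledger["acetate_c"].iloc[-1], rel=1e-12
        )

    def test_discretization_invariance_of_cumulative_products(self):
        coarse = simulate(paper_preset(noise_cv=0.0, dt=1.0))
        fine = simulate(paper_preset(noise_cv=0.0, dt=0.1))
        for column in ("acetate_c", "inorganic_c", "eps_c", "h2_mmol"):
            assert fine.ledger[column].iloc[-1] == pytest.approx(
                coarse.ledger[column].iloc[-1], rel=5e-3
            )


class TestControlBehaviour:
    def test_inhibited_control_shows_no_activity(self):
        out = simulate(paper_preset(noise_cv=0.0, inhibited=True))
        led = out.ledger
        for name in ("alpha_ISA_c", "beta_ISA_c", "xylo_ISA_c"):
            within_cycle = led[(led["event"] == "step") & (led["time_d"] < 14.0)][name]
            assert within_cycle.nunique() == 1  # constant between feeds
        assert led["h2_mmol"].iloc[-1] == 0.0
        assert led["acetate_c"].iloc[-1] <= led["acetate_c"].iloc[0] + 1e-12


class TestPreset:
    def test_preset_reproduces_the_study_conditions(self):
        config = paper_preset()
        assert config.rate_constants["beta_ISA"] == pytest.approx(9.36e-2)
        assert config.rate_constants["alpha_ISA"] == pytest.approx(3.33e-2)
        assert config.rate_constants["xylo_ISA"] == pytest.approx(6.78e-2)
        assert config.phi_eps + config.phi_biomass < 1
        assert config.schedule.waste_fraction == 0.10
        assert config.schedule.reactor_volume == 0.25
        assert config.headspace_volume == 0.075
        assert config.temperature == pytest.approx(293.15)

    def test_same_seed_is_bit_identical_different_seed_is_not(self):
        a = simulate(paper_preset(seed=1))
        b = simulate(paper_preset(seed=1))
        c = simulate(paper_preset(seed=2))
        conc_a = [r.concentration for r in a.chemistry.records]
        conc_b = [r.concentration for r in b.chemistry.records]
        conc_c = [r.concentration for r in c.chemistry.records]
        assert conc_a == conc_b
        assert conc_a != conc_c

    def test_invalid_diversion_fractions_rejected(self):
        with pytest.raises(Exception, match="phi"):
            paper_preset(phi_eps=0.8, phi_biomass=0.3)


class TestObservations:
    def test_noise_free_observations_match_ledger_truth(self):
        out = simulate(single_pool_config())
        led = out.ledger
        for t, conc in out.chemistry.pooled("alpha_ISA"):
            row = led[(led["time_d"] == t) & (led["event"] != "pre_feed")].iloc[-1]
            assert conc == pytest.approx(row["alpha_ISA_c"] / 6 / 0.25, rel=1e-9)

    def test_headspace_pressure_rises_with_hydrogen(self):
        out = simulate(single_pool_config())
        pressures = [rec.pressure for rec in out.headspace]
        assert pressures[-1] > pressures[0]
        assert out.headspace[0].mole_fractions["h2"] == pytest.approx(0.0)

    def test_replicates_are_emitted_when_requested(self):
        out = simulate(single_pool_config(n_replicates=3, noise_cv=0.05))
        reps = {r.replicate for r in out.chemistry.records}
        assert reps == {"r1", "r2", "r3"}
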