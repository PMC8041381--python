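"""CAT simulator: rate laws, closed-form oracles, and mechanistic properties."""

import dataclasses
import math

import numpy as np
import pytest

from colonsim.metrics import auc_0_t
from colonsim.physiology import Compartment, DosingPlan, Physiology, build_physiology, configure_route
from colonsim.records import DrugRecord, PKParameters
from colonsim.simulator import (
    FormulationState,
    SimSettings,
    absorption_rate_coefficient,
    dissolution_rate,
    formulation_state,
    simulate,
)

KA_COLON = 8.7e-4 * 3600 * 17 / 78.5     # ketoprofen in the area-dialect colon, 1/h
KT_COLON = 60 / 720.0                    # 1/h


def single_compartment_gut(ka_area: float = 17.0, volume: float = 78.5,
                           transit_min: float = 720.0) -> Physiology:
    """Minimal chain whose terminal compartment is the only absorptive one."""
    comps = (
        Compartment(name="stomach", surface_area=0.0, volume=10.0, transit_time=15.0,
                    pH=3.0, micellar_volume_fraction=0.0, absorption_enabled=False),
        Compartment(name="duodenum", surface_area=0.0, volume=10.0, transit_time=15.0,
                    pH=6.5, micellar_volume_fraction=0.0, absorption_enabled=False),
        Compartment(name="colon", surface_area=ka_area, volume=volume,
                    transit_time=transit_min, pH=6.5, micellar_volume_fraction=0.0),
    )
    return Physiology(dialect="area_based", compartments=comps, colon_indices=(2,))


def probe_drug(peff: float = 8.7, solubility: float = 1e6) -> DrugRecord:
    return DrugRecord(name="probe", molecular_weight=300.0, peff_dog=peff,
                      solubility_buffer=solubility, solubility_buffer_ph=6.5,
                      molar_density=1.2, diffusion_coefficient=0.76)


def probe_pk(eh: float = 0.0, k10: float = 0.2, v: float = 0.5) -> PKParameters:
    return PKParameters(clearance=k10 * v, central_volume=v, first_pass_extraction=eh)


class TestAbsorptionRateCoefficient:
    def test_zero_permeability(self, area_physiology):
        assert absorption_rate_coefficient(0.0, area_physiology.compartments[-1]) == 0.0

    def test_colon_value_matches_hand_calculation(self, area_physiology):
        ka = absorption_rate_coefficient(8.7, area_physiology.compartments[-1])
        assert ka == pytest.approx(0.678, abs=1e-3)
        assert ka / 3600 == pytest.approx(1.884e-4, rel=1e-3)   # s⁻¹

    def test_linear_in_area(self):
        c1 = Compartment(name="a", surface_area=17.0, volume=78.5, transit_time=720, pH=6.5)
        c2 = Compartment(name="b", surface_area=34.0, volume=78.5, transit_time=720, pH=6.5)
        assert absorption_rate_coefficient(1.0, c2) == pytest.approx(
            2 * absorption_rate_coefficient(1.0, c1)
        )

    def test_disabled_compartment_returns_zero(self):
        c = Compartment(name="stomach", surface_area=100.0, volume=50.0,
                        transit_time=15, pH=3.0, absorption_enabled=False)
        assert absorption_rate_coefficient(5.0, c) == 0.0


class TestDissolutionRate:
    def test_saturation_stops_dissolution(self):
        assert dissolution_rate(10.0, 5.0, 100.0, 100.0, 1.2, 0.76) == 0.0

    def test_small_particles_dissolve_quadratically_faster_per_unit_mass(self):
        # under sink with h = r (< cap): rate/M ∝ 1/r²
        r1 = dissolution_rate(10.0, 1.0, 0.0, 50.0, 1.2, 0.76)
        r2 = dissolution_rate(20.0, 1.0, 0.0, 50.0, 1.2, 0.76)
        assert r1 / r2 == pytest.approx(4.0)

    def test_diffusion_layer_cap_engages_for_large_particles(self):
        # h capped at 30 μm: rate/M ∝ 1/(r·30) above the cap
        r1 = dissolution_rate(60.0, 1.0, 0.0, 50.0, 1.2, 0.76, diffusion_layer_cap=30.0)
        r2 = dissolution_rate(120.0, 1.0, 0.0, 50.0, 1.2, 0.76, diffusion_layer_cap=30.0)
        assert r1 / r2 == pytest.approx(2.0)

    def test_exhausted_bin_is_inert(self):
        assert dissolution_rate(10.0, 0.0, 0.0, 50.0, 1.2, 0.76) == 0.0


class TestFormulationState:
    def test_solution_rejects_bins(self):
        with pytest.raises(ValueError):
            FormulationState("solution", 10.0, ((5.0, 1.0),))

    def test_suspension_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FormulationState("suspension", 10.0, ((5.0, 0.5), (10.0, 0.4)))

    def test_default_particle_diameter_fallback(self):
        drug = probe_drug()
        state = formulation_state(drug, "suspension", 10.0)
        assert state.bins == ((10.0, 1.0),)   # 20 μm diameter → 10 μm radius


class TestSimulateOracles:
    def test_terminal_colon_competing_rates_limit(self, dataset, area_physiology):
        """Solution dosed to a terminal colon: f_abs → ka/(ka + k_t)."""
        drug = dataset.drug("Ketoprofen")
        pk = dataset.pk["Ketoprofen"]
        plan = configure_route(area_physiology, "colon")
        res = simulate(drug, pk, FormulationState("solution", 2.5), area_physiology,
                       plan, SimSettings(duration=200.0))
        expected = KA_COLON / (KA_COLON + KT_COLON)
        assert expected == pytest.approx(0.891, abs=5e-4)
        assert res.f_abs == pytest.approx(expected, abs=0.005)
        assert res.f_abs_colon == pytest.approx(res.f_abs, abs=1e-9)

    def test_plasma_matches_bateman_closed_form(self):
        """1-compartment disposition + constant-rate gut: double exponential."""
        phys = single_compartment_gut()
        drug = probe_drug()
        pk = probe_pk(eh=0.0, k10=0.2, v=0.5)
        dose = 10.0
        plan = DosingPlan(route="colon", deposit_compartment=2)
        res = simulate(drug, pk, FormulationState("solution", dose), phys, plan,
                       SimSettings(duration=48.0))
        ka = KA_COLON
        lam = ka + KT_COLON
        k10 = 0.2
        v_ml = 0.5 * 12 * 1000
        model = dose * ka / (lam - k10) * (
            np.exp(-k10 * res.times) - np.exp(-lam * res.times)
        ) / v_ml * 1000
        scale = model.max()
        assert np.allclose(res.plasma_concentration, model, atol=scale * 1e-4)

    def test_zero_permeability_everything_to_feces(self, area_physiology):
        drug = probe_drug(peff=1e-12)
        res = simulate(drug, probe_pk(), FormulationState("solution", 10.0),
                       area_physiology, configure_route(area_physiology, "oral"),
                       SimSettings(duration=500.0))
        assert res.f_abs == pytest.approx(0.0, abs=1e-9)
        assert res.plasma_concentration.max() < 1e-9
        assert res.excreted_to_feces[-1] == pytest.approx(10.0, rel=1e-3)

    def test_complete_first_pass_separates_absorption_from_exposure(self, area_physiology):
        drug = probe_drug()
        plan = configure_route(area_physiology, "colon")
        res_eh0 = simulate(drug, probe_pk(eh=0.0), FormulationState("solution", 10.0),
                           area_physiology, plan, SimSettings(duration=48.0))
        res_eh1 = simulate(drug, probe_pk(eh=1.0), FormulationState("solution", 10.0),
                           area_physiology, plan, SimSettings(duration=48.0))
        assert res_eh1.f_abs == pytest.approx(res_eh0.f_abs, rel=1e-9)
        assert np.all(res_eh1.plasma_concentration == 0.0)
        assert res_eh0.plasma_concentration.max() > 0


class TestSimulateProperties:
    def test_mass_balance_on_representative_arms(self, open_model_rows):
        assert all(r["mass_balance_error"] <= 1e-3 for r in open_model_rows.values())

    def test_fabs_monotone_in_peff(self, area_physiology):
        plan = configure_route(area_physiology, "colon")
        fabs = []
        for peff in (0.5, 2.0, 8.0):
            drug = probe_drug(peff=peff)
            res = simulate(drug, probe_pk(), FormulationState("solution", 10.0),
                           area_physiology, plan, SimSettings(duration=96.0))
            fabs.append(res.f_abs)
        assert fabs[0] < fabs[1] < fabs[2]

    def test_suspension_never_beats_solution(self, dataset, area_physiology):
        plan = configure_route(area_physiology, "colon")
        for name, dose in (("AZ3", 75.0), ("Felodipine", 10.0)):
            drug = dataset.drug(name)
            pk = dataset.pk[name]
            sol = simulate(drug, pk, formulation_state(drug, "solution", dose),
                           area_physiology, plan, SimSettings(duration=48.0))
            susp = simulate(drug, pk, formulation_state(drug, "suspension", dose),
                            area_physiology, plan, SimSettings(duration=48.0))
            assert susp.f_abs <= sol.f_abs + 1e-9

    def test_reference_route_has_zero_colonic_absorption(self, dataset, area_physiology):
        drug = dataset.drug("Ketoprofen")
        pk = dataset.pk["Ketoprofen"]
        res = simulate(drug, pk, FormulationState("solution", 2.5), area_physiology,
                       configure_route(area_physiology, "oral"), SimSettings(duration=48.0))
        assert res.cumulative_absorbed_colonic[-1] == 0.0
        assert res.f_abs > 0.5

    def test_colon_route_has_zero_pre_colonic_absorption(self, dataset, area_physiology):
        drug = dataset.drug("Ketoprofen")
        pk = dataset.pk["Ketoprofen"]
        res = simulate(drug, pk, FormulationState("solution", 2.5), area_physiology,
                       configure_route(area_physiology, "colon"), SimSettings(duration=48.0))
        assert res.f_abs_colon == pytest.approx(res.f_abs, abs=1e-12)

    def test_dose_linearity_of_auc(self, area_physiology):
        plan = configure_route(area_physiology, "colon")
        aucs = []
        for dose in (5.0, 10.0):
            res = simulate(probe_drug(), probe_pk(), FormulationState("solution", dose),
                           area_physiology, plan, SimSettings(duration=96.0))
            aucs.append(auc_0_t(res.times, res.plasma_concentration))
        assert aucs[1] == pytest.approx(2 * aucs[0], rel=1e-6)

    def test_solution_skips_dissolution_entirely(self, area_physiology):
        res = simulate(probe_drug(), probe_pk(), FormulationState("solution", 10.0),
                       area_physiology, configure_route(area_physiology, "colon"),
                       SimSettings(duration=2.0))
        assert np.all(res.solid == 0.0)
        assert res.dissolved[:, 0].sum() == pytest.approx(10.0)

    def test_geometry_colon_protocol_reaches_the_colon(self, dataset, geometry_physiology):
        drug = dataset.drug("Ketoprofen")
        pk = dataset.pk["Ketoprofen"]
        res = simulate(drug, pk, FormulationState("solution", 2.5), geometry_physiology,
                       configure_route(geometry_physiology, "colon"),
                       SimSettings(duration=48.0))
        # near-instant upstream transit delivers essentially the whole dose colonally
        assert res.f_abs_colon > 0.95 * res.f_abs
        assert res.mass_balance_error <= 1e-3
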