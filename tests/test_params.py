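"""Parameter-derivation rules: clearances, extraction, diffusion, solubility."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from colonsim.params import (
    DerivationContext,
    diffusion_coefficient,
    dog_peff_for,
    estimate_dog_peff,
    hepatic_extraction,
    luminal_solubility,
    molar_density,
    renal_clearance,
    solubility_at_ph,
)
from colonsim.physiology import build_physiology
from colonsim.records import DrugRecord

CTX = DerivationContext()


class TestRenalClearance:
    def test_absent_fu_means_zero(self):
        assert renal_clearance(None, CTX, 1.0) == 0.0

    def test_fu_times_gfr_with_unit_conversion(self):
        # fu 0.9 × 61.3 mL/min = 55.17 mL/min = 3.31 L/h
        assert renal_clearance(0.9, CTX, 10.0) == pytest.approx(3.3102)

    def test_clamped_to_zero_when_exceeding_total_clearance(self):
        # high fu, low total CL: fu×GFR estimate is inconsistent with in vivo CL
        total = 0.083 * 12  # L/h
        candidate = 0.85 * 61.3 * 60 / 1000
        assert candidate > total
        assert renal_clearance(0.85, CTX, total) == 0.0

    def test_zero_fu_gives_zero(self):
        assert renal_clearance(0.0, CTX, 1.0) == 0.0

    def test_fu_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            renal_clearance(1.2, CTX, 1.0)


class TestHepaticExtraction:
    def test_zero_clearance_gives_zero(self):
        assert hepatic_extraction(0.0, 0.0, CTX) == 0.0

    def test_reproduces_printed_first_pass_for_ketoprofen(self):
        # CL 0.146 L/h/kg at 30 kg, no renal component: E_H = 4.38/39.6
        eh = hepatic_extraction(0.146 * 30, 0.0, CTX)
        assert eh == pytest.approx(0.1106, abs=1e-4)
        assert eh == pytest.approx(0.1103, rel=0.005)  # printed 11.03 %

    def test_saturates_at_cap(self):
        assert hepatic_extraction(CTX.hepatic_blood_flow * 2, 0.0, CTX) == 0.999

    @given(st.floats(0.1, 30.0), st.floats(1.0, 4.0))
    def test_invariant_under_joint_scaling(self, cl_h, scale):
        ctx2 = DerivationContext(hepatic_blood_flow=CTX.hepatic_blood_flow * scale)
        assert hepatic_extraction(cl_h * scale, 0.0, ctx2) == pytest.approx(
            hepatic_extraction(cl_h, 0.0, CTX)
        )


class TestDiffusionCoefficient:
    def test_default_when_radius_absent(self):
        assert diffusion_coefficient(None, CTX) == 0.76

    def test_stokes_einstein_closed_form(self):
        # kT/(6πηr) at 310.15 K, η 6.92e-4 Pa·s, r 0.40 nm
        assert diffusion_coefficient(0.40e-9, CTX) == pytest.approx(0.821, abs=0.001)

    def test_inverse_in_radius(self):
        assert diffusion_coefficient(0.2e-9, CTX) == pytest.approx(
            2 * diffusion_coefficient(0.4e-9, CTX)
        )


class TestMolarDensity:
    def test_default(self):
        assert molar_density(384.0, None) == 1.2

    def test_ratio(self):
        assert molar_density(384.0, 300.0) == pytest.approx(1.28)

    def test_identity(self):
        assert molar_density(250.0, 250.0) == 1.0


class TestDogPeff:
    def test_strategy_one_is_identity(self):
        assert estimate_dog_peff(5.0, 1) == 5.0

    def test_strategy_two_scales_uniformly(self):
        assert estimate_dog_peff(5.0, 2) == 15.0

    @pytest.mark.parametrize(
        "human,expected",
        [(8.7, 8.7), (7.1, 7.1), (7.7, 7.7),  # high-permeability: unchanged
         (1.34, 4.02),                        # boundary is "lower or equal": ×3
         (0.5, 1.5)],
    )
    def test_strategy_three_piecewise(self, human, expected):
        assert estimate_dog_peff(human, 3) == pytest.approx(expected)

    @given(st.floats(0.01, 20.0))
    def test_strategy_three_ratio_is_one_or_three(self, human):
        ratio = estimate_dog_peff(human, 3) / human
        assert ratio == pytest.approx(3.0 if human <= 1.34 else 1.0)

    def test_measured_dog_value_takes_precedence(self):
        drug = DrugRecord(name="x", molecular_weight=100, solubility_buffer=1,
                          peff_dog=4.83, peff_human=1.34)
        assert dog_peff_for(drug, strategy=3) == 4.83

    def test_unknown_strategy_fatal(self):
        with pytest.raises(ValueError):
            estimate_dog_peff(1.0, 4)


class TestSolubility:
    AREA = build_physiology("area_based")

    def test_neutral_compound_flat_in_ph(self):
        for ph in (1.2, 6.45, 7.4):
            assert solubility_at_ph(53.0, [], ph, ref_ph=6.5) == 53.0

    def test_weak_acid_amplification(self):
        # ketoprofen: pKa 4.02, reference 51 μg/mL at pH 1.2 (essentially intrinsic)
        s = solubility_at_ph(51.0, [(4.02, "acid")], 6.45, ref_ph=1.2)
        s0 = 51.0 / (1 + 10 ** (1.2 - 4.02))
        assert s == pytest.approx(s0 * (1 + 10 ** (6.45 - 4.02)), rel=1e-12)
        assert s == pytest.approx(13_770, rel=0.01)

    def test_self_consistency_at_reference_ph(self):
        s = solubility_at_ph(8.9, [(12.0, "acid"), (2.2, "base")], 6.5, ref_ph=6.5)
        assert s == pytest.approx(8.9, rel=1e-12)

    def test_amplification_cap(self):
        s = solubility_at_ph(1.0, [(4.0, "acid")], 14.0 - 1e-9, ref_ph="intrinsic",
                             max_amplification=1000.0)
        assert s == pytest.approx(1000.0)

    def test_micellar_fraction_zero_gives_aqueous_only(self, dataset):
        felo = dataset.drug("Felodipine")
        colon = self.AREA.compartments[-1]
        assert luminal_solubility(felo, colon, CTX) == pytest.approx(1.0)

    def test_fassif_reference_level_recovers_measured_value(self, dataset):
        felo = dataset.drug("Felodipine")
        duodenum = self.AREA.compartments[1]  # micellar fraction = FaSSIF reference
        assert luminal_solubility(felo, duodenum, CTX) == pytest.approx(53.0)

    def test_half_reference_level_interpolates_linearly(self, dataset):
        felo = dataset.drug("Felodipine")
        from colonsim.physiology import Compartment
        half = Compartment(name="half", surface_area=1.0, volume=1.0, transit_time=1.0,
                           pH=6.5, micellar_volume_fraction=1e-4)
        assert luminal_solubility(felo, half, CTX) == pytest.approx(27.0)

    def test_no_fassif_measurement_means_no_enhancement(self, dataset):
        keto = dataset.drug("Ketoprofen")
        duodenum = self.AREA.compartments[1]
        assert luminal_solubility(keto, duodenum, CTX) == pytest.approx(
            solubility_at_ph(51.0, [(4.02, "acid")], 6.2, ref_ph=1.2)
        )

    @given(st.floats(0.0, 3e-4))
    def test_luminal_never_below_aqueous(self, mvf):
        from colonsim.physiology import Compartment
        felo = DrugRecord(name="felodipine-like", molecular_weight=384.0, peff_dog=7.7,
                          solubility_buffer=1.0, solubility_buffer_ph=6.5,
                          solubility_fassif=53.0)
        comp = Compartment(name="c", surface_area=1.0, volume=1.0, transit_time=1.0,
                           pH=6.5, micellar_volume_fraction=mvf)
        assert luminal_solubility(felo, comp, CTX) >= 1.0 - 1e-12
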