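"""Derivation of simulation-ready parameters from raw drug/PK records.

Covers the parameter-harmonization rules applied before simulation: renal
clearance from fu × GFR (with the zero-clamp when the estimate exceeds total
clearance), the well-stirred hepatic extraction ratio, Stokes–Einstein
diffusion, molar density, dog effective-permeability estimation from human
values, and pH-/micelle-dependent luminal solubility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .physiology import Compartment
from .records import DrugRecord

log = logging.getLogger(__name__)

BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class DerivationContext:
    """Physiological and physical constants used by the derivations.

    Defaults describe a 12 kg fasted Beagle: hepatic blood flow Q_H
    39.6 L/h, glomerular filtration rate 61.3 mL/min, blood:plasma ratio 1.
    ``fassif_micellar_fraction`` / ``fassif_bile_salt`` set the reference
    micellar level at which the measured FaSSIF solubility applies; compartment
    micellar content is scaled linearly against it.
    """

    hepatic_blood_flow: float = 39.6          # L/h
    glomerular_filtration_rate: float = 61.3  # mL/min
    blood_plasma_ratio: float = 1.0
    body_weight: float = 12.0                 # kg
    temperature: float = 310.15               # K
    water_viscosity: float = 6.92e-4          # Pa·s at 37 °C
    fassif_micellar_fraction: float = 2e-4    # matches the fasted SI compartments
    fassif_bile_salt: float = 3.0             # mM taurocholate in FaSSIF
    default_density: float = 1.2              # g/mL
    default_diffusion: float = 0.76           # 10⁻⁹ m²/s
    default_particle_diameter: float = 20.0   # μm

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0")


def renal_clearance(
    fu: float | None, context: DerivationContext, total_clearance: float
) -> float:
    """Renal clearance CL_R = fu × GFR, in L/h.

    Missing fu means CL_R is taken as zero.  When the fu × GFR estimate
    exceeds the total clearance observed in vivo the estimate is physically
    inconsistent and CL_R is clamped to zero (with a warning) rather than
    producing a negative hepatic clearance.
    """
    if total_clearance < 0:
        raise ValueError("total_clearance must be >= 0")
    if fu is None:
        return 0.0
    if not 0.0 <= fu <= 1.0:
        raise ValueError("fu must lie in [0, 1]")
    cl_r = fu * context.glomerular_filtration_rate * 60.0 / 1000.0  # mL/min → L/h
    if cl_r > total_clearance:
        log.warning(
            "fu*GFR (%.3g L/h) exceeds total clearance (%.3g L/h); CL_R set to 0",
            cl_r, total_clearance,
        )
        return 0.0
    return cl_r


def hepatic_extraction(
    total_clearance: float, renal_cl: float, context: DerivationContext
) -> float:
    """Well-stirred hepatic extraction ratio E_H = CL_H / (Q_H × B/P).

    CL_H is the nonrenal clearance CL − CL_R.  The linear numerator form is
    used (no CL_H term in the denominator) and the result clamped to
    [0, 0.999].
    """
    if context.hepatic_blood_flow <= 0:
        raise ValueError("hepatic blood flow must be > 0")
    if not total_clearance >= renal_cl >= 0:
        raise ValueError("need total_clearance >= renal_clearance >= 0")
    cl_h = total_clearance - renal_cl
    eh = cl_h / (context.hepatic_blood_flow * context.blood_plasma_ratio)
    return min(max(eh, 0.0), 0.999)


def diffusion_coefficient(
    molecule_radius: float | None, context: DerivationContext
) -> float:
    """Stokes–Einstein aqueous diffusion coefficient, in 10⁻⁹ m²/s.

    D = kT / (6πηr) with the molecule radius in meters; an absent radius
    falls back to the 0.76 × 10⁻⁹ m²/s default.
    """
    if molecule_radius is None:
        return context.default_diffusion
    if molecule_radius <= 0:
        raise ValueError("molecule radius must be > 0")
    d = BOLTZMANN * context.temperature / (
        6.0 * math.pi * context.water_viscosity * molecule_radius
    )
    return d / 1e-9


def molar_density(molecular_weight: float, molar_volume: float | None,
                  default: float = 1.2) -> float:
    """ρ = M_W / V_M in g/mL; 1.2 g/mL when the molar volume is unknown."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    if molar_volume is None:
        return default
    if molar_volume <= 0:
        raise ValueError("molar volume must be > 0")
    return molecular_weight / molar_volume


def estimate_dog_peff(
    human_peff: float, strategy: int, cutoff: float = 1.34, fold: float = 3.0
) -> float:
    """Dog effective permeability from a human value (both 10⁻⁴ cm/s).

    Strategy 1 assumes identical permeability in dogs and humans; strategy 2
    a uniform ``fold`` (3×) increase in dogs; strategy 3 applies the 3× factor
    only to low-permeability compounds, i.e. human Peff ≤ ``cutoff`` (1.34,
    the high-permeability marker metoprolol — the boundary itself gets the
    factor), and identity above it.
    """
    if human_peff <= 0:
        raise ValueError("human_peff must be > 0")
    if strategy == 1:
        return human_peff
    if strategy == 2:
        return fold * human_peff
    if strategy == 3:
        return fold * human_peff if human_peff <= cutoff else human_peff
    raise ValueError(f"unknown Peff strategy {strategy!r}")


def dog_peff_for(drug: DrugRecord, strategy: int = 3, cutoff: float = 1.34,
                 fold: float = 3.0) -> float:
    """Dog Peff for a drug record: a measured value takes precedence."""
    if drug.peff_dog is not None:
        return drug.peff_dog
    return estimate_dog_peff(drug.peff_human, strategy, cutoff, fold)


def _amplification(pH: float, pka_list, max_amplification: float) -> float:
    amp = 1.0
    for pka, kind in pka_list:
        if kind == "acid":
            amp += 10.0 ** (pH - pka)
        else:
            amp += 10.0 ** (pka - pH)
    return min(amp, max_amplification)


def solubility_at_ph(
    s_ref: float,
    pka_list,
    target_ph: float,
    ref_ph: float | str = 7.0,
    max_amplification: float = 1000.0,
) -> float:
    """Henderson–Hasselbalch completion of a single-pH solubility, μg/mL.

    The intrinsic solubility S₀ is backed out of the reference measurement
    via the ionization amplification 1 + Σ10^(pH−pKa,acid) + Σ10^(pKa,base−pH)
    and re-applied at the target pH.  The amplification is capped (default
    1000×) relative to S₀ for numerical robustness.  ``ref_ph`` may be
    ``"intrinsic"`` (S_ref is S₀ directly) or ``"water"`` (taken as pH 7.0).
    """
    if s_ref <= 0:
        raise ValueError("reference solubility must be > 0")
    if ref_ph == "intrinsic":
        s0 = s_ref
    else:
        ph0 = 7.0 if ref_ph == "water" else float(ref_ph)
        s0 = s_ref / _amplification(ph0, pka_list, max_amplification)
    return s0 * _amplification(target_ph, pka_list, max_amplification)


def luminal_solubility(
    drug: DrugRecord,
    compartment: Compartment,
    context: DerivationContext,
    max_amplification: float = 1000.0,
) -> float:
    """Solubility in a GI compartment: pH-adjusted aqueous part plus a
    micelle-solubilized part scaled by the compartment's micellar content.

    The micellar enhancement is (S_FaSSIF − S_buffer at the FaSSIF pH),
    scaled linearly by the compartment micellar volume fraction (or bile-salt
    concentration) relative to the FaSSIF reference level.  Compartments with
    zero micellar content (stomach, colon), or drugs without a measured
    FaSSIF solubility, get the aqueous solubility only.
    """
    aqueous = solubility_at_ph(
        drug.solubility_buffer, drug.pka_list, compartment.pH,
        ref_ph=drug.solubility_buffer_ph, max_amplification=max_amplification,
    )
    if drug.solubility_fassif is None:
        return aqueous
    if compartment.micellar_volume_fraction is not None:
        scale = compartment.micellar_volume_fraction / context.fassif_micellar_fraction
    elif compartment.bile_salt is not None:
        scale = compartment.bile_salt / context.fassif_bile_salt
    else:
        scale = 0.0
    if scale == 0.0:
        return aqueous
    fassif_ph = 6.5
    buffer_at_fassif_ph = solubility_at_ph(
        drug.solubility_buffer, drug.pka_list, fassif_ph,
        ref_ph=drug.solubility_buffer_ph, max_amplification=max_amplification,
    )
    enhancement = drug.solubility_fassif - buffer_at_fassif_ph
    if enhancement < 0:
        log.warning(
            "%s: FaSSIF solubility below buffer solubility at pH %.2f; "
            "micellar enhancement clamped to 0", drug.name, fassif_ph,
        )
        enhancement = 0.0
    return aqueous + scale * enhancement
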