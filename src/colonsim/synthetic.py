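"""Synthetic drugs, study designs, and noisy "observed" outcomes.

The generator emulates the structure of a regional-absorption study in dogs:
drugs spanning the four BCS quadrants (solubility high/low × permeability
high/low, sampled log-uniformly within ranges bracketing the real compound
set), paired oral-reference and colon arms, plasma sampling on a fixed
schedule, and multiplicative lognormal residual noise.  One lognormal
deviate is drawn per arm and applied to every sample of that arm's profile,
so an arm's observed/true AUC ratio is itself a single lognormal draw — the
property the metric-calibration checks rely on.  Ground truth is returned
alongside every record so recovery can be asserted end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .metrics import auc_0_t, resample_profile
from .physiology import build_physiology, configure_route
from .records import DrugRecord, PKParameters, StudyArm
from .simulator import SimSettings, formulation_state, simulate

BCS_CLASSES = ("I", "II", "III", "IV")

# ranges bracketing the real compound set
PEFF_RANGE = (0.8, 8.7)          # 10⁻⁴ cm/s
SOLUBILITY_RANGE = (0.37, 43000.0)   # μg/mL
CL_RANGE = (0.08, 2.6)           # L/h/kg

# quadrant split points: geometric midpoints of the ranges
PEFF_SPLIT = math.sqrt(PEFF_RANGE[0] * PEFF_RANGE[1])
SOLUBILITY_SPLIT = math.sqrt(SOLUBILITY_RANGE[0] * SOLUBILITY_RANGE[1])

#: (high solubility, high permeability) flags per BCS class
_BCS_QUADRANT = {"I": (True, True), "II": (False, True), "III": (True, False), "IV": (False, False)}


@dataclass(frozen=True)
class SyntheticStudySpec:
    n_drugs: int = 8
    bcs_mix: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in BCS_CLASSES}
    )
    formulations: tuple[str, ...] = ("solution", "suspension")
    routes: tuple[str, ...] = ("oral", "colon")
    sampling_schedule: tuple[float, ...] = (
        0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 36.0, 48.0
    )
    residual_cv: float = 0.2
    dose_mg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs <= 0:
            raise ValueError("n_drugs must be > 0")
        if abs(sum(self.bcs_mix.values()) - 1.0) > 1e-9:
            raise ValueError("bcs_mix fractions must sum to 1")
        if self.residual_cv < 0:
            raise ValueError("residual_cv must be >= 0")
        if np.any(np.diff(self.sampling_schedule) <= 0):
            raise ValueError("sampling schedule must be strictly increasing")


def log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    """Log-uniform samples on [lo, hi] (median = geometric mean of bounds)."""
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


def noise_sigma(cv: float) -> float:
    """Lognormal σ for a given coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv))


def analytic_aafe(cv: float) -> float:
    """Expected AAFE of self-prediction under arm-level lognormal noise.

    |log ε| of a lognormal(0, σ) deviate is half-normal with mean σ√(2/π),
    so AAFE → exp(σ√(2/π)) as the number of arms grows.
    """
    return math.exp(noise_sigma(cv) * math.sqrt(2.0 / math.pi))


def _rng(spec: SyntheticStudySpec, *keys: int) -> np.random.Generator:
    return np.random.default_rng([abs(spec.seed) % (2**31), *keys])


def generate_drug(
    spec: SyntheticStudySpec, index: int
) -> tuple[DrugRecord, PKParameters, dict]:
    """Deterministically generate one synthetic drug and its ground truth."""
    rng = _rng(spec, 1, index)
    classes = sorted(spec.bcs_mix)
    bcs = str(rng.choice(classes, p=[spec.bcs_mix[c] for c in classes]))
    high_sol, high_perm = _BCS_QUADRANT[bcs]
    peff_lo, peff_hi = (PEFF_SPLIT, PEFF_RANGE[1]) if high_perm else (PEFF_RANGE[0], PEFF_SPLIT)
    sol_lo, sol_hi = (
        (SOLUBILITY_SPLIT, SOLUBILITY_RANGE[1]) if high_sol else (SOLUBILITY_RANGE[0], SOLUBILITY_SPLIT)
    )
    peff = float(log_uniform(rng, peff_lo, peff_hi))
    solubility = float(log_uniform(rng, sol_lo, sol_hi))
    cl = float(log_uniform(rng, *CL_RANGE))
    v = float(log_uniform(rng, 0.15, 1.5))
    fu = float(rng.uniform(0.05, 0.95))
    radius = float(log_uniform(rng, 1.0, 25.0))
    two_compartment = bool(rng.random() < 0.5)
    drug = DrugRecord(
        name=f"SYN{index:03d}",
        molecular_weight=float(rng.uniform(180.0, 540.0)),
        pka_list=[],                      # neutral: solubility independent of pH
        logd74=float(rng.uniform(-2.0, 4.0)),
        molar_density=1.2,
        particle_radius_mean=radius,
        diffusion_coefficient=0.76,
        peff_dog=peff,
        solubility_buffer=solubility,
        solubility_buffer_ph=6.5,
        bcs_class=bcs,
    )
    pk = PKParameters(
        clearance=cl,
        central_volume=v,
        k12=float(rng.uniform(0.5, 6.0)) if two_compartment else None,
        k21=float(rng.uniform(0.3, 3.0)) if two_compartment else None,
        fraction_unbound=fu,
        first_pass_extraction=min(cl * 12.0 / 39.6, 0.95),  # well-stirred at 12 kg
    )
    truth = {
        "index": index, "bcs": bcs, "peff_dog": peff, "solubility": solubility,
        "clearance": cl, "central_volume": v, "particle_radius": radius,
    }
    return drug, pk, truth


def _simulate_truth(drug, pk, formulation, route, spec, settings=None):
    physiology = build_physiology("area_based")
    plan = configure_route(physiology, route)
    state = formulation_state(drug, formulation, spec.dose_mg)
    settings = settings or SimSettings(duration=spec.sampling_schedule[-1])
    return simulate(drug, pk, state, physiology, plan, settings)


def generate_observed_arm(
    drug: DrugRecord,
    pk: PKParameters,
    formulation: str,
    route: str,
    spec: SyntheticStudySpec,
    arm_index: int = 0,
    settings: SimSettings | None = None,
) -> tuple[StudyArm, dict]:
    """Simulate the true profile and contaminate it with residual noise.

    The arm's samples all share one lognormal deviate (CV = residual_cv).
    Colon arms also simulate a matching oral reference (same dose and
    formulation, independent noise) to yield an observed F_rel,colon.
    """
    schedule = np.asarray(spec.sampling_schedule)
    result = _simulate_truth(drug, pk, formulation, route, spec, settings)
    true_samples = resample_profile(result.times, result.plasma_concentration, schedule)
    sigma = noise_sigma(spec.residual_cv)
    name_key = sum(ord(ch) for ch in drug.name) % 100003  # stable across runs
    rng = _rng(spec, 2, name_key, arm_index)
    eps = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
    observed = true_samples * eps
    t0 = np.concatenate([[0.0], schedule])
    obs_auc = auc_0_t(t0, np.concatenate([[0.0], observed]))
    truth = {
        "auc_true": auc_0_t(t0, np.concatenate([[0.0], true_samples])),
        "f_abs": result.f_abs,
        "f_abs_colon": result.f_abs_colon,
        "noise": eps,
    }
    observed_frel = None
    if route == "colon":
        ref = _simulate_truth(drug, pk, formulation, "oral", spec, settings)
        ref_samples = resample_profile(ref.times, ref.plasma_concentration, schedule)
        eps_ref = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
        ref_auc = auc_0_t(t0, np.concatenate([[0.0], ref_samples * eps_ref]))
        truth["auc_ref_true"] = auc_0_t(t0, np.concatenate([[0.0], ref_samples]))
        truth["frel_true"] = (
            truth["auc_true"] / truth["auc_ref_true"] if truth["auc_ref_true"] > 0 else float("nan")
        )
        observed_frel = obs_auc / ref_auc if ref_auc > 0 else None
    arm = StudyArm(
        drug_name=drug.name, dose=spec.dose_mg, formulation=formulation,
        route=route, observed_auc_0t=obs_auc, observed_frel_colon=observed_frel,
        t_last=float(schedule[-1]),
    )
    return arm, truth


def self_prediction_aucs(
    spec: SyntheticStudySpec, n_arms: int
) -> tuple[np.ndarray, np.ndarray]:
    """(observed, true) AUC pairs for metric calibration.

    The cohort's drugs are reused cyclically (one simulation per drug) and
    each arm draws its own noise deviate; with arm-level noise this is exactly
    equivalent to rerunning ``generate_observed_arm`` per replicate.
    """
    drugs = [generate_drug(spec, i) for i in range(spec.n_drugs)]
    true_aucs = []
    schedule = np.asarray(spec.sampling_schedule)
    t0 = np.concatenate([[0.0], schedule])
    for drug, pk, _ in drugs:
        res = _simulate_truth(drug, pk, "solution", "colon", spec)
        samples = resample_profile(res.times, res.plasma_concentration, schedule)
        true_aucs.append(auc_0_t(t0, np.concatenate([[0.0], samples])))
    sigma = noise_sigma(spec.residual_cv)
    rng = _rng(spec, 3)
    true = np.array([true_aucs[i % spec.n_drugs] for i in range(n_arms)])
    eps = np.exp(rng.normal(0.0, sigma, size=n_arms)) if sigma > 0 else np.ones(n_arms)
    return true * eps, true
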