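"""Typed records for study inputs: drugs, systemic PK, and study arms.

All records are plain dataclasses with eager validation in ``__post_init__``;
an invalid record raises :class:`ValueError` at construction time so that a
malformed fixture row can never reach the simulator.

Unit conventions (kept throughout the package):

* amounts mg, volumes mL, times h, concentrations μg/mL
* permeability in 10⁻⁴ cm/s, diffusion coefficients in 10⁻⁹ m²/s
* clearances and volumes of distribution per kg body weight (L/h/kg, L/kg)
"""

from __future__ import annotations

from dataclasses import dataclass, field


_PKA_KINDS = ("acid", "base")
_FORMULATIONS = ("solution", "suspension")
_ROUTES = ("oral", "duodenal", "colon")
_BCS_CLASSES = ("I", "II", "III", "IV")


@dataclass
class DrugRecord:
    """Physicochemical and biopharmaceutics identity of one compound.

    ``solubility_buffer_ph`` is the reference condition of the buffer
    solubility: a pH value, or the strings ``"intrinsic"`` (the value is the
    intrinsic solubility of the neutral species) or ``"water"`` (unbuffered
    water, treated as pH 7.0 downstream).
    """

    name: str
    molecular_weight: float                       # g/mol
    pka_list: list[tuple[float, str]] = field(default_factory=list)
    logd74: float | None = None
    molar_density: float | None = None            # g/mL
    particle_radius_mean: float | None = None     # μm
    particle_size_distribution: list[tuple[float, float]] | None = None
    diffusion_coefficient: float | None = None    # 10⁻⁹ m²/s
    peff_dog: float | None = None                 # 10⁻⁴ cm/s
    peff_human: float | None = None               # 10⁻⁴ cm/s
    solubility_buffer: float = 0.0                # μg/mL
    solubility_buffer_ph: float | str = 7.0
    solubility_fassif: float | None = None        # μg/mL
    bcs_class: str = "I"

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular_weight must be > 0")
        if self.solubility_buffer <= 0:
            raise ValueError(f"{self.name}: solubility_buffer must be > 0")
        if self.solubility_fassif is not None and self.solubility_fassif <= 0:
            raise ValueError(f"{self.name}: solubility_fassif must be > 0")
        for value, kind in self.pka_list:
            if kind not in _PKA_KINDS:
                raise ValueError(f"{self.name}: pKa kind {kind!r} not in {_PKA_KINDS}")
        if self.particle_size_distribution is not None:
            total = sum(w for _, w in self.particle_size_distribution)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: particle size distribution mass fractions sum "
                    f"to {total!r}, expected 1"
                )
        if self.peff_dog is None and self.peff_human is None:
            raise ValueError(f"{self.name}: at least one of peff_dog/peff_human required")
        if self.bcs_class not in _BCS_CLASSES:
            raise ValueError(f"{self.name}: unknown BCS class {self.bcs_class!r}")


@dataclass
class PKParameters:
    """Systemic disposition (1/2/3-compartment) and first-pass extraction.

    ``clearance`` and ``central_volume`` are normalized per kg body weight;
    the micro rate constants define optional peripheral compartments
    (``k13``/``k31`` present only together).  ``first_pass_extraction`` is the
    hepatic extraction ratio E_H as a fraction, taken as a given input when
    available and derivable from clearance otherwise.
    """

    clearance: float                     # L/h/kg
    central_volume: float                # L/kg
    k12: float | None = None             # 1/h
    k21: float | None = None
    k13: float | None = None
    k31: float | None = None
    fraction_unbound: float | None = None
    first_pass_extraction: float | None = None   # fraction
    body_weight: float = 12.0            # kg

    def __post_init__(self) -> None:
        if self.clearance < 0:
            raise ValueError("clearance must be >= 0")
        if self.central_volume <= 0:
            raise ValueError("central_volume must be > 0")
        if (self.k12 is None) != (self.k21 is None):
            raise ValueError("k12 and k21 must be present together")
        if (self.k13 is None) != (self.k31 is None):
            raise ValueError("k13 present iff k31 present")
        if self.k13 is not None and self.k12 is None:
            raise ValueError("third compartment requires a second one")
        fu = self.fraction_unbound
        if fu is not None and not 0.0 <= fu <= 1.0:
            raise ValueError("fraction_unbound must lie in [0, 1]")
        eh = self.first_pass_extraction
        if eh is not None and not 0.0 <= eh <= 1.0:
            raise ValueError("first_pass_extraction must lie in [0, 1]")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")


@dataclass
class StudyArm:
    """One administration event with observed and software-predicted outcomes.

    Predicted columns are keyed by software label (e.g. ``"gisim"``,
    ``"gastroplus"``, ``"open_model"``).  ``predicted_fabs_colon_by_software``
    is stored in percent, as reported.
    """

    drug_name: str
    dose: float                          # mg
    formulation: str
    route: str
    observed_auc_0t: float | None = None             # μg·h/mL
    observed_frel_colon: float | None = None         # fraction
    predicted_auc_0t_by_software: dict[str, float] = field(default_factory=dict)
    predicted_frel_by_software: dict[str, float] = field(default_factory=dict)
    predicted_fabs_colon_by_software: dict[str, float] = field(default_factory=dict)
    t_last: float | None = None                      # h

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError(f"{self.drug_name}: dose must be > 0")
        if self.formulation not in _FORMULATIONS:
            raise ValueError(f"{self.drug_name}: formulation {self.formulation!r}")
        if self.route not in _ROUTES:
            raise ValueError(f"{self.drug_name}: route {self.route!r}")
        for label, store in (
            ("observed_auc_0t", [self.observed_auc_0t]),
            ("observed_frel_colon", [self.observed_frel_colon]),
            ("predicted_auc_0t", self.predicted_auc_0t_by_software.values()),
            ("predicted_frel", self.predicted_frel_by_software.values()),
            ("predicted_fabs_colon", self.predicted_fabs_colon_by_software.values()),
        ):
            for v in store:
                if v is not None and v < 0:
                    raise ValueError(f"{self.drug_name}: {label} must be >= 0")
        colon_specific = (
            self.observed_frel_colon is not None
            or self.predicted_frel_by_software
            or self.predicted_fabs_colon_by_software
        )
        if colon_specific and self.route != "colon":
            raise ValueError(
                f"{self.drug_name}: colon-specific outcomes on a {self.route} arm"
            )


@dataclass
class Dataset:
    """Drugs, their PK parameters, and study arms, cross-validated."""

    drugs: list[DrugRecord]
    pk: dict[str, PKParameters]
    arms: list[StudyArm]

    def __post_init__(self) -> None:
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names")
        self._by_name = {d.name: d for d in self.drugs}
        for arm in self.arms:
            if arm.drug_name not in self._by_name:
                raise ValueError(f"arm references unknown drug {arm.drug_name!r}")
            if arm.drug_name not in self.pk:
                raise ValueError(f"no PK parameters for {arm.drug_name!r}")

    def drug(self, name: str) -> DrugRecord:
        return self._by_name[name]
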