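"""Fasted-Beagle gastrointestinal physiologies and dosing-route configuration.

Two dialects of the nine-compartment GI chain are provided:

* ``area_based`` — compartments carry an absorptive surface area directly
  (stomach non-absorptive, terminal colon compartment).  The colonic surface
  area is scaled so that colon/total area equals 3.5 % of the whole tract,
  giving 17 cm² from the small-intestinal areas.
* ``geometry_based`` — compartments carry cylinder geometry (length, radius)
  plus a surface-area enhancement factor (SEF); the effective absorptive area
  is 2πrL × SEF.  The terminal segments are a cecum and an ascending colon,
  jointly treated as "colonic" for colon-absorption accounting.

Colon dosing differs by dialect: the area dialect deposits the dose directly
into the colon compartment, while the geometry dialect doses the stomach and
collapses upstream residence by setting compartments 1–7 transit to 0.001 min
and the small-intestinal fluid to 0.1 % of default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

AREA_BASED = "area_based"
GEOMETRY_BASED = "geometry_based"
DIALECTS = (AREA_BASED, GEOMETRY_BASED)
ROUTES = ("oral", "duodenal", "colon")


@dataclass(frozen=True)
class Compartment:
    """One luminal GI segment.

    Exactly one of ``surface_area`` (area dialect) or the
    ``length``/``radius``/``surface_enhancement_factor`` triple (geometry
    dialect) is populated.  ``transit_time`` is the mean residence time of the
    first-order transit step, in minutes.
    """

    name: str
    volume: float            # mL
    transit_time: float      # min
    pH: float
    surface_area: float | None = None            # cm²
    length: float | None = None                  # cm
    radius: float | None = None                  # cm
    surface_enhancement_factor: float | None = None
    micellar_volume_fraction: float | None = None
    bile_salt: float | None = None               # mM
    absorption_enabled: bool = True

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError(f"{self.name}: volume must be >= 0")
        if self.transit_time <= 0:
            raise ValueError(f"{self.name}: transit_time must be > 0")
        if not 0.0 < self.pH < 14.0:
            raise ValueError(f"{self.name}: pH out of range")
        has_area = self.surface_area is not None
        has_geom = all(
            v is not None
            for v in (self.length, self.radius, self.surface_enhancement_factor)
        )
        if has_area == has_geom:
            raise ValueError(
                f"{self.name}: exactly one of surface_area or "
                "(length, radius, SEF) must be populated"
            )

    @property
    def effective_area(self) -> float:
        """Absorptive area in cm²: the tabulated area, or 2πrL × SEF."""
        if self.surface_area is not None:
            return self.surface_area
        return 2.0 * math.pi * self.radius * self.length * self.surface_enhancement_factor


@dataclass(frozen=True)
class Physiology:
    dialect: str
    compartments: tuple[Compartment, ...]
    colon_indices: tuple[int, ...]   # positions of the colonic segment(s)

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if len(self.compartments) < 3:
            raise ValueError("physiology needs >= 3 compartments")
        for i in self.colon_indices:
            if not 0 <= i < len(self.compartments):
                raise ValueError("colon index out of range")

    def index_of(self, name: str) -> int:
        for i, c in enumerate(self.compartments):
            if c.name == name:
                return i
        raise KeyError(name)

    def to_yaml(self) -> str:
        doc = {
            "dialect": self.dialect,
            "colon_indices": list(self.colon_indices),
            "compartments": [
                {k: v for k, v in vars(c).items() if v is not None}
                for c in self.compartments
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)


@dataclass(frozen=True)
class DosingPlan:
    route: str
    deposit_compartment: int
    transit_overrides: dict[int, float] = field(default_factory=dict)   # min
    fluid_fraction_override: float | None = None
    colon_absorption_in_reference: bool = True

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")


# area dialect: (name, surface area cm², volume mL, transit min, pH, micellar fraction)
_AREA_TABLE = (
    ("stomach", 0.0, 450.0, 15.0, 3.0, 0.0),
    ("duodenum", 140.6, 35.16, 15.6, 6.2, 0.0002),
    ("jejunum 1", 103.6, 25.90, 15.6, 6.2, 0.0002),
    ("jejunum 2", 76.3, 19.08, 15.6, 6.2, 0.0002),
    ("ileum 1", 56.2, 14.06, 15.6, 6.4, 0.0002),
    ("ileum 2", 41.4, 10.36, 15.6, 6.6, 0.0002),
    ("ileum 3", 30.5, 7.632, 15.6, 6.68, 0.0002),
    ("ileum 4", 22.5, 5.621, 15.6, 6.75, 0.0002),
    ("colon", 17.0, 78.50, 720.0, 6.45, 0.0),
)

# geometry dialect: (name, length cm, radius cm, SEF, volume mL, transit min, pH, bile salt mM)
_GEOMETRY_TABLE = (
    ("stomach", 15.00, 1.00, 1.000, 51.00, 15.0, 3.00, 0.0),
    ("duodenum", 12.43, 0.62, 6.940, 6.083, 16.8, 6.20, 5.000),
    ("jejunum 1", 66.64, 0.47, 5.905, 18.58, 51.0, 6.20, 4.050),
    ("jejunum 2", 66.64, 0.41, 4.161, 13.74, 37.8, 6.20, 1.820),
    ("ileum 1", 1.43, 0.47, 3.271, 0.389, 1.2, 6.40, 0.610),
    ("ileum 2", 1.43, 0.47, 3.233, 0.396, 1.2, 6.60, 0.440),
    ("ileum 3", 1.43, 0.47, 3.196, 0.403, 1.2, 6.68, 0.310),
    ("cecum", 1.99, 0.93, 1.630, 0.538, 228.6, 6.75, 0.0),
    ("asc colon", 4.26, 1.42, 1.700, 2.700, 491.4, 6.45, 0.0),
)

#: small-intestinal surface areas of the area dialect (duodenum..ileum 4), cm²
SMALL_INTESTINE_AREAS = tuple(row[1] for row in _AREA_TABLE[1:8])

#: colon fraction of total GI surface area used to scale the colon compartment
COLON_AREA_FRACTION = 0.035


def scale_colon_surface_area(si_surface_areas, colon_fraction_of_total: float = COLON_AREA_FRACTION) -> float:
    """Colon surface area making colon/total area equal the given fraction.

    Solving A_colon / (A_colon + ΣA_SI) = f gives A_colon = f/(1−f) × ΣA_SI.
    With the seven tabulated small-intestinal areas and f = 3.5 % this yields
    ≈ 17 cm².
    """
    areas = list(si_surface_areas)
    if any(a <= 0 for a in areas):
        raise ValueError("surface areas must be > 0")
    f = colon_fraction_of_total
    if not 0.0 <= f < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    return f / (1.0 - f) * sum(areas)


def build_physiology(dialect: str, overrides: dict[str, dict[str, float]] | None = None) -> Physiology:
    """Build one of the two fasted-Beagle physiologies.

    ``overrides`` maps compartment name → {field: value} and is applied last;
    referencing an unknown compartment or field raises.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    comps: list[Compartment] = []
    if dialect == AREA_BASED:
        for name, area, vol, tt, ph, mvf in _AREA_TABLE:
            comps.append(
                Compartment(
                    name=name, surface_area=area, volume=vol, transit_time=tt,
                    pH=ph, micellar_volume_fraction=mvf,
                    absorption_enabled=area > 0,
                )
            )
        colon_indices = (8,)
    else:
        for name, length, radius, sef, vol, tt, ph, bs in _GEOMETRY_TABLE:
            comps.append(
                Compartment(
                    name=name, length=length, radius=radius,
                    surface_enhancement_factor=sef, volume=vol, transit_time=tt,
                    pH=ph, bile_salt=bs,
                    absorption_enabled=name != "stomach",
                )
            )
        colon_indices = (7, 8)  # cecum + ascending colon

    if overrides:
        by_name = {c.name: c for c in comps}
        for comp_name, fields in overrides.items():
            if comp_name not in by_name:
                raise ValueError(f"override references unknown compartment {comp_name!r}")
            current = by_name[comp_name]
            for fname in fields:
                if not hasattr(current, fname):
                    raise ValueError(f"override references unknown field {fname!r}")
            by_name[comp_name] = replace(current, **fields)
        comps = [by_name[c.name] for c in comps]

    return Physiology(dialect=dialect, compartments=tuple(comps), colon_indices=colon_indices)


def configure_route(physiology: Physiology, route: str) -> DosingPlan:
    """Dosing plan for a route under the physiology's dialect.

    Never mutates ``physiology``; colon dosing under the area dialect deposits
    straight into the colon, under the geometry dialect into the stomach with
    near-zero upstream transit (0.001 min in compartments 1–7) and the SI
    fluid cut to 0.1 % of default.  Oral/duodenal reference administrations in
    the area dialect disable colonic absorption.
    """
    if route not in ROUTES:
        raise ValueError(f"unknown route {route!r}")
    n = len(physiology.compartments)
    if physiology.dialect == AREA_BASED:
        if route == "colon":
            return DosingPlan(route=route, deposit_compartment=physiology.colon_indices[0])
        deposit = 0 if route == "oral" else physiology.index_of("duodenum")
        return DosingPlan(
            route=route, deposit_compartment=deposit,
            colon_absorption_in_reference=False,
        )
    # geometry dialect
    if route == "colon":
        return DosingPlan(
            route=route, deposit_compartment=0,
            transit_overrides={i: 0.001 for i in range(min(7, n))},
            fluid_fraction_override=0.001,
        )
    if route == "oral":
        return DosingPlan(route=route, deposit_compartment=0)
    # duodenal reference: dose the stomach but flush it instantly
    return DosingPlan(route=route, deposit_compartment=0, transit_overrides={0: 0.001})
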