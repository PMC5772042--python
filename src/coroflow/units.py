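"""Physical constants, clinical/SI unit conversion, and the Poiseuille
geometry <-> RLC relations for a vessel segment.

All internal computation in :mod:`coroflow` is in SI units (Pa, s, m³).
Clinical units (mmHg, s, ml, mm, cm) appear only at the I/O boundary —
config files, printed tables, CLI output — and are converted exactly once.

A cylindrical segment of diameter ``D``, length ``l`` and wall thickness
``h`` maps to the electrical-analogue triple

    R = 128 μ l / (π D⁴)      viscous (Poiseuille) resistance
    C = π D³ l / (4 G h)      wall compliance
    L = 4 ρ l / (π D²)        blood inertance

with blood viscosity μ, density ρ and vessel Young's modulus G.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MMHG_PA",
    "ML_M3",
    "ConfigurationError",
    "PhysicalConstants",
    "VesselGeometry",
    "VesselRLC",
    "convert_units",
    "rlc_from_geometry",
    "geometry_from_rl",
]

#: Pascals per mmHg.
MMHG_PA = 133.322
#: Cubic metres per millilitre.
ML_M3 = 1e-6


class ConfigurationError(ValueError):
    """Raised for malformed configuration input (unknown keys/tags, schema
    violations)."""


# Multiplicative factor clinical -> SI, per quantity kind.
_CLINICAL_TO_SI = {
    "P": MMHG_PA,            # mmHg            -> Pa
    "R": MMHG_PA / ML_M3,    # mmHg·s/ml       -> Pa·s/m³
    "L": MMHG_PA / ML_M3,    # mmHg·s²/ml      -> Pa·s²/m³
    "C": ML_M3 / MMHG_PA,    # ml/mmHg         -> m³/Pa
    "Q": ML_M3,              # ml/s            -> m³/s
    "V": ML_M3,              # ml              -> m³
}


def convert_units(value: float, from_system: str, to_system: str) -> float:
    """Convert a scalar between the clinical and SI unit systems.

    Unit tags are ``"<kind>_clinical"`` / ``"<kind>_SI"`` with kind in
    ``P`` (pressure), ``R`` (resistance), ``L`` (inertance), ``C``
    (compliance), ``Q`` (flow), ``V`` (volume).  Conversion between the
    same system is the identity; kinds must match.
    """
    kf, sf = _parse_tag(from_system)
    kt, st = _parse_tag(to_system)
    if kf != kt:
        raise ConfigurationError(
            f"cannot convert quantity kind {kf!r} to {kt!r}"
        )
    factor = 1.0
    if sf == "clinical":
        factor *= _CLINICAL_TO_SI[kf]
    if st == "clinical":
        factor /= _CLINICAL_TO_SI[kf]
    return value * factor


def _parse_tag(tag: str) -> tuple[str, str]:
    try:
        kind, system = tag.split("_", 1)
    except (ValueError, AttributeError):
        raise ConfigurationError(f"malformed unit tag {tag!r}") from None
    kind = kind.upper()
    system = system.lower()
    if kind not in _CLINICAL_TO_SI or system not in ("clinical", "si"):
        raise ConfigurationError(f"unknown unit tag {tag!r}")
    return kind, system


@dataclass(frozen=True)
class PhysicalConstants:
    """Global blood/vessel constants.

    Attributes
    ----------
    mu : float
        Blood dynamic viscosity (Pa·s).
    rho : float
        Blood density (kg/m³).
    G : float
        Vessel wall Young's modulus (Pa).
    wall_ratio : float
        Wall-thickness-to-diameter ratio h/D (dimensionless).
    t_cycle : float
        Cardiac period (s); 0.8 s corresponds to 75 beats per minute.
    """

    mu: float = 4e-3
    rho: float = 1.04e3
    G: float = 2e5
    wall_ratio: float = 0.08
    t_cycle: float = 0.8

    def __post_init__(self) -> None:
        for name in ("mu", "rho", "G", "wall_ratio", "t_cycle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class VesselGeometry:
    """Cylindrical segment geometry: lumen diameter ``D``, length ``l`` and
    wall thickness ``h``, all in metres."""

    D: float
    l: float
    h: float

    def __post_init__(self) -> None:
        if self.D <= 0 or self.l <= 0:
            raise ValueError("D and l must be strictly positive")
        if not 0 < self.h < self.D:
            raise ValueError("wall thickness must satisfy 0 < h < D")


@dataclass(frozen=True)
class VesselRLC:
    """Electrical-analogue triple of one segment, in SI units
    (Pa·s/m³, Pa·s²/m³, m³/Pa)."""

    R: float
    L: float = 0.0
    C: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be strictly positive")
        if self.L < 0 or self.C < 0:
            raise ValueError("L and C must be nonnegative")


def rlc_from_geometry(
    geom: VesselGeometry, const: PhysicalConstants = PhysicalConstants()
) -> VesselRLC:
    """Poiseuille-tube lumped values from segment geometry (SI)."""
    D, l, h = geom.D, geom.l, geom.h
    R = 128.0 * const.mu * l / (math.pi * D**4)
    C = math.pi * D**3 * l / (4.0 * const.G * h)
    L = 4.0 * const.rho * l / (math.pi * D**2)
    return VesselRLC(R=R, L=L, C=C)


def geometry_from_rl(
    R: float, L: float, const: PhysicalConstants = PhysicalConstants()
) -> VesselGeometry:
    """Invert the Poiseuille relations for (D, l) from resistance and
    inertance (SI units).

    From R = 128μl/(πD⁴) and L = 4ρl/(πD²):
    D² = 32 μ L / (ρ R) and l = L π D² / (4 ρ).  Wall thickness is set to
    ``const.wall_ratio · D``.
    """
    if R <= 0 or L <= 0:
        raise ValueError("R and L must be strictly positive")
    D2 = 32.0 * const.mu * L / (const.rho * R)
    D = math.sqrt(D2)
    l = L * math.pi * D2 / (4.0 * const.rho)
    return VesselGeometry(D=D, l=l, h=const.wall_ratio * D)
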