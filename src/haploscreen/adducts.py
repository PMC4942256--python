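"""Monoisotopic mass arithmetic for Paal-Knorr adduct detection.

Ophiobolin A carries a 1,4-dicarbonyl that condenses with primary amines
(the ethanolamine head group of PE, or free ethanolamine) to a pyrrole,
losing two molecules of water.  This module computes the neutral adduct
mass, the [M+H]+ m/z, and the ppm window used to extract ion chromatograms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

# Monoisotopic (most-abundant-isotope) atomic masses, IUPAC/CODATA, Da.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

PROTON_MASS = 1.007276467  # Da
# H2O monoisotopic, derived from the element table (18.0105646... Da)
WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Reference formulas used throughout the package.
OPA_FORMULA = "C25H36O4"          # ophiobolin A
ETHANOLAMINE_FORMULA = "C2H7NO"   # Etn
DIOLEOYL_PE_FORMULA = "C41H78NO8P"


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts."""
    if not formula:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        if not match.group(0):
            break
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic ("exact") mass of a molecular formula, Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    if not counts:
        raise ValueError("empty formula")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class Molecule:
    """A named species defined by formula or by a fixed monoisotopic mass."""

    name: str
    formula: str | None = None
    mass: float | None = None

    def monoisotopic_mass(self) -> float:
        if self.formula is not None:
            return monoisotopic_mass(self.formula)
        if self.mass is None or self.mass <= 0:
            raise ValueError(f"{self.name}: no formula and no positive mass")
        return self.mass


def paal_knorr_adduct_mass(carbonyl_parent: float, primary_amine: float) -> float:
    """Neutral mass of the pyrrole condensation product: the addition
    product minus two molecules of water."""
    return carbonyl_parent + primary_amine - 2.0 * WATER_MASS


def protonated_mz(neutral_mass: float, charge: int = 1) -> float:
    """m/z of the [M+zH]^z+ ion."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON_MASS) / charge


def round4(x: float) -> float:
    """Half-up rounding at 4 decimals, the usual mass-report precision."""
    return float(Decimal(repr(x)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MzWindow:
    """An extracted-ion-chromatogram m/z interval around a center mass."""

    low: float
    high: float
    center: float
    ppm: float

    def __post_init__(self) -> None:
        if not self.low <= self.center <= self.high:
            raise ValueError("window must bracket its center")

    def contains(self, mz: float) -> bool:
        return self.low <= mz <= self.high


def eic_window(center: float, ppm: float = 5.0) -> MzWindow:
    """Symmetric ppm window: the center is first rounded to 4 decimals, then
    widened by ±ppm and each bound rounded to 4 decimals."""
    if center <= 0:
        raise ValueError("center m/z must be positive")
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    c = round4(center)
    half = c * ppm * 1e-6
    return MzWindow(low=round4(c - half), high=round4(c + half), center=c, ppm=ppm)


def adduct_eic_window(
    parent: Molecule | str, amine: Molecule | str, ppm: float = 5.0, charge: int = 1
) -> MzWindow:
    """Convenience: formula/mass in, EIC window of the protonated Paal-Knorr
    adduct out."""
    parent_mass = (
        parent.monoisotopic_mass() if isinstance(parent, Molecule) else monoisotopic_mass(parent)
    )
    amine_mass = (
        amine.monoisotopic_mass() if isinstance(amine, Molecule) else monoisotopic_mass(amine)
    )
    neutral = paal_knorr_adduct_mass(parent_mass, amine_mass)
    return eic_window(protonated_mz(neutral, charge), ppm)
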