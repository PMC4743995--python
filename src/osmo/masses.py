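"""Monoisotopic mass arithmetic for accurate-mass ion annotation.

All masses are in daltons (Da). The atomic mass table is bundled as a
constant so that annotation windows are bit-reproducible across
environments: an accurate-mass match within 0.005 Da must not depend on
which physical-constants release a host library happens to ship.
"""
from __future__ import annotations

import re

# Monoisotopic masses of the most abundant isotope, IUPAC/CODATA values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.96370693,
    "Cl": 34.96885271,
    "F": 18.99840320,
    "Br": 78.9183376,
    "I": 126.904468,
    "Se": 79.9165218,
    "Fe": 55.9349421,
    "Mg": 23.98504190,
    "Ca": 39.96259098,
    "Zn": 63.9291466,
    "Cu": 62.9296011,
    "Mn": 54.9380496,
    "Co": 58.9332002,
    "Ni": 57.9353479,
    "Mo": 97.9054078,
    "B": 11.0093055,
    "Si": 27.9769265,
    "W": 183.9509326,
}

#: Mass of a proton (H+ with the electron removed), Da. Negative-mode
#: deprotonation removes a proton, not a neutral hydrogen atom.
PROTON_MASS = 1.00727646688

#: Mass difference between 13C and 12C, Da.
C13_C12_DELTA = 1.0033548378

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """An elemental formula could not be parsed or contains unknown elements."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C5H9NO4`` into an element→count map.

    Only flat Hill-style formulas are supported (no parentheses, charges
    or isotope labels); that is the format of KEGG-style compound tables.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"unparsable formula {formula!r} at position {pos}")
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"unparsable formula {formula!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Neutral monoisotopic mass in Da of an elemental formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    if not counts:
        raise FormulaError("empty formula")
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items()))
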