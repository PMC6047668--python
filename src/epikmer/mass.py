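"""Monoisotopic m/z from molecular formulas, for conjugate identity checks.

Masses use the most abundant isotope of each element; for ions the electron
mass is subtracted per positive charge (added per negative charge) before
dividing by |charge|. Values are reported rounded half-even to 4 decimals,
the precision at which ESI-TOF calculated masses are quoted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# Monoisotopic masses (Da), CODATA/IUPAC values.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}
ELECTRON_MASS = 0.0005485799

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHARGE_RE = re.compile(r"([+-]+)$")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts plus an integer charge (positive for cations)."""

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("formula must contain at least one element")
        if any(n < 0 for _, n in self.counts):
            raise ValueError("element counts must be non-negative")

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        body = "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self.counts if n > 0
        )
        if self.charge == 0:
            return body
        sign = "+" if self.charge > 0 else "-"
        magnitude = abs(self.charge)
        return body + (sign if magnitude == 1 else f"{magnitude}{sign}")


def parse_formula(text: str) -> MolecularFormula:
    """Parse e.g. 'C60H69N14O10+' -> counts {C:60, H:69, N:14, O:10}, +1.

    Bare element symbols have implicit count 1; trailing '+'/'-' signs set
    the charge (one unit per sign, so '++' is a dication).
    """
    text = text.strip()
    if not text:
        raise ValueError("empty formula")
    charge = 0
    m = _CHARGE_RE.search(text)
    if m:
        signs = m.group(1)
        if len(set(signs)) != 1:
            raise ValueError(f"mixed charge signs in {text!r}")
        charge = len(signs) if signs[0] == "+" else -len(signs)
        text = text[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula near {text[pos:]!r}")
        if not m.group(0):
            break
        element, digits = m.groups()
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {element!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text) or not counts:
        raise ValueError(f"cannot parse formula {text!r}")
    return MolecularFormula(counts=tuple(counts.items()), charge=charge)


def neutral_monoisotopic_mass(formula: MolecularFormula) -> float:
    """Sum of per-element monoisotopic masses, no electron correction."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts)


def monoisotopic_mz(formula: MolecularFormula | str) -> float:
    """Electron-corrected monoisotopic m/z, rounded half-even to 4 decimals.

    Neutral species (charge 0) return the plain monoisotopic mass.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mass = neutral_monoisotopic_mass(formula) - formula.charge * ELECTRON_MASS
    if abs(formula.charge) >= 1:
        mass /= abs(formula.charge)
    return round(mass, 4)
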