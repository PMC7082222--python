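"""Chemical formula parsing and molecular weights.

Formulas follow the flat Hill convention used by the SBML fbc
``chemicalFormula`` attribute (no parentheses, no isotopes, no charges),
e.g. ``C6H12O6``.  Wildcard tokens (``R``, ``X``, ``*`` or any uppercase
symbol without a tabulated weight) mark a polymeric or generic group; the
parse succeeds but the element map is flagged as not fully specified and
has no defined molecular weight.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict

__all__ = [
    "ElementMap",
    "FormulaError",
    "UndefinedWeightError",
    "parse_formula",
    "molecular_weight",
    "render_formula",
    "ATOMIC_WEIGHTS",
]

#: IUPAC conventional atomic weights (abridged to three decimals).
ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.94, "Be": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.95, "Ru": 101.07, "Rh": 102.906, "Pd": 106.42,
    "Ag": 107.868, "Cd": 112.414, "In": 114.818, "Sn": 118.710,
    "Sb": 121.760, "Te": 127.60, "I": 126.904, "Xe": 131.293,
    "Cs": 132.905, "Ba": 137.327, "La": 138.905, "Ce": 140.116,
    "W": 183.84, "Pt": 195.084, "Au": 196.967, "Hg": 200.592,
    "Tl": 204.38, "Pb": 207.2, "Bi": 208.980, "U": 238.029,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\*)(\d*)")


class FormulaError(ValueError):
    """Syntactically invalid formula (distinct from the wildcard case)."""


class UndefinedWeightError(ValueError):
    """Molecular weight requested for a formula with wildcard groups."""


@dataclass
class ElementMap:
    counts: Dict[str, int] = field(default_factory=dict)
    is_fully_specified: bool = True

    def __add__(self, other: "ElementMap") -> "ElementMap":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementMap(merged, self.is_fully_specified and other.is_fully_specified)


def parse_formula(formula: str) -> ElementMap:
    """Parse a flat Hill-notation formula into an element map."""
    if not isinstance(formula, str) or formula.strip() == "":
        raise FormulaError("empty formula")
    formula = formula.strip()
    if "(" in formula or ")" in formula:
        raise FormulaError("parenthesized (nested) formulas are not supported")
    counts: Dict[str, int] = {}
    fully = True
    pos = 0
    while pos < len(formula):
        match = _TOKEN.match(formula, pos)
        if match is None or match.start() != pos:
            raise FormulaError(f"invalid formula token at {formula[pos:]!r}")
        if match.group(3) is not None:  # '*' wildcard
            fully = False
            pos = match.end()
            continue
        symbol, digits = match.group(1), match.group(2)
        count = int(digits) if digits else 1
        if symbol in ATOMIC_WEIGHTS:
            counts[symbol] = counts.get(symbol, 0) + count
        else:
            # R, X and other untabulated uppercase symbols: wildcard groups
            fully = False
        pos = match.end()
    return ElementMap(counts, fully)


def molecular_weight(em: ElementMap) -> float:
    """Molecular weight in g·mol⁻¹; requires a fully specified formula."""
    if not em.is_fully_specified:
        raise UndefinedWeightError("molecular weight undefined for wildcard formulas")
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in em.counts.items())


def render_formula(em: ElementMap) -> str:
    """Render counts in Hill order (C, H, then alphabetical)."""
    parts = []
    order = [el for el in ("C", "H") if el in em.counts]
    order += sorted(el for el in em.counts if el not in ("C", "H"))
    for el in order:
        n = em.counts[el]
        if n:
            parts.append(el + (str(n) if n != 1 else ""))
    return "".join(parts)
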