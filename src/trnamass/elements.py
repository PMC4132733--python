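"""Element mass table and molecular-formula arithmetic.

All numeric masses in the package are derived from molecular formulas
evaluated over this table, so a single set of element masses controls
precision everywhere.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Mapping

__all__ = [
    "MONOISOTOPIC",
    "AVERAGE",
    "PROTON_MASS",
    "parse_formula",
    "formula_mass",
    "formula_add",
    "formula_sub",
    "format_formula",
    "WATER",
    "HPO3",
    "CH2",
]

#: element symbol -> monoisotopic mass of the principal isotope, Da (CODATA/IUPAC)
MONOISOTOPIC: Mapping[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Se": 79.9165218,
}

#: element symbol -> standard atomic weight, Da
AVERAGE: Mapping[str, float] = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "P": 30.973762,
    "S": 32.065,
    "Se": 78.96,
}

#: mass of the proton charge carrier (not the H atom), Da
PROTON_MASS = 1.00727646688

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formulas or unknown element symbols."""


def parse_formula(formula: str | Mapping[str, int]) -> Counter:
    """Parse ``"C9H12N2O6"`` into an element->count Counter.

    Accepts an already-parsed mapping for convenience. Negative counts are
    allowed in mappings (formula deltas) but not in strings.
    """
    if isinstance(formula, Mapping):
        return Counter(formula)
    counts: Counter = Counter()
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"malformed formula {formula!r} at offset {pos}")
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC:
            raise FormulaError(f"unknown element {symbol!r} in formula {formula!r}")
        counts[symbol] += int(digits) if digits else 1
        pos = match.end()
    if pos != len(formula) or not counts:
        raise FormulaError(f"malformed formula {formula!r}")
    return counts


def formula_mass(formula: str | Mapping[str, int], kind: str = "mono") -> float:
    """Mass of a formula over the element table (``kind``: mono|avg)."""
    if kind == "mono":
        table = MONOISOTOPIC
    elif kind == "avg":
        table = AVERAGE
    else:
        raise ValueError(f"kind must be 'mono' or 'avg', got {kind!r}")
    counts = parse_formula(formula)
    unknown = set(counts) - set(table)
    if unknown:
        raise FormulaError(f"unknown elements {sorted(unknown)}")
    return sum(table[el] * n for el, n in counts.items())


def formula_add(a: str | Mapping[str, int], b: str | Mapping[str, int]) -> Counter:
    out = parse_formula(a)
    out.update(parse_formula(b))
    return +out


def formula_sub(a: str | Mapping[str, int], b: str | Mapping[str, int]) -> Counter:
    out = parse_formula(a)
    out.subtract(parse_formula(b))
    return Counter({el: n for el, n in out.items() if n != 0})


def format_formula(counts: Mapping[str, int]) -> str:
    """Render a count mapping in Hill order (C, H, then alphabetical)."""
    parts = []
    ordered = [el for el in ("C", "H") if counts.get(el)]
    ordered += sorted(el for el in counts if el not in ("C", "H") and counts[el])
    for el in ordered:
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


WATER = parse_formula("H2O")
HPO3 = parse_formula("HPO3")
CH2 = parse_formula("CH2")
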