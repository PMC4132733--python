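"""Neutral masses, ESI m/z values, nucleoside adducts and CID ladders.

Fragment neutral mass convention (matching printed oligonucleotide MWs):

    M = sum(nucleoside masses)
      + (n - 1) * (HPO3 - H2O)            # phosphodiester linkages
      + HPO3          if 3'-linear phosphate
      + HPO3 - H2O    if 2',3'-cyclic phosphate
      + HPO3          if 5'-phosphate

Hydroxyl termini add nothing. The ESI charge carrier is the proton
(1.007276 Da): negative mode m/z = (M - z*mp)/z, positive (M + z*mp)/z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .elements import PROTON_MASS, formula_mass
from .registry import Registry, default_registry
from .sequence import ModifiedSequence

__all__ = [
    "PredictedIon",
    "CIDIon",
    "fragment_neutral_mass",
    "mz",
    "nucleoside_adduct_mz",
    "predict_ions",
    "predict_cid_ladder",
    "WATER_MASS",
    "HPO3_MASS",
    "LINKAGE_MASS",
]

WATER_MASS = formula_mass("H2O")
HPO3_MASS = formula_mass("HPO3")
#: net mass of one internal phosphodiester linkage (condensation)
LINKAGE_MASS = HPO3_MASS - WATER_MASS

_WATER_AVG = formula_mass("H2O", "avg")
_HPO3_AVG = formula_mass("HPO3", "avg")


@dataclass(frozen=True)
class PredictedIon:
    """A charged species predicted for one fragment."""

    fragment: str  # bracket-notation label of the neutral fragment
    neutral_mass: float
    polarity: str  # "+" | "-"
    charge: int
    mz: float


@dataclass(frozen=True)
class CIDIon:
    """One collision-induced dissociation product ion."""

    series: str  # c | y | w | a-B
    index: int
    neutral_mass: float
    charge: int
    mz: float


def fragment_neutral_mass(
    fragment: ModifiedSequence,
    registry: Registry | None = None,
    kind: str = "mono",
) -> float:
    """Neutral mass of a fragment under the module's terminus convention."""
    registry = registry or default_registry()
    if kind == "mono":
        water, hpo3 = WATER_MASS, HPO3_MASS
    elif kind == "avg":
        water, hpo3 = _WATER_AVG, _HPO3_AVG
    else:
        raise ValueError(f"kind must be 'mono' or 'avg', got {kind!r}")
    total = sum(registry.residue_mass(code, kind) for code in fragment.residues)
    total += (len(fragment) - 1) * (hpo3 - water)
    if fragment.three_prime == "p":
        total += hpo3
    elif fragment.three_prime == ">p":
        total += hpo3 - water
    if fragment.five_prime == "p":
        total += hpo3
    return total


def mz(neutral_mass: float, charge: int, polarity: str = "-") -> float:
    """m/z of the z-fold (de)protonated ion of a neutral of given mass."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if polarity in ("-", "neg", "negative"):
        return (neutral_mass - charge * PROTON_MASS) / charge
    if polarity in ("+", "pos", "positive"):
        return (neutral_mass + charge * PROTON_MASS) / charge
    raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")


def nucleoside_adduct_mz(
    code: str, resolution: str = "unit", registry: Registry | None = None
) -> float:
    """[M+H]+ m/z of a free nucleoside, unit-rounded by default."""
    registry = registry or default_registry()
    accurate = registry.residue_mass(code) + PROTON_MASS
    if resolution == "accurate":
        return accurate
    if resolution == "unit":
        return float(round(accurate))
    raise ValueError(f"resolution must be 'unit' or 'accurate', got {resolution!r}")


def predict_ions(
    fragment: ModifiedSequence,
    charges: Iterable[int] = (1, 2),
    polarity: str = "-",
    registry: Registry | None = None,
) -> list[PredictedIon]:
    """Predicted ions of one fragment at the requested charge states."""
    from .sequence import serialize_sequence

    registry = registry or default_registry()
    neutral = fragment_neutral_mass(fragment, registry)
    label = serialize_sequence(fragment)
    return [
        PredictedIon(
            fragment=label,
            neutral_mass=neutral,
            polarity=polarity,
            charge=z,
            mz=mz(neutral, z, polarity),
        )
        for z in charges
    ]


_CID_SERIES = ("c", "y", "w", "a-B")


def predict_cid_ladder(
    fragment: ModifiedSequence,
    series: Sequence[str] = _CID_SERIES,
    max_charge: int = 1,
    polarity: str = "-",
    registry: Registry | None = None,
) -> list[CIDIon]:
    """c/y/w/a-B ion ladders for indices 1..n-1.

    Conventions (neutral fragment masses):

    * ``c_i``  5' piece of i residues ending in a 3'-linear phosphate,
      keeping the parent 5' terminus
    * ``y_i``  3' piece of i residues with a 5'-OH, keeping the parent
      3' terminus
    * ``w_i``  3' piece of i residues with a 5'-phosphate
    * ``a-B_i`` 5' piece of i residues with a 3'-OH minus the neutral
      nucleobase of its 3'-terminal residue

    Closure identity: mass(c_i) + mass(y_{n-i}) = parent mass + H2O.
    """
    registry = registry or default_registry()
    n = len(fragment)
    if n < 2:
        raise ValueError("CID ladder requires a fragment of length >= 2")
    unknown = set(series) - set(_CID_SERIES)
    if unknown:
        raise ValueError(f"unknown CID series {sorted(unknown)}")
    ions: list[CIDIon] = []
    for i in range(1, n):
        pieces: dict[str, float] = {}
        if "c" in series:
            piece = fragment.slice(0, i, fragment.five_prime, "p")
            pieces["c"] = fragment_neutral_mass(piece, registry)
        if "y" in series:
            piece = fragment.slice(n - i, n, "OH", fragment.three_prime)
            pieces["y"] = fragment_neutral_mass(piece, registry)
        if "w" in series:
            piece = fragment.slice(n - i, n, "p", fragment.three_prime)
            pieces["w"] = fragment_neutral_mass(piece, registry)
        if "a-B" in series:
            piece = fragment.slice(0, i, fragment.five_prime, "OH")
            base = registry.get(fragment.residues[i - 1]).base_formula
            pieces["a-B"] = fragment_neutral_mass(piece, registry) - formula_mass(base)
        for name, neutral in pieces.items():
            for z in range(1, max_charge + 1):
                ions.append(
                    CIDIon(
                        series=name,
                        index=i,
                        neutral_mass=neutral,
                        charge=z,
                        mz=mz(neutral, z, polarity),
                    )
                )
    return ions
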