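"""In-silico nuclease digestion of modified RNA sequences.

Both enzymes modelled here cleave the phosphodiester bond 3' of a target
residue by transesterification through the 2'-OH, so cleavage is blocked
when the residue 5' of the scissile bond is 2'-O-methylated. Products get
a 5'-OH and a 3'-phosphate (linear by default; the 2',3'-cyclic
intermediate form is available as an option). The parent's own termini
are preserved on the first and last fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .registry import Registry, ResidueDefinition, default_registry
from .sequence import ModifiedSequence, TRNARecord

__all__ = [
    "EnzymeRule",
    "DigestFragment",
    "RNASE_T1",
    "RNASE_A",
    "get_enzyme",
    "digest",
    "fragment_for_position",
]


@dataclass(frozen=True)
class EnzymeRule:
    """Endoribonuclease cleavage rule: cleaves 3' of matching residues."""

    name: str
    cleaves_after: Callable[[ResidueDefinition], bool]
    blocked_by_2prime_methyl: bool = True

    def is_site(self, residue: ResidueDefinition) -> bool:
        if self.blocked_by_2prime_methyl and residue.ribose_2prime_methyl:
            return False
        return self.cleaves_after(residue)


#: cleaves 3' of guanosine (flagged residues); Gm is not a site
RNASE_T1 = EnzymeRule("RNaseT1", lambda r: r.t1_cleavable)

#: cleaves 3' of pyrimidines (flagged residues); Um/Cm are not sites
RNASE_A = EnzymeRule("RNaseA", lambda r: r.rnaseA_cleavable)

_ENZYMES = {
    "t1": RNASE_T1,
    "rnaset1": RNASE_T1,
    "rnasea": RNASE_A,
    "a": RNASE_A,
}


def get_enzyme(name: str) -> EnzymeRule:
    try:
        return _ENZYMES[name.replace(" ", "").lower()]
    except KeyError:
        raise ValueError(
            f"unknown enzyme {name!r}; choose from t1, rnaseA"
        ) from None


@dataclass(frozen=True)
class DigestFragment:
    """One digestion product in parent coordinates (0-based half-open)."""

    parent_id: str
    start: int
    end: int
    sequence: ModifiedSequence
    missed_cleavages: int = 0

    def covers(self, index: int) -> bool:
        return self.start <= index < self.end


def cut_sites(seq: ModifiedSequence, enzyme: EnzymeRule, registry: Registry) -> list[int]:
    """Indices i such that the bond between residues i and i+1 is cleaved."""
    return [
        i
        for i in range(len(seq) - 1)
        if enzyme.is_site(registry.get(seq.residues[i]))
    ]


def digest(
    seq: ModifiedSequence,
    enzyme: EnzymeRule,
    registry: Registry | None = None,
    missed_cleavages: int = 0,
    phosphate_form: str = "linear",
    parent_id: str = "",
) -> list[DigestFragment]:
    """Digest ``seq``, returning fragments in 5'->3' order.

    Zero-missed-cleavage fragments tile the parent exactly; with
    ``missed_cleavages=k`` every union of up to k+1 adjacent fragments is
    additionally emitted, ordered by (start, end).
    """
    registry = registry or default_registry()
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if phosphate_form not in ("linear", "cyclic"):
        raise ValueError(f"phosphate_form must be linear or cyclic, got {phosphate_form!r}")
    for code in seq.residues:
        registry.get(code)  # raises RegistryError on unregistered residues

    product_3p = "p" if phosphate_form == "linear" else ">p"
    sites = cut_sites(seq, enzyme, registry)
    boundaries = [0] + [i + 1 for i in sites] + [len(seq)]

    fragments: list[DigestFragment] = []
    n_base = len(boundaries) - 1
    for i in range(n_base):
        max_j = min(n_base, i + 1 + missed_cleavages)
        for j in range(i + 1, max_j + 1):
            start, end = boundaries[i], boundaries[j]
            five = seq.five_prime if start == 0 else "OH"
            three = seq.three_prime if end == len(seq) else product_3p
            fragments.append(
                DigestFragment(
                    parent_id=parent_id,
                    start=start,
                    end=end,
                    sequence=seq.slice(start, end, five, three),
                    missed_cleavages=j - i - 1,
                )
            )
    fragments.sort(key=lambda f: (f.start, f.end))
    return fragments


def fragment_for_position(
    record: TRNARecord,
    enzyme: EnzymeRule,
    standard_position: int,
    registry: Registry | None = None,
    phosphate_form: str = "linear",
) -> DigestFragment:
    """The unique zero-missed-cleavage fragment covering a standard position."""
    index = record.index_of(standard_position)  # KeyError if absent
    fragments = digest(
        record.sequence,
        enzyme,
        registry=registry,
        phosphate_form=phosphate_form,
        parent_id=record.id,
    )
    for fragment in fragments:
        if fragment.covers(index):
            return fragment
    raise AssertionError("zero-missed-cleavage digest must tile the parent")
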