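"""Rule engine for position-37 modification outcomes and substrate checks.

Encodes the Escherichia coli biosynthesis logic for the N6-threonyl-
carbamoyladenosine (t6A) family at tRNA position 37:

* t6A is installed by the four-enzyme machinery on tRNAs decoding
  ANN codons (anticodon position 36 = U);
* TrmO N6-methylates t6A to m6t6A on tRNAs carrying the anticodon-arm
  determinants C31-G39, G34 and G35;
* TcdA dehydrates t6A to cyclic t6A (ct6A) on everything else (and on
  TrmO substrates when TrmO is absent); ct6A partially hydrolyzes back
  to t6A during sample handling;
* TrmO acts on t6A only — never on A, ct6A or m6t6A.

These determinant rules are bacterial; the engine refuses to issue
substrate verdicts for records flagged non-bacterial because the human
enzyme recognizes different elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .registry import Registry, default_registry
from .sequence import TRNARecord

__all__ = [
    "Genotype",
    "Position37State",
    "DeterminantReport",
    "is_t6A_eligible",
    "is_trmO_substrate",
    "predict_position37_state",
    "methylation_order_constraint",
]

POSITION37_STATES = ("A", "t6A", "m6t6A", "ct6A")


@dataclass(frozen=True)
class Genotype:
    """Gene-presence flags of a strain.

    ``t6a_machinery`` collapses the four essential synthesis genes
    (tsaB/tsaC/tsaD/tsaE) into one flag. csdA/csdE activate cyclization
    efficiency but do not gate the outcome; they are recorded only.
    """

    trmO: bool = True
    tcdA: bool = True
    t6a_machinery: bool = True
    csdA: bool = True
    csdE: bool = True

    def label(self) -> str:
        missing = [
            name
            for name, present in (
                ("trmO", self.trmO),
                ("tcdA", self.tcdA),
                ("t6a", self.t6a_machinery),
                ("csdA", self.csdA),
                ("csdE", self.csdE),
            )
            if not present
        ]
        return "wild-type" if not missing else "Δ" + "/Δ".join(missing)


@dataclass(frozen=True)
class Position37State:
    """Predicted modification state at position 37."""

    primary: str
    minor: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.primary not in POSITION37_STATES:
            raise ValueError(f"unknown position-37 state {self.primary!r}")


@dataclass(frozen=True)
class DeterminantReport:
    """Per-determinant pass/fail for methyltransferase substrate checks."""

    checks: dict[str, bool] = field(default_factory=dict)
    notes: tuple[str, ...] = ()

    @property
    def verdict(self) -> bool:
        return all(self.checks.values())

    def __bool__(self) -> bool:
        return self.verdict

    def failed(self) -> list[str]:
        return [name for name, passed in self.checks.items() if not passed]


def _canonical_at(
    record: TRNARecord, position: int, registry: Registry
) -> str:
    """Canonical base identity (A/C/G/U) at a standard position."""
    return registry.canonical_parent(record.residue_at(position))


def is_t6A_eligible(record: TRNARecord, registry: Registry | None = None) -> bool:
    """True iff the anticodon decodes ANN codons (position 36 is a U)."""
    registry = registry or default_registry()
    record.anticodon()  # raises if anticodon positions are undefined
    return _canonical_at(record, record.anticodon_positions[2], registry) == "U"


def is_trmO_substrate(
    record: TRNARecord, registry: Registry | None = None
) -> DeterminantReport:
    """Determinant report for N6-methylation of t6A37 in bacteria.

    Verdict is the conjunction: U36 (t6A-eligible) and the C31-G39
    anticodon-stem base pair and G34 and G35.
    """
    registry = registry or default_registry()
    if not record.bacterial:
        raise ValueError(
            f"record {record.id!r} is flagged non-bacterial: the determinant "
            "rules encoded here are for the bacterial enzyme only and the "
            "human enzyme recognizes different elements"
        )
    positions = (31, 34, 35, 36, 39)
    missing = [p for p in positions if not record.has_position(p)]
    if missing:
        raise KeyError(
            f"positions {missing} unresolvable in record {record.id!r}"
        )
    at = {p: _canonical_at(record, p, registry) for p in positions}
    checks = {
        "U36": at[36] == "U",
        "C31-G39": at[31] == "C" and at[39] == "G",
        "G34": at[34] == "G",
        "G35": at[35] == "G",
    }
    notes = ()
    if all(checks.values()):
        notes = (
            "full anticodon stem-loop context may slightly enhance activity",
        )
    return DeterminantReport(checks=checks, notes=notes)


def predict_position37_state(
    record: TRNARecord,
    genotype: Genotype,
    handling_hydrolysis: bool = True,
    registry: Registry | None = None,
) -> Position37State:
    """Predict the position-37 state of a tRNA in a given genotype.

    Rule order: no synthesis machinery (or not an ANN decoder) -> A;
    methyltransferase present and the record passes the determinant
    checks -> m6t6A; otherwise dehydratase present -> ct6A (with a
    qualitative minor-t6A flag for spontaneous hydrolysis during
    handling); otherwise -> t6A.
    """
    registry = registry or default_registry()
    if not record.has_position(37):
        raise KeyError(f"record {record.id!r} has no standard position 37")
    if not genotype.t6a_machinery:
        return Position37State(primary="A", notes=("no t6A synthesis machinery",))
    if not is_t6A_eligible(record, registry):
        return Position37State(
            primary="A", notes=("not an ANN-codon decoder; no t6A installed",)
        )
    if genotype.trmO and is_trmO_substrate(record, registry).verdict:
        return Position37State(primary="m6t6A")
    if genotype.tcdA:
        minor = ("t6A",) if handling_hydrolysis else ()
        notes = (
            ("minor t6A arises from spontaneous ct6A hydrolysis during handling",)
            if handling_hydrolysis
            else ()
        )
        return Position37State(primary="ct6A", minor=minor, notes=notes)
    return Position37State(primary="t6A")


def methylation_order_constraint(state: str) -> bool:
    """Whether a position-37 state is methylatable by the m6t6A writer.

    Only t6A is; the threonylcarbamoyl moiety is required (A fails) and
    neither ct6A nor m6t6A is a substrate.
    """
    if state not in POSITION37_STATES:
        raise ValueError(f"unknown position-37 state {state!r}")
    return state == "t6A"
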