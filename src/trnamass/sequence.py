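"""Modification-annotated RNA sequences and tRNA records.

Sequence text grammar
---------------------
* single characters ``A C G U`` are canonical residues
* a bracketed token ``[code]`` is one modified residue (code must resolve
  in the registry, e.g. ``[t6A]``, ``[m6t6A]``, ``[Y]`` for pseudouridine)
* leading ``p`` = 5'-phosphate; trailing ``p`` = 3'-linear phosphate;
  trailing ``>p`` = 2',3'-cyclic phosphate; otherwise hydroxyl termini

Internally sequences use 0-based half-open sequential coordinates.
Standard tRNA numbering (anticodon 34-36, hypermodified 37) is exposed
only through a record's numbering map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .registry import Registry, RegistryError, default_registry

__all__ = [
    "SequenceParseError",
    "ModifiedSequence",
    "TRNARecord",
    "SequenceVariant",
    "parse_modified_sequence",
    "serialize_sequence",
    "apply_variant",
    "naive_numbering",
    "read_bracket_fasta",
    "write_bracket_fasta",
]

FIVE_PRIME_TERMINI = ("OH", "p")
THREE_PRIME_TERMINI = ("OH", "p", ">p")


class SequenceParseError(ValueError):
    """Malformed bracket-notation sequence text."""


@dataclass(frozen=True)
class ModifiedSequence:
    """Ordered residue codes plus 5'/3' terminal chemistry."""

    residues: tuple[str, ...]
    five_prime: str = "OH"
    three_prime: str = "OH"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceParseError("sequence must contain at least one residue")
        if self.five_prime not in FIVE_PRIME_TERMINI:
            raise ValueError(f"bad 5' terminus {self.five_prime!r}")
        if self.three_prime not in THREE_PRIME_TERMINI:
            raise ValueError(f"bad 3' terminus {self.three_prime!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return serialize_sequence(self)

    def slice(
        self, start: int, end: int, five_prime: str, three_prime: str
    ) -> "ModifiedSequence":
        """Sub-sequence [start, end) with explicit termini."""
        if not (0 <= start < end <= len(self.residues)):
            raise IndexError(f"bad slice [{start}, {end}) of length {len(self)}")
        return ModifiedSequence(self.residues[start:end], five_prime, three_prime)


def parse_modified_sequence(
    text: str, registry: Registry | None = None
) -> ModifiedSequence:
    """Parse bracket-notation text into a :class:`ModifiedSequence`."""
    registry = registry or default_registry()
    if not text:
        raise SequenceParseError("empty sequence string")
    five_prime, three_prime = "OH", "OH"
    body = text
    if body.startswith("p"):
        five_prime = "p"
        body = body[1:]
    if body.endswith(">p"):
        three_prime = ">p"
        body = body[:-2]
    elif body.endswith("p"):
        three_prime = "p"
        body = body[:-1]
    residues: list[str] = []
    i = 0
    while i < len(body):
        char = body[i]
        if char == "[":
            close = body.find("]", i)
            if close == -1:
                raise SequenceParseError(f"dangling bracket at offset {i} in {text!r}")
            code = body[i + 1 : close]
            if not code:
                raise SequenceParseError(f"empty bracket token in {text!r}")
            i = close + 1
        elif char in "ACGU":
            code = char
            i += 1
        else:
            raise SequenceParseError(
                f"unexpected character {char!r} at offset {i} in {text!r}"
            )
        if code not in registry:
            raise SequenceParseError(f"unknown residue code {code!r} in {text!r}")
        residues.append(registry.resolve(code))
    if not residues:
        raise SequenceParseError(f"no residues in {text!r}")
    return ModifiedSequence(tuple(residues), five_prime, three_prime)


def serialize_sequence(seq: ModifiedSequence) -> str:
    """Canonical text form; inverse of :func:`parse_modified_sequence`."""
    parts = ["p"] if seq.five_prime == "p" else []
    for code in seq.residues:
        parts.append(code if code in "ACGU" and len(code) == 1 else f"[{code}]")
    if seq.three_prime == "p":
        parts.append("p")
    elif seq.three_prime == ">p":
        parts.append(">p")
    return "".join(parts)


def naive_numbering(length: int, anticodon_start_index: int | None = None) -> dict[int, int]:
    """Standard-position -> sequential-index map without Sprinzl alignment.

    Without an anticodon anchor, standard position ``n`` is sequential index
    ``n - 1``. With one, positions are offset so that standard 34 falls on
    ``anticodon_start_index``. This is an approximation: true tRNA numbering
    (D-loop gaps, variable loop) requires an explicit map.
    """
    if anticodon_start_index is None:
        offset = -1
    else:
        offset = anticodon_start_index - 34
    return {
        idx - offset: idx
        for idx in range(length)
        if idx - offset > 0
    }


@dataclass(frozen=True)
class TRNARecord:
    """A tRNA with modification annotations and standard numbering."""

    id: str
    sequence: ModifiedSequence
    organism: str = ""
    numbering_map: Mapping[int, int] = field(default_factory=dict)  # standard -> index
    anticodon_positions: tuple[int, int, int] = (34, 35, 36)
    bacterial: bool = True
    numbering_approximate: bool = False

    def __post_init__(self) -> None:
        if not self.numbering_map:
            object.__setattr__(
                self,
                "numbering_map",
                naive_numbering(len(self.sequence)),
            )
            object.__setattr__(self, "numbering_approximate", True)
        values = list(self.numbering_map.values())
        if len(set(values)) != len(values):
            raise ValueError(f"numbering_map of {self.id!r} is not injective")

    def index_of(self, standard_position: int) -> int:
        try:
            return self.numbering_map[standard_position]
        except KeyError:
            raise KeyError(
                f"standard position {standard_position} not present in "
                f"record {self.id!r}"
            ) from None

    def has_position(self, standard_position: int) -> bool:
        return standard_position in self.numbering_map

    def residue_at(self, standard_position: int) -> str:
        return self.sequence.residues[self.index_of(standard_position)]

    def anticodon(self) -> tuple[str, str, str]:
        """Residue codes at standard positions 34-36, in order."""
        p34, p35, p36 = self.anticodon_positions
        missing = [p for p in (p34, p35, p36) if not self.has_position(p)]
        if missing:
            raise KeyError(
                f"anticodon positions {missing} missing from record {self.id!r}"
            )
        return (self.residue_at(p34), self.residue_at(p35), self.residue_at(p36))


@dataclass(frozen=True)
class SequenceVariant:
    """A base record plus standard-position -> residue-code substitutions."""

    base: TRNARecord
    substitutions: Mapping[int, str] = field(default_factory=dict)

    def name(self) -> str:
        """Variant label in the usual ``A31C/U39G`` style."""
        parts = []
        for pos in sorted(self.substitutions):
            parts.append(f"{self.base.residue_at(pos)}{pos}{self.substitutions[pos]}")
        return "/".join(parts) or "wild-type"


def apply_variant(
    variant: SequenceVariant, registry: Registry | None = None
) -> TRNARecord:
    """Return a new record with the listed substitutions applied."""
    registry = registry or default_registry()
    base = variant.base
    residues = list(base.sequence.residues)
    for pos, code in variant.substitutions.items():
        if not base.has_position(pos):
            raise KeyError(
                f"substitution position {pos} not in numbering_map of {base.id!r}"
            )
        if code not in registry:
            raise RegistryError(f"unknown residue code {code!r} in substitution")
        residues[base.index_of(pos)] = registry.resolve(code)
    new_seq = replace(base.sequence, residues=tuple(residues))
    suffix = variant.name()
    new_id = base.id if suffix == "wild-type" else f"{base.id}:{suffix}"
    return replace(base, id=new_id, sequence=new_seq)


# -- bracket-FASTA I/O -----------------------------------------------------


def _parse_header(line: str) -> tuple[str, str, int | None]:
    fields = line[1:].strip().split("|")
    record_id = fields[0] if fields and fields[0] else "unnamed"
    organism = fields[1] if len(fields) > 1 else ""
    anticodon_start = None
    if len(fields) > 2 and fields[2]:
        anticodon_start = int(fields[2])
    return record_id, organism, anticodon_start


def read_bracket_fasta(
    path: str | Path, registry: Registry | None = None
) -> list[TRNARecord]:
    """Read records whose sequence lines use the bracket grammar.

    Header format: ``>id|organism|anticodon_start`` where the optional
    ``anticodon_start`` is the 1-based sequential position of standard
    position 34.
    """
    registry = registry or default_registry()
    records: list[TRNARecord] = []
    header: tuple[str, str, int | None] | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        record_id, organism, anticodon_start = header
        text = "".join(chunks)
        seq = parse_modified_sequence(text, registry)
        if anticodon_start is not None:
            numbering = naive_numbering(len(seq), anticodon_start - 1)
            approximate = False
        else:
            numbering = naive_numbering(len(seq))
            approximate = True
        records.append(
            TRNARecord(
                id=record_id,
                organism=organism,
                sequence=seq,
                numbering_map=numbering,
                numbering_approximate=approximate,
            )
        )

    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = _parse_header(line)
                chunks = []
            else:
                if header is None:
                    raise SequenceParseError("sequence line before first header")
                chunks.append(line)
        flush()
    return records


def write_bracket_fasta(records: Iterable[TRNARecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for record in records:
            anticodon_start = ""
            if record.has_position(34):
                anticodon_start = str(record.index_of(34) + 1)
            handle.write(f">{record.id}|{record.organism}|{anticodon_start}\n")
            handle.write(serialize_sequence(record.sequence) + "\n")
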