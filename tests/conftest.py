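from __future__ import annotations

import pytest

from trnamass import ModifiedSequence, TRNARecord, default_registry
from trnamass.sequence import naive_numbering


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_record(
    record_id: str,
    assignments: dict[int, str],
    length: int = 60,
    default: str = "A",
    bacterial: bool = True,
    organism: str = "synthetic",
) -> TRNARecord:
    """Synthetic record with naive numbering (standard n = index n-1)."""
    letters = [default] * length
    numbering = naive_numbering(length)
    for position, code in assignments.items():
        letters[numbering[position]] = code
    return TRNARecord(
        id=record_id,
        organism=organism,
        sequence=ModifiedSequence(tuple(letters)),
        numbering_map=numbering,
        bacterial=bacterial,
    )


THR3_ARM = {31: "C", 34: "G", 35: "G", 36: "U", 37: "t6A", 38: "A", 39: "G"}
THR4_ARM = {31: "A", 34: "U", 35: "G", 36: "U", 37: "t6A", 38: "A", 39: "U"}
SER_ARM = {
    31: "A",
    34: "G",
    35: "C",
    36: "U",
    37: "t6A",
    38: "A",
    39: "Y",
    40: "C",
    41: "C",
    42: "A",
    43: "U",
    44: "Um",
    45: "G",
}


@pytest.fixture
def thr3_record() -> TRNARecord:
    """ACY-decoder-like record carrying every methyltransferase determinant."""
    return make_record("Thr3-like", THR3_ARM)


@pytest.fixture
def thr4_record() -> TRNARecord:
    """Isoacceptor-like record failing the C31-G39 pair and G34."""
    return make_record("Thr4-like", THR4_ARM)


@pytest.fixture
def ser_record() -> TRNARecord:
    """Human-tRNA-Ser-like record (GCU anticodon, non-bacterial)."""
    return make_record("Ser-like", SER_ARM, bacterial=False, organism="human")
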