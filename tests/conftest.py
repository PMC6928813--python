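import pytest

from cpbarcode.seqio import Alignment, SequenceRecord, parse_species_label


def make_record(identifier: str, residues: str) -> SequenceRecord:
    species, individual = parse_species_label(identifier)
    return SequenceRecord(identifier, species, individual, residues)


def make_alignment(rows, ids=None) -> Alignment:
    if ids is None:
        ids = [f"sp{i + 1:02d}" for i in range(len(rows))]
    return Alignment([make_record(i, r) for i, r in zip(ids, rows)])


@pytest.fixture
def toy_alignment():
    """Columns read top-down: AAAA, AATT, ACGA, AAAT.

    Three variable columns, of which exactly one (A/A/T/T) is
    parsimony-informative.
    """
    return make_alignment(["AAAA", "AACA", "ATGA", "ATAT"])
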