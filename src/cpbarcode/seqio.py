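"""Sequence and tree I/O plus species-label parsing.

All coordinates are 0-based half-open internally.  GenBank's 1-based
inclusive feature locations are converted at the parsing boundary and
nowhere else.  Ambiguity codes are retained in residues; downstream
statistics treat them as missing data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO as _BioSeqIO

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted in residue strings (gap included).
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

#: The four unambiguous bases.
CANONICAL_BASES = set("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


class FastaFormatError(ValueError):
    """Raised when a FASTA file is malformed."""


class AlignmentError(ValueError):
    """Raised when rows of an alignment violate the equal-length invariant."""


def reverse_complement(residues: str) -> str:
    """Reverse-complement of an IUPAC DNA string; gaps map to themselves."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One DNA sequence with species/individual labels parsed from its id.

    Parameters
    ----------
    identifier : str
        Full sequence identifier as read from the file.
    species : str
        Species label, e.g. ``"Quercus_rubra"``.
    individual : str
        Individual token within the species; ``"1"`` when absent.
    residues : str
        Upper-case IUPAC DNA, optionally gapped.
    """

    identifier: str
    species: str
    individual: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.identifier!r} has empty residues")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.identifier!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )
        if not self.species:
            raise ValueError(f"record {self.identifier!r} has empty species label")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """Equal-length gapped sequence matrix; the substrate of every statistic."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise AlignmentError("alignment requires at least one record")
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            offenders = ", ".join(
                f"{r.identifier}({len(r)})" for r in records
            )
            raise AlignmentError(f"unequal row lengths: {offenders}")
        self.records = records

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_cols(self) -> int:
        return len(self.records[0])

    @property
    def identifiers(self) -> list[str]:
        return [r.identifier for r in self.records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def slice_columns(self, start: int, end: int) -> "Alignment":
        """Column slice ``[start, end)`` as a new alignment."""
        if not (0 <= start < end <= self.n_cols):
            raise IndexError(f"column slice [{start}, {end}) out of bounds")
        return Alignment(
            [
                SequenceRecord(r.identifier, r.species, r.individual,
                               r.residues[start:end])
                for r in self.records
            ]
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Alignment(n_rows={self.n_rows}, n_cols={self.n_cols})"


@dataclass
class Feature:
    """An annotated feature on a genome, 0-based half-open."""

    name: str
    type: str  # gene | tRNA | rRNA | intergenic
    start: int
    end: int
    strand: str  # '+' | '-'

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"feature {self.name}: bad interval "
                             f"[{self.start}, {self.end})")


@dataclass
class AnnotatedGenome:
    """A genome sequence together with its feature table."""

    record: SequenceRecord
    features: list[Feature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        n = len(self.record)
        for f in self.features:
            if f.end > n:
                raise ValueError(
                    f"feature {f.name} end {f.end} exceeds genome length {n}"
                )

    def feature_by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def parse_species_label(identifier: str, delimiter: str = "|") -> tuple[str, str]:
    """Split an identifier into (species, individual).

    Default convention is ``Genus_species|individual``; when the delimiter
    is absent the whole identifier is the species and the individual
    defaults to ``"1"``.
    """
    if not identifier:
        raise ValueError("empty sequence identifier")
    if delimiter in identifier:
        species, _, individual = identifier.partition(delimiter)
    else:
        species, individual = identifier, "1"
    if not species:
        raise ValueError(f"identifier {identifier!r} has empty species part")
    return species, individual


def _record_from_entry(identifier: str, residues: str,
                       delimiter: str) -> SequenceRecord:
    species, individual = parse_species_label(identifier, delimiter)
    return SequenceRecord(identifier, species, individual, residues.upper())


def read_fasta(path: str | Path, delimiter: str = "|") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved and residues are upper-cased.  Malformed content
    raises :class:`FastaFormatError` naming the offending line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    # Line-level scan so errors can name a line number; parsing itself is
    # then delegated per entry.
    identifier: str | None = None
    chunks: list[str] = []
    header_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if identifier is not None:
                    records.append(_flush_entry(identifier, chunks,
                                                header_line, delimiter))
                identifier = line[1:].split()[0] if len(line) > 1 else ""
                if not identifier:
                    raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if identifier is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before any header"
                    )
                bad = set(line.upper()) - IUPAC_DNA
                if bad:
                    raise FastaFormatError(
                        f"{path}:{lineno}: illegal characters {sorted(bad)}"
                    )
                chunks.append(line)
    if identifier is not None:
        records.append(_flush_entry(identifier, chunks, header_line, delimiter))
    if not records:
        logger.warning("FASTA file %s contains no sequences", path)
    return records


def _flush_entry(identifier: str, chunks: list[str], header_line: int,
                 delimiter: str) -> SequenceRecord:
    residues = "".join(chunks)
    if not residues:
        raise FastaFormatError(
            f"entry {identifier!r} (line {header_line}) has no sequence"
        )
    return _record_from_entry(identifier, residues, delimiter)


def read_alignment(path: str | Path, delimiter: str = "|") -> Alignment:
    """Read an aligned FASTA file; rows must be equal length, >= 2 entries."""
    records = read_fasta(path, delimiter=delimiter)
    if len(records) < 2:
        raise AlignmentError(f"{path}: an alignment needs at least 2 entries")
    return Alignment(records)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records as FASTA; gaps are preserved verbatim."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


_GENE_NAME_QUALIFIERS = ("gene", "standard_name", "product", "note")


def read_genbank(path: str | Path, delimiter: str = "|") -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    Feature locations are converted from GenBank 1-based inclusive to
    internal 0-based half-open.  ``join()``/``complement()`` locations are
    resolved to their outermost span.  Unparseable features are skipped
    with a warning; a missing ORIGIN sequence is an error.
    """
    path = Path(path)
    seqrec = next(_BioSeqIO.parse(str(path), "genbank"), None)
    if seqrec is None:
        raise FastaFormatError(f"{path}: no GenBank record found")
    residues = str(seqrec.seq).upper()
    if not residues or set(residues) == {"N"}:
        raise FastaFormatError(f"{path}: GenBank record has no ORIGIN sequence")
    record = _record_from_entry(seqrec.id, residues, delimiter)

    circular = seqrec.annotations.get("topology", "circular") == "circular"
    features: list[Feature] = []
    seen: dict[tuple[str, str], int] = {}
    for feat in seqrec.features:
        if feat.type not in ("gene", "tRNA", "rRNA", "CDS"):
            continue
        name = None
        for q in _GENE_NAME_QUALIFIERS:
            if q in feat.qualifiers:
                name = feat.qualifiers[q][0]
                break
        if name is None:
            logger.warning("%s: unnamed %s feature skipped", path, feat.type)
            continue
        try:
            # Biopython locations are already 0-based half-open; outermost
            # span of compound locations.
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
        except (TypeError, ValueError) as exc:
            logger.warning("%s: feature %s skipped (%s)", path, name, exc)
            continue
        ftype = _classify_feature(feat.type, name)
        key = (name, ftype)
        if key in seen:
            seen[key] += 1
            name = f"{name}_{seen[key]}"
        else:
            seen[key] = 1
        features.append(Feature(name, ftype, start, end, strand))
    return AnnotatedGenome(record, features, circular)


def _classify_feature(gb_type: str, name: str) -> str:
    if gb_type == "tRNA" or name.lower().startswith("trn"):
        return "tRNA"
    if gb_type == "rRNA" or name.lower().startswith("rrn"):
        return "rRNA"
    return "gene"


# -- newick ----------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as newick with branch lengths to 6 significant digits."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a newick tree, preserving underscores in labels."""
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
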