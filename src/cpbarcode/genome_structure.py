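"""Quadripartite plastome partitioning and per-genome summaries.

Chloroplast genomes are circular and carry two identical inverted repeats
(IRa/IRb) separating a large and a small single-copy region (LSC/SSC).
The detector finds the maximal pair of reverse-complementary exact
repeats by seed-and-extend over shared k-mers between the sequence and
its reverse complement, handling origin wrap-around, then labels the
longer inter-repeat segment LSC and the shorter SSC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .seqio import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class NoQuadripartiteStructureError(ValueError):
    """No reverse-complementary repeat pair of the required length exists."""


class AmbiguousRepeatError(ValueError):
    """More than one maximal repeat pair of equal length was found."""


@dataclass(frozen=True)
class GenomePartition:
    """LSC/IRb/SSC/IRa intervals, 0-based half-open on the circular genome.

    On a canonical genome the intervals tile ``[0, total)`` in the order
    LSC, IRb, SSC, IRa.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    total: int

    @property
    def lsc_len(self) -> int:
        return _circ_len(self.lsc, self.total)

    @property
    def ir_len(self) -> int:
        return _circ_len(self.irb, self.total)

    @property
    def ssc_len(self) -> int:
        return _circ_len(self.ssc, self.total)

    def validate(self, residues: str | None = None) -> None:
        """Check tiling, equal IR lengths, LSC > SSC, and (optionally) that
        the IR copies are exact reverse complements."""
        if self.lsc_len + self.ssc_len + 2 * self.ir_len != self.total:
            raise ValueError("partition does not tile the genome")
        if _circ_len(self.ira, self.total) != self.ir_len:
            raise ValueError("IR copies differ in length")
        if self.lsc_len <= self.ssc_len:
            raise ValueError("LSC must be longer than SSC")
        if residues is not None:
            irb = _circ_slice(residues, self.irb)
            ira = _circ_slice(residues, self.ira)
            if reverse_complement(irb) != ira:
                raise ValueError("IR copies are not reverse complements")


@dataclass
class GenomeSummary:
    """Per-genome length and GC breakdown (one IR copy reported)."""

    species: str
    lsc_len: int
    ir_len: int
    ssc_len: int
    total_len: int
    gc_total: float
    gc_lsc: float
    gc_ssc: float
    gc_ir: float


def _circ_len(interval: tuple[int, int], total: int) -> int:
    # intervals are stored as (start, start + length); end may exceed
    # ``total`` when the interval wraps the origin
    start, end = interval
    return end - start


def _circ_slice(residues: str, interval: tuple[int, int]) -> str:
    """Slice a circular sequence; ``end`` may exceed ``len`` to wrap."""
    start, end = interval
    n = len(residues)
    if end <= n:
        return residues[start:end]
    return residues[start:] + residues[:end - n]


def gc_content(residues: str) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes and gaps are excluded entirely."""
    gc = residues.count("G") + residues.count("C")
    at = residues.count("A") + residues.count("T")
    denom = gc + at
    if denom == 0:
        raise ValueError("no unambiguous bases: GC content undefined")
    return gc / denom


def detect_inverted_repeats(
    genome: SequenceRecord,
    min_ir_len: int = 10_000,
    k: int = 25,
) -> GenomePartition:
    """Find the IR pair and partition the circular genome.

    Seeds are shared ``k``-mers between the sequence and its reverse
    complement; each seed is extended to a maximal exact
    reverse-complementary match.  Origin wrap-around is handled by
    scanning the doubled sequence.  The longer inter-repeat segment is
    labelled LSC, the shorter SSC.

    Raises
    ------
    NoQuadripartiteStructureError
        If no repeat pair of length >= ``min_ir_len`` exists.
    AmbiguousRepeatError
        If two distinct non-overlapping maximal pairs tie in length.
    """
    seq = genome.residues
    n = len(seq)
    if n < 2 * min_ir_len:
        raise NoQuadripartiteStructureError(
            f"genome length {n} < 2 * min_ir_len ({min_ir_len})"
        )
    doubled = seq + seq
    max_len = n // 2  # an IR copy cannot exceed half the circle

    # k-mer index of the doubled sequence.
    index: dict[str, list[int]] = {}
    for i in range(2 * n - k + 1):
        index.setdefault(doubled[i:i + k], []).append(i)

    # A seed pairs position i (first copy, read forward) with position q
    # (second copy) such that doubled[i:i+k] == revcomp(doubled[q:q+k]).
    # Along a maximal extension the quantity i + q + m - 1 (m = current
    # match length) is invariant, so one extension per diagonal suffices.
    diagonals: dict[int, tuple[int, int]] = {}
    rc = reverse_complement(seq)
    for j in range(n - k + 1):
        kmer = rc[j:j + k]
        # rc[j:j+k] corresponds to seq[n-j-k : n-j] reverse-complemented
        q0 = n - j - k
        for i in index.get(kmer, ()):
            if i >= n:
                continue
            for q in (q0, q0 + n):  # second copy may sit past the origin
                if q <= i:
                    continue
                diag = i + q + k - 1
                if diag not in diagonals or i < diagonals[diag][0]:
                    diagonals[diag] = (i, q)

    # Extend with seeds shifted one genome copy to the right in a 4x
    # concatenation: a match that wraps the origin can then grow in both
    # directions without hitting a string boundary (match length is
    # capped at n//2, so the flanking copies are never exhausted).
    extended = doubled + doubled
    candidates: dict[tuple[tuple[int, int], tuple[int, int]], int] = {}
    for i, q in diagonals.values():
        first, second, m = _extend(extended, i + n, q + n, k, max_len)
        if m < min_ir_len:
            continue
        if second[0] < first[1]:  # overlapping copies: not a true IR pair
            continue
        key = _normalize_pair(first, second, n)
        candidates[key] = max(candidates.get(key, 0), m)

    if not candidates:
        raise NoQuadripartiteStructureError(
            f"no reverse-complementary repeat pair >= {min_ir_len} bp: "
            "no quadripartite structure"
        )
    best_len = max(candidates.values())
    best = [pair for pair, m in candidates.items() if m == best_len]
    if len(best) > 1:
        raise AmbiguousRepeatError(
            f"{len(best)} maximal repeat pairs of length {best_len}: {best}"
        )
    (first, second) = best[0]
    return _partition_from_pair(first, second, n)


def _extend(doubled: str, i: int, q: int, k: int,
            max_len: int) -> tuple[tuple[int, int], tuple[int, int], int]:
    """Extend a seed to the maximal exact reverse-complementary match.

    Invariant: ``doubled[i:i+m] == revcomp(doubled[q:q+m])``.
    """
    n2 = len(doubled)
    m = k
    # right of first copy pairs with left of second copy
    while (m < max_len and i + m < q
           and doubled[i + m] == _COMP.get(doubled[q - 1], "?")):
        q -= 1
        m += 1
    # left of first copy pairs with right of second copy
    while (m < max_len and i > 0 and q + m < n2
           and doubled[i - 1] == _COMP.get(doubled[q + m], "?")):
        i -= 1
        m += 1
    return (i, i + m), (q, q + m), m


def _normalize_pair(first: tuple[int, int], second: tuple[int, int],
                    n: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Canonical representation of a repeat pair on the circle."""
    a = (first[0] % n, first[0] % n + (first[1] - first[0]))
    b = (second[0] % n, second[0] % n + (second[1] - second[0]))
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def _partition_from_pair(first: tuple[int, int], second: tuple[int, int],
                         n: int) -> GenomePartition:
    """Build a GenomePartition from two repeat copy intervals (mod n)."""
    s1, e1 = first[0] % n, first[1]
    s2, e2 = second[0] % n, second[1]
    ir_len = e1 - first[0]
    # Gap segments between the copies, walking the circle forward.
    gap_a_len = (s2 - e1) % n   # after copy1, before copy2
    gap_b_len = (s1 - e2) % n   # after copy2, before copy1
    if gap_a_len == 0 or gap_b_len == 0:
        raise NoQuadripartiteStructureError(
            "repeat copies are adjacent; no single-copy regions"
        )
    gap_a = (e1 % n, e1 % n + gap_a_len)
    gap_b = (e2 % n, e2 % n + gap_b_len)
    if gap_a_len == gap_b_len:
        raise AmbiguousRepeatError(
            "inter-repeat segments have equal length; LSC/SSC undecidable"
        )
    if gap_a_len > gap_b_len:
        # forward order: copy1, LSC, copy2, SSC -> IRb is copy2
        lsc, ssc = gap_a, gap_b
        irb = (s2, s2 + ir_len)
        ira = (s1, s1 + ir_len)
    else:
        lsc, ssc = gap_b, gap_a
        irb = (s1, s1 + ir_len)
        ira = (s2, s2 + ir_len)
    return GenomePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, total=n)


def canonicalize_orientation(
    genome: SequenceRecord, partition: GenomePartition
) -> tuple[SequenceRecord, GenomePartition]:
    """Rotate (and strand-flip if needed) to the canonical representation.

    The canonical genome starts at LSC position 0 with region order
    LSC, IRb, SSC, IRa.  Both strands admit such a rotation; the
    lexicographically smaller of the two canonical strings is chosen so
    that a genome and its reverse complement canonicalize identically.
    """
    seq = genome.residues
    fwd = _rotate_to_lsc(seq, partition)
    # reverse complement swaps the roles of the two IR copies
    rc_seq = reverse_complement(seq)
    n = len(seq)
    rc_partition = _reverse_partition(partition, n)
    rev = _rotate_to_lsc(rc_seq, rc_partition)
    canonical = min(fwd, rev)
    lsc_len = partition.lsc_len
    ir_len = partition.ir_len
    ssc_len = partition.ssc_len
    new_partition = GenomePartition(
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        ira=(lsc_len + ir_len + ssc_len, n),
        total=n,
    )
    new_record = SequenceRecord(
        genome.identifier, genome.species, genome.individual, canonical
    )
    new_partition.validate(canonical)
    return new_record, new_partition


def _rotate_to_lsc(seq: str, partition: GenomePartition) -> str:
    start = partition.lsc[0] % len(seq)
    return seq[start:] + seq[:start]


def _reverse_partition(p: GenomePartition, n: int) -> GenomePartition:
    """Partition of the reverse-complemented sequence."""
    def flip(interval: tuple[int, int]) -> tuple[int, int]:
        start, end = interval[0] % n, interval[1]
        length = end - interval[0]
        new_start = (n - (start + length)) % n
        return (new_start, new_start + length)

    return GenomePartition(
        lsc=flip(p.lsc), irb=flip(p.ira), ssc=flip(p.ssc), ira=flip(p.irb),
        total=n,
    )


def summarize_genome(genome: SequenceRecord,
                     partition: GenomePartition) -> GenomeSummary:
    """Length and GC summary for a canonically partitioned genome."""
    seq = genome.residues
    lsc = _circ_slice(seq, partition.lsc)
    irb = _circ_slice(seq, partition.irb)
    ssc = _circ_slice(seq, partition.ssc)
    return GenomeSummary(
        species=genome.species,
        lsc_len=partition.lsc_len,
        ir_len=partition.ir_len,
        ssc_len=partition.ssc_len,
        total_len=partition.total,
        gc_total=gc_content(seq),
        gc_lsc=gc_content(lsc),
        gc_ssc=gc_content(ssc),
        gc_ir=gc_content(irb),
    )
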