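"""Marker extraction/concatenation and species-discrimination scoring.

Two distance-based criteria are provided.  ``unique_haplotype`` (the
default, appropriate when each species contributes a single sequence)
scores a species as identified iff its minimum distance to every
heterospecific sequence is strictly greater than zero — sharing a
haplotype with another species is the failure condition.
``near_neighbour`` (for multi-individual sampling) scores an individual
as identified iff its nearest non-self neighbour is conspecific; ties
that include any heterospecific sequence count as failure, and
singleton species necessarily fail under this criterion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np

from . import divergence
from .seqio import Alignment, AnnotatedGenome, SequenceRecord

logger = logging.getLogger(__name__)

Criterion = Literal["unique_haplotype", "near_neighbour"]


@dataclass
class DiscriminationReport:
    """Per-species identification success and the overall percentage."""

    criterion: str
    per_species: dict[str, bool]
    excluded_species: list[str] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.per_species)

    @property
    def n_successes(self) -> int:
        return sum(self.per_species.values())

    @property
    def success_percent(self) -> float:
        """Percentage of species identified, rounded half-up to 2 decimals."""
        raw = Decimal(100 * self.n_successes) / Decimal(self.n_species)
        return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def extract_marker_columns(alignment: Alignment, start_col: int,
                           end_col: int) -> Alignment:
    """Column-slice marker extraction (exact: rows stay aligned)."""
    return alignment.slice_columns(start_col, end_col)


def extract_marker_feature(
    genomes: Sequence[AnnotatedGenome], feature_name: str
) -> list[SequenceRecord]:
    """Per-genome unaligned subsequences of a named feature.

    Genomes lacking the feature are dropped with a warning.  The
    returned records are unaligned; align them externally before
    computing statistics.
    """
    out = []
    for g in genomes:
        try:
            feat = g.feature_by_name(feature_name)
        except KeyError:
            logger.warning("genome %s lacks feature %s; dropped",
                           g.record.identifier, feature_name)
            continue
        residues = g.record.residues[feat.start:feat.end]
        if feat.strand == "-":
            from .seqio import reverse_complement
            residues = reverse_complement(residues)
        out.append(SequenceRecord(
            g.record.identifier, g.record.species, g.record.individual,
            residues,
        ))
    return out


def concatenate_markers(markers: Sequence[Alignment]) -> Alignment:
    """Column-wise concatenation of marker alignments.

    Rows are matched by identifier; every marker must cover exactly the
    same label set.
    """
    if not markers:
        raise ValueError("no marker alignments supplied")
    base_labels = markers[0].identifiers
    base_set = set(base_labels)
    for m in markers[1:]:
        other = set(m.identifiers)
        if other != base_set:
            missing = sorted(base_set.symmetric_difference(other))
            raise ValueError(f"marker label sets differ; unmatched: {missing}")
    by_id = [{r.identifier: r for r in m.records} for m in markers]
    records = []
    for rec in markers[0].records:
        residues = "".join(d[rec.identifier].residues for d in by_id)
        records.append(SequenceRecord(
            rec.identifier, rec.species, rec.individual, residues))
    return Alignment(records)


def discriminate(
    alignment: Alignment,
    criterion: Criterion = "unique_haplotype",
    model: divergence.Model = "k2p",
    dist: divergence.DistanceMatrix | None = None,
) -> DiscriminationReport:
    """Distance-based species-discrimination scoring.

    Species whose every comparison to some other sequence is undefined
    (distance saturation or no shared columns) are flagged and excluded
    from the denominator.
    """
    species = alignment.species
    if len(set(species)) < 2:
        raise ValueError("discrimination requires >= 2 species")
    if dist is None:
        dist = divergence.distance_matrix(alignment, model=model)
    values, defined = dist.values, dist.defined_mask
    n = len(species)
    sp_arr = np.array(species)

    # a sequence with any undefined comparison poisons its species' score
    undefined_rows = {
        i for i in range(n) for j in range(n)
        if i != j and not defined[i, j]
    }
    excluded = sorted({species[i] for i in undefined_rows})
    per_species: dict[str, bool] = {}
    if criterion == "unique_haplotype":
        for sp in dict.fromkeys(species):  # preserve first-seen order
            if sp in excluded:
                continue
            own = np.flatnonzero(sp_arr == sp)
            hetero = np.flatnonzero(sp_arr != sp)
            min_d = values[np.ix_(own, hetero)].min()
            per_species[sp] = bool(min_d > 0.0)
    elif criterion == "near_neighbour":
        indiv_ok: dict[str, list[bool]] = {}
        for i in range(n):
            sp = species[i]
            if sp in excluded:
                continue
            others = [j for j in range(n) if j != i]
            d_others = values[i, others]
            d_min = d_others.min()
            nearest = [others[k] for k, d in enumerate(d_others)
                       if d == d_min]
            # singleton species fail: their nearest neighbour cannot be
            # conspecific; heterospecific ties also fail
            ok = all(species[j] == sp for j in nearest)
            indiv_ok.setdefault(sp, []).append(ok)
        for sp in dict.fromkeys(species):
            if sp in excluded:
                continue
            per_species[sp] = all(indiv_ok[sp])
    else:
        raise ValueError(f"unknown criterion: {criterion}")
    if excluded:
        logger.warning("species with undefined distances excluded: %s",
                       excluded)
    if not per_species:
        raise ValueError("every species had undefined distances")
    return DiscriminationReport(
        criterion=criterion,
        per_species=per_species,
        excluded_species=excluded,
    )


@dataclass
class MarkerReport:
    """One row of a marker-comparison table."""

    marker: str
    length: int
    n_variable: int
    percent_variable: float
    n_informative: int
    percent_informative: float
    success_percent: float


def marker_report(
    name: str,
    alignment: Alignment,
    criterion: Criterion = "unique_haplotype",
    model: divergence.Model = "k2p",
) -> MarkerReport:
    """Variability and discrimination summary for one marker alignment."""
    cls = divergence.classify_sites(alignment)
    rep = discriminate(alignment, criterion=criterion, model=model)
    return MarkerReport(
        marker=name,
        length=alignment.n_cols,
        n_variable=cls.n_variable,
        percent_variable=cls.percent_variable,
        n_informative=cls.n_informative,
        percent_informative=cls.percent_informative,
        success_percent=rep.success_percent,
    )
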