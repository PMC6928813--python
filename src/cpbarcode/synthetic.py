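"""Synthetic plastome and alignment generator with known truth.

Sequences evolve along a pure-birth (Yule) species tree under the
Kimura two-parameter substitution process with a transition/transversion
rate ratio ``kappa`` and per-site rate multipliers: a low-rate inverted
repeat, a moderately elevated small single-copy region, and a small
number of planted high-rate "hotspot" windows, emulating the rate
landscape of real chloroplast genomes.  The two IR copies are mirrored
(IRa is the exact reverse complement of the evolved IRb) and every
emitted genome is independently rotated — and possibly strand-flipped —
to exercise canonicalization.

All randomness flows from a single integer seed; identical
(config, seed) produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np

from .genome_structure import GenomePartition
from .seqio import Alignment, SequenceRecord, reverse_complement

_BASES = np.array(list("ACGT"))
_DECODE = {0: "A", 1: "C", 2: "G", 3: "T"}


@dataclass(frozen=True)
class RegionSpec:
    """One rate tile: a half-open interval with a rate multiplier."""

    start: int
    end: int
    multiplier: float
    label: str  # LSC | IRb | SSC | IRa | hotspot | background

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")
        if self.multiplier <= 0:
            raise ValueError("rate multiplier must be positive")


@dataclass
class SimulationConfig:
    """Study-scale defaults at one-tenth genome size.

    The default emulates 24 single-individual species on a ~16 kb
    quadripartite genome (LSC 9000, IR 2600 x 2, SSC 1900) with rate
    multipliers IR 0.2 < LSC 1.0 < SSC 1.5 and four planted 5x hotspots
    (two 800 bp in the LSC, two 400 bp in the SSC), kappa = 2, and a
    tree height of 0.0016 substitutions/site.  On a Yule tree most
    pairwise coalescences sit near the root, so pairwise diversity is
    roughly twice the height — about 0.003, the few-per-mille regime of
    congeneric plastomes.
    """

    n_species: int = 24
    individuals_per_species: int = 1
    length: int = 16_000
    region_map: list[RegionSpec] | None = None
    kappa: float = 2.0
    tree_height: float = 0.0016
    within_species_height: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def resolved_region_map(self) -> list[RegionSpec]:
        if self.region_map is not None:
            _check_tiling(self.region_map)
            return list(self.region_map)
        return [RegionSpec(0, self.length, 1.0, "background")]


@dataclass
class SimulationTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    tree: dendropy.Tree
    species_of: dict[str, str]
    rate_multipliers: np.ndarray
    hotspots: list[tuple[int, int]]
    region_map: list[RegionSpec]
    seed: int
    partition: GenomePartition | None = None
    alignment: Alignment | None = None


def _check_tiling(regions: Sequence[RegionSpec]) -> int:
    regions = sorted(regions, key=lambda r: r.start)
    if regions[0].start != 0:
        raise ValueError("region map must start at 0")
    for a, b in zip(regions, regions[1:]):
        if a.end != b.start:
            raise ValueError(
                f"region map gap/overlap at [{a.end}, {b.start})")
    return regions[-1].end


def plastome_region_map(
    lsc_len: int = 9_000,
    ir_len: int = 2_600,
    ssc_len: int = 1_900,
    lsc_multiplier: float = 1.0,
    ir_multiplier: float = 0.2,
    ssc_multiplier: float = 1.5,
    hotspots: Sequence[tuple[int, int, float]] | None = None,
) -> list[RegionSpec]:
    """Quadripartite rate map: LSC, IRb, SSC, IRa tiles plus hotspots.

    ``hotspots`` are (start, end, multiplier) in genome coordinates and
    must fall inside a single-copy region.  Defaults plant four 800 bp
    5x hotspots, two in the LSC and two in the SSC.
    """
    l1 = lsc_len
    l2 = l1 + ir_len
    l3 = l2 + ssc_len
    total = l3 + ir_len
    if hotspots is None:
        hotspots = [
            (l1 // 4, l1 // 4 + 800, 5.0),
            (3 * l1 // 5, 3 * l1 // 5 + 800, 5.0),
            (l2 + ssc_len // 5, l2 + ssc_len // 5 + 400, 5.0),
            (l2 + 3 * ssc_len // 5, l2 + 3 * ssc_len // 5 + 400, 5.0),
        ]
    base = [
        RegionSpec(0, l1, lsc_multiplier, "LSC"),
        RegionSpec(l1, l2, ir_multiplier, "IRb"),
        RegionSpec(l2, l3, ssc_multiplier, "SSC"),
        RegionSpec(l3, total, ir_multiplier, "IRa"),
    ]
    for hs, he, hm in hotspots:
        host = next((r for r in base if r.start <= hs and he <= r.end), None)
        if host is None or host.label not in ("LSC", "SSC"):
            raise ValueError(
                f"hotspot [{hs}, {he}) must lie within LSC or SSC")
    tiles: list[RegionSpec] = []
    hotspot_tiles = sorted(hotspots)
    for region in base:
        cursor = region.start
        for hs, he, hm in hotspot_tiles:
            if hs >= region.end or he <= region.start:
                continue
            if hs > cursor:
                tiles.append(replace(region, start=cursor, end=hs))
            tiles.append(RegionSpec(hs, he, hm, "hotspot"))
            cursor = he
        if cursor < region.end:
            tiles.append(replace(region, start=cursor))
    return tiles


def multiplier_array(regions: Sequence[RegionSpec]) -> np.ndarray:
    length = _check_tiling(regions)
    mult = np.empty(length)
    for r in regions:
        mult[r.start:r.end] = r.multiplier
    return mult


def _species_label(i: int) -> str:
    return f"sp{i + 1:02d}"


def simulate_species_tree(config: SimulationConfig) -> dendropy.Tree:
    """Pure-birth (Yule) species tree, ultrametric, root-to-tip depth
    rescaled to ``tree_height`` exactly; per-individual star branches of
    ``within_species_height`` are appended when
    ``individuals_per_species > 1``.
    """
    n = config.n_species
    if n < 2:
        raise ValueError("need >= 2 species")
    rng = np.random.default_rng([config.seed, 11])
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node

    # forward-time simulation of speciation events at unit rate per lineage
    t = 0.0
    first = [dendropy.Node(), dendropy.Node()]
    for child in first:
        root.add_child(child)
    births = {id(first[0]): 0.0, id(first[1]): 0.0}
    active = list(first)
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        parent.edge.length = t - births[id(parent)]
        kids = [dendropy.Node(), dendropy.Node()]
        for kid in kids:
            parent.add_child(kid)
            births[id(kid)] = t
            active.append(kid)
    present = t + rng.exponential(1.0 / n)
    for leaf in active:
        leaf.edge.length = present - births[id(leaf)]

    if present > 0 and config.tree_height >= 0:
        scale = config.tree_height / present
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale

    species_leaves = [lf for lf in tree.leaf_node_iter()]
    # deterministic species labelling in leaf order
    for i, leaf in enumerate(species_leaves):
        sp = _species_label(i)
        if config.individuals_per_species == 1:
            leaf.taxon = taxa.new_taxon(label=sp)
        else:
            for k in range(config.individuals_per_species):
                child = dendropy.Node()
                child.taxon = taxa.new_taxon(label=f"{sp}|{k + 1}")
                child.edge.length = config.within_species_height
                leaf.add_child(child)
    return tree


def _k2p_step(seq: np.ndarray, d: np.ndarray, kappa: float,
              rng: np.random.Generator) -> np.ndarray:
    """Evolve encoded bases for per-site branch lengths ``d`` (subs/site)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1  # both transversions together
    u = rng.random(seq.size)
    v = rng.integers(0, 2, size=seq.size).astype(np.uint8)
    out = seq.copy()
    ts = u < p_ts
    tv = ~ts & (u < p_ts + p_tv)
    out[ts] = (seq[ts] + 2) % 4
    out[tv] = (seq[tv] ^ 1) ^ (2 * v[tv])
    return out


def simulate_alignment(
    tree: dendropy.Tree, config: SimulationConfig
) -> tuple[Alignment, SimulationTruth]:
    """Evolve sequences along ``tree`` and return the gap-free truth
    alignment (plus gapped columns when ``indel_rate > 0``).

    Indels are modelled as deletions relative to the ancestral
    coordinate system (a geometric-length run of one row is replaced by
    gaps) so planted intervals keep their coordinates.
    """
    regions = config.resolved_region_map()
    mult = multiplier_array(regions)
    length = mult.size
    rng = np.random.default_rng([config.seed, 23])
    root_seq = rng.integers(0, 4, size=length).astype(np.uint8)

    seqs: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = root_seq
            continue
        parent_seq = seqs[id(node.parent_node)]
        d = (node.edge.length or 0.0) * mult
        seqs[id(node)] = _k2p_step(parent_seq, d, config.kappa, rng)

    records = []
    species_of = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        residues = "".join(_DECODE[b] for b in seqs[id(leaf)])
        if config.indel_rate > 0:
            residues = _apply_deletions(residues, config.indel_rate, rng)
        rec_species = label.split("|")[0]
        records.append(SequenceRecord(label, rec_species,
                                      label.split("|")[1]
                                      if "|" in label else "1", residues))
        species_of[label] = rec_species
    alignment = Alignment(records)
    truth = SimulationTruth(
        tree=tree,
        species_of=species_of,
        rate_multipliers=mult,
        hotspots=[(r.start, r.end) for r in regions if r.label == "hotspot"],
        region_map=regions,
        seed=config.seed,
        alignment=alignment,
    )
    return alignment, truth


def _apply_deletions(residues: str, rate: float,
                     rng: np.random.Generator) -> str:
    n = len(residues)
    n_events = rng.poisson(rate * n)
    chars = list(residues)
    for _ in range(n_events):
        start = int(rng.integers(0, n))
        span = int(rng.geometric(1.0 / 5.0))  # mean length 5
        for i in range(start, min(start + span, n)):
            chars[i] = "-"
    return "".join(chars)


def simulate_plastome_set(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], SimulationTruth]:
    """Simulate unaligned circular quadripartite genomes.

    The core (LSC + IRb + SSC) evolves under the configured rate map;
    IRa is appended as the exact reverse complement of each genome's
    evolved IRb, so the IR multiplier applies once.  One base at each
    single-copy junction is adjusted, if needed, so the planted IR is
    also the *maximal* reverse-complementary repeat (an accidental
    complementary base at a junction would otherwise let exact-match
    extension overshoot the planted boundary).  Each genome is then
    independently rotated by a random offset and strand-flipped with
    probability 1/2.  Truth retains the canonical (unrotated, forward)
    genomes as the homologous alignment.
    """
    if config.indel_rate > 0:
        raise ValueError("indels are not supported for circular genome "
                         "simulation; use simulate_alignment")
    regions = config.region_map if config.region_map is not None \
        else plastome_region_map()
    _check_tiling(regions)
    by_label = {r.label: r for r in regions if r.label in
                ("LSC", "IRb", "SSC", "IRa")}
    for need in ("LSC", "IRb", "SSC", "IRa"):
        if need not in by_label:
            raise ValueError(f"plastome region map lacks {need}")
    irb = by_label["IRb"]
    ira = by_label["IRa"]
    if irb.end - irb.start != ira.end - ira.start:
        raise ValueError("IRb and IRa must have equal length")
    core_regions = [r for r in regions if r.start < ira.start]
    core_len = ira.start
    total = ira.end

    core_config = replace(config, length=core_len,
                          region_map=core_regions)
    tree = simulate_species_tree(core_config)
    core_alignment, truth = simulate_alignment(tree, core_config)

    l1, l2, l3 = by_label["LSC"].end, irb.end, ira.start
    partition = GenomePartition(
        lsc=(0, l1), irb=(l1, l2), ssc=(l2, l3), ira=(l3, total),
        total=total,
    )
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rng = np.random.default_rng([config.seed, 37])
    records = []
    canonical_records = []
    for rec in core_alignment.records:
        core = rec.residues
        genome = list(core + reverse_complement(core[l1:l2]))
        # junction guards: last LSC base vs first LSC base (IR extension
        # wraps the origin there) and last SSC base vs first SSC base
        if genome[l1 - 1] == comp[genome[0]]:
            genome[l1 - 1] = genome[0]
        if genome[l3 - 1] == comp[genome[l2]]:
            genome[l3 - 1] = genome[l2]
        # guards touch only single-copy bases, so the mirror stays exact
        canonical = "".join(genome)
        offset = int(rng.integers(0, total))
        flipped = bool(rng.integers(0, 2))
        emitted = canonical[offset:] + canonical[:offset]
        if flipped:
            emitted = reverse_complement(emitted)
        records.append(SequenceRecord(rec.identifier, rec.species,
                                      rec.individual, emitted))
        canonical_records.append(SequenceRecord(
            rec.identifier, rec.species, rec.individual, canonical))
    mult_full = np.concatenate([
        truth.rate_multipliers,
        truth.rate_multipliers[l1:l2][::-1],
    ])
    truth = SimulationTruth(
        tree=tree,
        species_of=truth.species_of,
        rate_multipliers=mult_full,
        hotspots=truth.hotspots,
        region_map=list(regions),
        seed=config.seed,
        partition=partition,
        alignment=Alignment(canonical_records),
    )
    return records, truth
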