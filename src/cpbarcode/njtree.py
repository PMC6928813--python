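"""Neighbor-joining trees, column-resampling bootstrap, and monophyly.

The joining criterion is the canonical Saitou-Nei Q statistic,
Q(i,j) = (n-2)*d(i,j) - r_i - r_j with r the row sums; ties are broken
lexicographically on the pair of cluster labels (each cluster is
labelled by its smallest leaf label) so the output is deterministic.
Negative branch lengths are retained, not clamped, and flagged.
NJ is exact on additive matrices: leaf-to-leaf path lengths on the
output tree reproduce the input distances.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import dendropy
import numpy as np

from . import divergence
from .seqio import Alignment

logger = logging.getLogger(__name__)


def neighbor_joining(dist: divergence.DistanceMatrix,
                     warn_negative: bool = True) -> dendropy.Tree:
    """Build an unrooted NJ tree (trifurcating root) from a distance matrix.

    Negative branch lengths are retained; they are logged unless
    ``warn_negative`` is off (bootstrap replicates suppress the log).
    Raises ``ValueError`` if any entry is undefined; mask or drop taxa
    first.
    """
    n = dist.n
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    iu = np.triu_indices(n, k=1)
    if not dist.defined_mask[iu].all():
        raise ValueError(
            "distance matrix has undefined entries; remove or mask the "
            "affected taxa before tree building"
        )

    taxa = dendropy.TaxonNamespace(dist.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for label in dist.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    # cluster label = smallest leaf label beneath, for tie-breaking
    cluster_labels = list(dist.labels)
    d = dist.values.astype(float).copy()
    active = list(range(n))

    negative_seen = False
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_key = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_label = tuple(sorted((cluster_labels[i],
                                           cluster_labels[j])))
                key = (q, pair_label)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0 or lj < 0:
            negative_seen = True
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # replace cluster i with the new node; deactivate j
        new_d = np.array([
            0.5 * (d[i, k] + d[j, k] - d[i, j]) for k in range(d.shape[0])
        ])
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        cluster_labels[i] = min(cluster_labels[i], cluster_labels[j])
        active.remove(j)

    # resolve the final three clusters on a trifurcating root
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = length
        if length < 0:
            negative_seen = True
    if negative_seen and warn_negative:
        logger.warning("NJ produced negative branch lengths (retained)")
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def leaf_path_distances(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths keyed by frozenset of the two labels."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Internal-edge bipartitions as frozensets of leaf labels.

    Each bipartition is normalized to the side NOT containing the
    lexicographically smallest leaf label, so both orientations of an
    edge map to the same key.
    """
    all_labels = frozenset(t.label for t in tree.taxon_namespace)
    anchor = min(all_labels)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) < 2 or len(all_labels) - len(below) < 2:
            continue  # trivial bipartition (single leaf on one side)
        side = below if anchor not in below else all_labels - below
        out[side] = node
    return out


def bootstrap_support(
    alignment: Alignment,
    model: divergence.Model = "k2p",
    replicates: int = 200,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; replicate r
    draws from a generator seeded deterministically with (seed, r), so
    results are reproducible and independent of evaluation order.
    Replicates whose distance matrix has undefined entries are dropped
    and the support denominator shrinks accordingly.
    """
    arr = divergence.encode_alignment(alignment)
    labels = alignment.identifiers
    base_dist = divergence.distance_matrix(arr, model=model, labels=labels)
    tree = neighbor_joining(base_dist)
    target = _bipartitions(tree)
    counts = {bp: 0 for bp in target}
    n_cols = arr.shape[1]
    retained = 0
    for r in range(replicates):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_dist = divergence.distance_matrix(
            arr[:, cols], model=model, labels=labels)
        try:
            rep_tree = neighbor_joining(rep_dist, warn_negative=False)
        except ValueError:
            logger.warning("bootstrap replicate %d dropped "
                           "(undefined distances)", r)
            continue
        retained += 1
        rep_bps = _bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if retained == 0:
        raise ValueError("every bootstrap replicate was dropped")
    for bp, node in target.items():
        node.label = f"{100.0 * counts[bp] / retained:g}"
    return tree


def species_monophyly(tree: dendropy.Tree,
                      species_of: dict[str, str]) -> float:
    """Proportion of species whose leaves form an exact clade.

    ``species_of`` maps leaf label -> species.  A species is
    monophyletic iff its leaf set equals one side of some bipartition of
    the unrooted tree; singleton species count as monophyletic.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(species_of) - leaf_labels
    if missing:
        raise ValueError(f"leaves absent from tree: {sorted(missing)}")
    groups: dict[str, set] = {}
    for label, sp in species_of.items():
        groups.setdefault(sp, set()).add(label)

    all_labels = frozenset(leaf_labels)
    sides = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.add(below)
        sides.add(all_labels - below)
    successes = 0
    for sp, members in groups.items():
        if len(members) == 1 or frozenset(members) in sides:
            successes += 1
    return successes / len(groups)
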