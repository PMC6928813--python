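"""Site classification and pairwise/ensemble divergence statistics.

Gap/ambiguity conventions follow the usual desktop-tool defaults:
pairwise deletion for distances (each pair of rows uses every column
where both have an unambiguous base) and complete deletion for
nucleotide diversity and site classification (a column with a gap or
ambiguity in any row is excluded for everybody).  Percentages in
region reports are computed against total alignment columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .seqio import Alignment

# base encoding: A=0 C=1 G=2 T=3, anything else (gap/ambiguity) = MISSING.
# Purines (A, G) are even, pyrimidines (C, T) odd, so a substitution is a
# transition iff the two codes share parity.
MISSING = 4
_ENCODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

CATEGORY_EXCLUDED = "excluded"
CATEGORY_INVARIANT = "invariant"
CATEGORY_VARIABLE = "variable_uninformative"
CATEGORY_INFORMATIVE = "parsimony_informative"


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """Encode to a (n_rows, n_cols) uint8 matrix; non-ACGT becomes MISSING."""
    rows = [np.frombuffer(r.residues.encode(), dtype=np.uint8)
            for r in alignment.records]
    return _ENCODE[np.vstack(rows)]


@dataclass
class SiteClassification:
    """Per-column site categories and their counts."""

    categories: np.ndarray  # dtype=object of category strings, len n_total
    n_total: int
    n_excluded: int
    n_variable: int
    n_informative: int

    @property
    def percent_variable(self) -> float:
        """Variable sites as a percentage of total alignment columns."""
        return 100.0 * self.n_variable / self.n_total

    @property
    def percent_informative(self) -> float:
        return 100.0 * self.n_informative / self.n_total


@dataclass
class PairwiseComparison:
    """Transition/transversion bookkeeping for one pair of rows."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_compared

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_compared

    @property
    def defined(self) -> bool:
        return self.n_compared > 0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a defined-entry mask."""

    labels: list[str]
    values: np.ndarray        # (n, n) float, NaN where undefined
    defined_mask: np.ndarray  # (n, n) bool

    @property
    def n(self) -> int:
        return len(self.labels)

    def offdiag_values(self) -> np.ndarray:
        """Defined off-diagonal entries (each unordered pair once)."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.values[iu]
        mask = self.defined_mask[iu]
        return vals[mask]


def classify_sites(alignment: Alignment | np.ndarray) -> SiteClassification:
    """Classify every alignment column.

    A column is *excluded* if any row carries a gap or ambiguity code,
    *variable* if at least two distinct bases occur, and
    *parsimony-informative* if at least two distinct bases each occur in
    at least two rows.
    """
    arr = alignment if isinstance(alignment, np.ndarray) \
        else encode_alignment(alignment)
    if arr.shape[0] < 2:
        raise ValueError("site classification requires >= 2 rows")
    n_total = arr.shape[1]
    excluded = (arr == MISSING).any(axis=0)
    counts = np.stack([(arr == b).sum(axis=0) for b in range(4)])  # (4, cols)
    n_distinct = (counts > 0).sum(axis=0)
    n_shared = (counts >= 2).sum(axis=0)
    variable = ~excluded & (n_distinct >= 2)
    informative = variable & (n_shared >= 2)
    categories = np.empty(n_total, dtype=object)
    categories[excluded] = CATEGORY_EXCLUDED
    categories[~excluded & ~variable] = CATEGORY_INVARIANT
    categories[variable & ~informative] = CATEGORY_VARIABLE
    categories[informative] = CATEGORY_INFORMATIVE
    return SiteClassification(
        categories=categories,
        n_total=n_total,
        n_excluded=int(excluded.sum()),
        n_variable=int(variable.sum()),
        n_informative=int(informative.sum()),
    )


def pairwise_compare(row_i: np.ndarray | str,
                     row_j: np.ndarray | str) -> PairwiseComparison:
    """Compare two rows under pairwise deletion.

    Columns where either row carries a gap or ambiguity are skipped.
    A differing pair of bases is a transition when both are purines or
    both pyrimidines (A<->G, C<->T), otherwise a transversion.
    """
    a = _as_codes(row_i)
    b = _as_codes(row_j)
    if a.shape != b.shape:
        raise ValueError("rows differ in length")
    valid = (a != MISSING) & (b != MISSING)
    diff = valid & (a != b)
    transitions = diff & ((a & 1) == (b & 1))
    return PairwiseComparison(
        n_compared=int(valid.sum()),
        n_transitions=int(transitions.sum()),
        n_transversions=int(diff.sum() - transitions.sum()),
    )


def _as_codes(row: np.ndarray | str) -> np.ndarray:
    if isinstance(row, str):
        return _ENCODE[np.frombuffer(row.encode(), dtype=np.uint8)]
    return row


def p_distance(comparison: PairwiseComparison) -> float:
    """Proportion of differing sites among compared sites."""
    if not comparison.defined:
        raise ValueError("comparison has no shared unambiguous columns")
    return (comparison.n_transitions + comparison.n_transversions) \
        / comparison.n_compared


def k2p_distance(comparison: PairwiseComparison) -> float:
    """Kimura two-parameter distance.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) where P and Q are the
    transition and transversion proportions.  Returns NaN when the
    correction saturates (logarithm argument <= 0).
    """
    if not comparison.defined:
        raise ValueError("comparison has no shared unambiguous columns")
    P, Q = comparison.P, comparison.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def substitution_count(comparison: PairwiseComparison) -> int:
    """Raw count of differing sites under pairwise deletion."""
    return comparison.n_transitions + comparison.n_transversions


Model = Literal["p", "k2p"]


def distance_matrix(alignment: Alignment | np.ndarray,
                    model: Model = "k2p",
                    labels: list[str] | None = None) -> DistanceMatrix:
    """All-pairs distances under the chosen model (pairwise deletion)."""
    arr = alignment if isinstance(alignment, np.ndarray) \
        else encode_alignment(alignment)
    if labels is None:
        labels = alignment.identifiers if isinstance(alignment, Alignment) \
            else [str(i) for i in range(arr.shape[0])]
    n = arr.shape[0]
    values = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    dist = p_distance if model == "p" else k2p_distance
    for i in range(n):
        for j in range(i + 1, n):
            comp = pairwise_compare(arr[i], arr[j])
            if not comp.defined:
                d = math.nan
            else:
                d = dist(comp)
            values[i, j] = values[j, i] = d
            if math.isnan(d):
                defined[i, j] = defined[j, i] = False
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=list(labels), values=values,
                          defined_mask=defined)


def nucleotide_diversity(alignment: Alignment | np.ndarray) -> float:
    """Nucleotide diversity (pi) per site, complete deletion.

    Mean over all unordered row pairs of their per-site difference
    proportion, restricted to columns free of gaps and ambiguities in
    every row.  Because every pair shares the same usable columns, this
    equals (total pairwise differences) / (n_pairs * n_usable_columns).
    """
    arr = alignment if isinstance(alignment, np.ndarray) \
        else encode_alignment(alignment)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("pi requires >= 2 rows")
    usable = ~(arr == MISSING).any(axis=0)
    n_cols = int(usable.sum())
    if n_cols == 0:
        raise ValueError("no gap/ambiguity-free columns: pi undefined")
    sub = arr[:, usable]
    counts = np.stack([(sub == b).sum(axis=0) for b in range(4)])
    # pairwise differences per column from base counts
    pair_diffs = (n * n - (counts.astype(np.int64) ** 2).sum(axis=0)) // 2
    n_pairs = n * (n - 1) // 2
    return float(pair_diffs.sum() / (n_pairs * n_cols))


@dataclass
class RegionDivergence:
    """Table-style per-region divergence summary."""

    name: str
    n_sites: int
    n_variable: int
    percent_variable: float
    n_informative: int
    percent_informative: float
    pi: float


def region_divergence(
    alignment: Alignment,
    regions: dict[str, tuple[int, int]],
) -> pd.DataFrame:
    """Site classification and pi restricted to named column intervals.

    ``regions`` maps a region name to a 0-based half-open column
    interval.  Supply the IR interval once; duplicated IR columns would
    double-weight identical data.
    """
    arr = encode_alignment(alignment)
    rows = []
    for name, (start, end) in regions.items():
        if not (0 <= start < end <= arr.shape[1]):
            raise IndexError(f"region {name}: [{start}, {end}) out of bounds")
        sub = arr[:, start:end]
        cls = classify_sites(sub)
        pi = nucleotide_diversity(sub)
        rows.append(RegionDivergence(
            name=name,
            n_sites=end - start,
            n_variable=cls.n_variable,
            percent_variable=cls.percent_variable,
            n_informative=cls.n_informative,
            percent_informative=cls.percent_informative,
            pi=pi,
        ))
    return pd.DataFrame([vars(r) for r in rows])
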