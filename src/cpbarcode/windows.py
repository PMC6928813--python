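"""Sliding-window divergence profiling and mutation-hotspot discovery.

A fixed-length window slides across the alignment at a fixed step; per
window we report nucleotide diversity (pi), the mean defined pairwise
K2P distance, and the proportion of zero pairwise distances.  Windows
at or above a threshold (absolute, or a quantile of the profile) are
merged into maximal hotspot regions and ranked by peak metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import math

import numpy as np
import pandas as pd

from . import divergence
from .seqio import Alignment, AnnotatedGenome

logger = logging.getLogger(__name__)


@dataclass
class WindowProfile:
    """Divergence metrics for one alignment window."""

    start_col: int
    end_col: int
    pi: float
    mean_k2p: float
    prop_zero: float

    @property
    def midpoint(self) -> float:
        return self.start_col + (self.end_col - self.start_col) / 2


@dataclass
class MarkerRegion:
    """A named alignment-column interval, from a hotspot or a feature."""

    name: str
    start_col: int
    end_col: int
    source: str = "hotspot"  # hotspot | named-feature
    peak_metric: float = math.nan

    def __post_init__(self) -> None:
        if self.start_col >= self.end_col:
            raise ValueError(f"region {self.name}: empty interval")


def proportion_zero_distances(dist: divergence.DistanceMatrix) -> float:
    """Share of unordered pairs with distance exactly zero (defined pairs)."""
    iu = np.triu_indices(dist.n, k=1)
    mask = dist.defined_mask[iu]
    if not mask.any():
        raise ValueError("no defined pairs")
    return float((dist.values[iu][mask] == 0.0).mean())


def sliding_windows(alignment: Alignment, window: int = 800,
                    step: int = 100) -> list[WindowProfile]:
    """Scan the alignment with fixed-length windows.

    Windows start at offsets 0, step, 2*step, ...; the count is
    floor((n_cols - window)/step) + 1 and every window is full length —
    trailing columns not covered by the last full window are ignored.
    If ``window`` exceeds the alignment, a single whole-alignment window
    is returned with a warning.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    n_cols = alignment.n_cols
    if window > n_cols:
        logger.warning(
            "window (%d) exceeds alignment length (%d); using one "
            "whole-alignment window", window, n_cols,
        )
        window = n_cols
    arr = divergence.encode_alignment(alignment)
    labels = alignment.identifiers
    profiles = []
    n_windows = (n_cols - window) // step + 1
    for w in range(n_windows):
        start = w * step
        sub = arr[:, start:start + window]
        pi = _pi_or_zero(sub)
        dist = divergence.distance_matrix(sub, model="k2p", labels=labels)
        offdiag = dist.offdiag_values()
        mean_k2p = float(offdiag.mean()) if offdiag.size else math.nan
        try:
            prop_zero = proportion_zero_distances(dist)
        except ValueError:  # every pairwise distance undefined
            prop_zero = math.nan
        profiles.append(WindowProfile(
            start_col=start, end_col=start + window,
            pi=pi, mean_k2p=mean_k2p, prop_zero=prop_zero,
        ))
    return profiles


def _pi_or_zero(arr: np.ndarray) -> float:
    try:
        return divergence.nucleotide_diversity(arr)
    except ValueError:  # window entirely gapped/ambiguous
        return math.nan


Metric = Literal["pi", "mean_k2p"]


def call_hotspots(
    profiles: Sequence[WindowProfile],
    metric: Metric = "pi",
    threshold: float | None = None,
    quantile: float = 0.98,
    step: int | None = None,
) -> list[MarkerRegion]:
    """Select windows at/above threshold and merge them into regions.

    With no absolute ``threshold``, the threshold is the ``quantile``
    (default: top 2% of windows) of the metric across the profile.
    Overlapping or adjacent (gap <= step) selected windows are merged;
    regions are ranked by their peak metric, descending.
    """
    if not profiles:
        raise ValueError("no window profiles supplied")
    values = np.array([getattr(p, metric) for p in profiles], dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size == 0:
        raise ValueError("metric undefined in every window")
    if threshold is None:
        threshold = float(np.quantile(finite, quantile))
    selected = [p for p, v in zip(profiles, values)
                if not math.isnan(v) and v >= threshold]
    if not selected:
        logger.warning("threshold %.6g excludes every window", threshold)
        return []
    if step is None:
        step = _infer_step(profiles)
    merged: list[list[WindowProfile]] = [[selected[0]]]
    for p in selected[1:]:
        if p.start_col <= merged[-1][-1].end_col + step:
            merged[-1].append(p)
        else:
            merged.append([p])
    regions = []
    for group in merged:
        peak = max(getattr(p, metric) for p in group)
        regions.append(MarkerRegion(
            name=f"region_{group[0].start_col}_{group[-1].end_col}",
            start_col=group[0].start_col,
            end_col=group[-1].end_col,
            source="hotspot",
            peak_metric=peak,
        ))
    regions.sort(key=lambda r: (-r.peak_metric, r.start_col))
    return regions


def _infer_step(profiles: Sequence[WindowProfile]) -> int:
    if len(profiles) >= 2:
        return profiles[1].start_col - profiles[0].start_col
    return profiles[0].end_col - profiles[0].start_col


def profile_table(profiles: Sequence[WindowProfile]) -> pd.DataFrame:
    """One row per window: midpoint, pi, mean K2P, prop of zero distances."""
    return pd.DataFrame({
        "midpoint": [p.midpoint for p in profiles],
        "start_col": [p.start_col for p in profiles],
        "end_col": [p.end_col for p in profiles],
        "pi": [p.pi for p in profiles],
        "mean_k2p": [p.mean_k2p for p in profiles],
        "prop_zero": [p.prop_zero for p in profiles],
    })


def column_to_reference_map(alignment: Alignment,
                            reference_id: str) -> np.ndarray:
    """Map alignment columns to ungapped positions on a reference row.

    Returns an int array of length n_cols; gap columns of the reference
    carry the position of the preceding reference base (-1 before the
    first base).
    """
    ref = next((r for r in alignment.records
                if r.identifier == reference_id), None)
    if ref is None:
        raise KeyError(f"reference row {reference_id!r} not in alignment")
    positions = np.empty(alignment.n_cols, dtype=np.int64)
    pos = -1
    for c, ch in enumerate(ref.residues):
        if ch != "-":
            pos += 1
        positions[c] = pos
    return positions


def map_regions_to_features(
    regions: Sequence[MarkerRegion],
    annotated: AnnotatedGenome,
    column_map: np.ndarray,
) -> list[MarkerRegion]:
    """Name hotspot regions by the reference features they overlap.

    A region overlapping one or more features is named by joining their
    names; a region falling between two features is named
    ``"left-right"``; a region on unannotated sequence keeps its
    coordinate-based name.
    """
    features = sorted(annotated.features, key=lambda f: f.start)
    named = []
    for region in regions:
        ref_start = int(column_map[region.start_col])
        ref_end = int(column_map[region.end_col - 1]) + 1
        overlapping = [f for f in features
                       if f.start < ref_end and f.end > max(ref_start, 0)]
        if overlapping:
            name = "-".join(f.name for f in overlapping)
        else:
            left = next((f for f in reversed(features)
                         if f.end <= max(ref_start, 0)), None)
            right = next((f for f in features if f.start >= ref_end), None)
            if left and right:
                name = f"{left.name}-{right.name}"
            else:
                name = f"region_{region.start_col}_{region.end_col}"
        named.append(MarkerRegion(
            name=name, start_col=region.start_col, end_col=region.end_col,
            source="named-feature" if name and not name.startswith("region_")
            else "hotspot",
            peak_metric=region.peak_metric,
        ))
    return named
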