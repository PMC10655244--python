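"""Stack identification: pairwise geometric criteria, adjacency graph and
connected-component cluster statistics.

Two rings are stacked when, simultaneously, (i) their directors are
close to parallel, |d_i . d_j| >= 1 - delta_omega, (ii) the axial
projection of their centre separation onto the lower-index ring's
director is at most v_parallel and (iii) the in-plane remainder is at
most v_perpendicular.  Boundary equalities count as satisfied.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .model import minimum_image

logger = logging.getLogger(__name__)

__all__ = [
    "StackCriteria",
    "StackPartition",
    "pair_stacked",
    "build_partition",
    "partition_from_sizes",
    "alignment_distribution",
]


@dataclass
class StackCriteria:
    delta_omega: float = 0.1
    v_parallel: float = 3.0
    v_perpendicular: float = 2.5
    neighbor_cut_factor: float = 0.5  # times rg0, for the alignment histogram

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_omega < 1.0:
            raise ValueError("delta_omega must lie in (0, 1)")
        if min(self.v_parallel, self.v_perpendicular) <= 0:
            raise ValueError("distance thresholds must be positive")


@dataclass
class StackPartition:
    labels: np.ndarray          # per-ring cluster id, contiguous from 0
    sizes: np.ndarray           # size of each cluster (by cluster id)
    W: dict                     # weight fraction per aggregation number N_s
    Nw: float                   # weight-averaged aggregation number
    dangling_fraction: float    # W(N_s = 1)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def pair_stacked(ring_i, ring_j, criteria: StackCriteria, box: float | None) -> bool:
    """Apply the three stacking criteria to an ordered pair (i < j).

    The projections use ring i's director, matching the strictly
    upper-triangular adjacency construction.  Degenerate directors make a
    pair ineligible.
    """
    if getattr(ring_i, "degenerate", False) or getattr(ring_j, "degenerate", False):
        logger.warning("pair excluded: degenerate director")
        return False
    di, dj = ring_i.director, ring_j.director
    if abs(float(di @ dj)) < 1.0 - criteria.delta_omega:
        return False
    rij = ring_j.com - ring_i.com
    if box is not None:
        rij = minimum_image(rij, box)
    axial = float(rij @ di)
    if abs(axial) > criteria.v_parallel:
        return False
    lateral = rij - axial * di
    return bool(np.linalg.norm(lateral) <= criteria.v_perpendicular)


def build_partition(shapes, criteria: StackCriteria | None = None,
                    box: float | None = None) -> StackPartition:
    """Connected components of the pairwise stacking graph plus statistics."""
    criteria = criteria or StackCriteria()
    M = len(shapes)
    rows, cols = [], []
    for i in range(M):
        for j in range(i + 1, M):
            if pair_stacked(shapes[i], shapes[j], criteria, box):
                rows.append(i)
                cols.append(j)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(M, M))
    n_comp, labels = connected_components(adj, directed=False)
    return _partition_stats(labels, n_comp)


def _partition_stats(labels: np.ndarray, n_comp: int) -> StackPartition:
    M = len(labels)
    sizes = np.bincount(labels, minlength=n_comp)
    counter = Counter(sizes.tolist())
    W = {ns: ns * cnt / M for ns, cnt in sorted(counter.items())}
    Nw = float(sum(ns * w for ns, w in W.items()))
    return StackPartition(labels=np.asarray(labels), sizes=sizes, W=W, Nw=Nw,
                          dangling_fraction=W.get(1, 0.0))


def partition_from_sizes(sizes) -> StackPartition:
    """Statistics for an explicitly given multiset of cluster sizes."""
    sizes = np.asarray(sizes, dtype=int)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return _partition_stats(labels, len(sizes))


def alignment_distribution(shapes, rg0: float, box: float | None = None,
                           n_bins: int = 50, neighbor_cut_factor: float = 0.5):
    """Probability mass of |d_i . d_j| over neighbouring ring pairs.

    Pairs qualify when their centre-of-mass separation (minimum image) is
    at most ``neighbor_cut_factor * rg0``.  Returns ``(hist, edges, n_pairs)``
    with ``hist.sum() == 1`` when any pair qualifies; an all-zero histogram
    and ``n_pairs == 0`` flag an empty distribution.
    """
    if rg0 <= 0:
        raise ValueError("rg0 must be positive")
    cut = neighbor_cut_factor * rg0
    dots = []
    M = len(shapes)
    for i in range(M):
        for j in range(i + 1, M):
            rij = shapes[j].com - shapes[i].com
            if box is not None:
                rij = minimum_image(rij, box)
            if np.linalg.norm(rij) <= cut:
                dots.append(abs(float(shapes[i].director @ shapes[j].director)))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if not dots:
        logger.warning("alignment distribution: no qualifying pairs")
        return np.zeros(n_bins), edges, 0
    hist, _ = np.histogram(np.clip(dots, 0.0, 1.0), bins=edges)
    return hist / hist.sum(), edges, len(dots)
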