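"""Generators of configurations with planted ground truth.

These scenes are unit-test fixtures, not Boltzmann-weighted samples: they
let every analysis stage (directors, stack clustering, threading,
condensation) be validated without running dynamics.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import make_ring_polygon
from .model import ION_MONO, ION_TRI, MONOMER, Configuration, ForceField, RingTopology

__all__ = [
    "SceneTruth",
    "make_planar_ring",
    "make_prolate_ring",
    "make_stack_scene",
    "make_threading_scene",
    "make_ion_cloud",
]


@dataclass
class SceneTruth:
    cluster_labels: Optional[np.ndarray] = None
    director_truth: Optional[np.ndarray] = None
    threading_truth: Optional[list] = None  # (active, passive, n_crossings)
    condensed_fraction_truth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cluster_labels is not None:
            labels = np.asarray(self.cluster_labels)
            uniq = np.unique(labels)
            if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
                raise ValueError("cluster labels must be contiguous from 0")
            self.cluster_labels = labels
        if self.director_truth is not None:
            d = np.asarray(self.director_truth, dtype=float)
            norms = np.linalg.norm(d, axis=-1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("director truth vectors must be unit length")
            self.director_truth = d


def _rotation_to(normal: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to ``normal``."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, n)
    s = np.linalg.norm(v)
    c = float(z @ n)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def make_planar_ring(N: int, bond_length: float = 0.96,
                     center=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Regular N-gon of circumradius b / (2 sin(pi/N)) in the plane normal to ``normal``."""
    ring = make_ring_polygon(N, bond_length)
    return ring @ _rotation_to(normal).T + np.asarray(center, dtype=float)


def make_prolate_ring(N: int, width: float = 2.0, bond_length: float = 0.96,
                      center=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Cigar-like ring: two antiparallel strands joined by hairpin turns.

    The contour is a thin rectangle of the given ``width`` (hairpin span)
    elongated along ``axis``, with N monomers spaced uniformly along the
    perimeter - an idealisation of the double-folded prolate conformations.
    """
    if N < 8:
        raise ValueError("prolate ring needs at least 8 monomers")
    perimeter = N * bond_length
    height = 0.5 * (perimeter - 2.0 * width)
    if height <= 0:
        raise ValueError("width too large for the given contour length")
    # walk the rectangle perimeter in the xz-plane, starting mid-left going up
    corners = np.array([
        [-width / 2.0, 0.0, -height / 2.0],
        [-width / 2.0, 0.0, height / 2.0],
        [width / 2.0, 0.0, height / 2.0],
        [width / 2.0, 0.0, -height / 2.0],
    ])
    seglens = [height, width, height, width]
    pts = []
    s_values = np.arange(N) * bond_length
    for s in s_values:
        acc = 0.0
        for ci, sl in enumerate(seglens):
            if s <= acc + sl or ci == 3:
                t = (s - acc) / sl
                a = corners[ci]
                b = corners[(ci + 1) % 4]
                pts.append(a + t * (b - a))
                break
            acc += sl
    coords = np.asarray(pts)
    rot = _rotation_to(axis)
    # rectangle is elongated along z already; rotate z onto the axis
    return coords @ rot.T + np.asarray(center, dtype=float)


def make_stack_scene(n_stacks: int, sizes: Sequence[int], spacing: float = 1.0,
                     tilt_max: float = 0.0, jitter: float = 0.0,
                     box: float = 100.0, N: int = 50,
                     bond_length: float = 0.96, n_dangling: int = 0,
                     seed: int = 0):
    """Coaxial ring columns with controlled tilt/jitter and planted labels.

    Returns ``(Configuration, RingTopology, SceneTruth)``.  Stack axes all
    point along z; columns are laid out on an xy-grid whose pitch exceeds
    both the ring diameter and the lateral stacking threshold, so distinct
    columns can never merge.  Dangling rings are placed on a separate,
    well-separated grid layer.
    """
    if len(sizes) != n_stacks:
        raise ValueError("need one size per stack")
    rng = np.random.default_rng(seed)
    radius = bond_length / (2.0 * math.sin(math.pi / N))
    pitch = max(2.0 * radius * 1.15, 8.0)
    n_cols = int(math.ceil(math.sqrt(n_stacks + n_dangling)))
    if n_cols * pitch > box:
        raise ValueError("stacks would overlap: box too small for the grid pitch")
    tallest = max(list(sizes) + [1]) * spacing
    if tallest > box:
        raise ValueError("stack taller than the box")

    coords = []
    labels = []
    directors = []
    axis = np.array([0.0, 0.0, 1.0])
    slot = 0
    for s_idx, size in enumerate(sizes):
        cx = (slot % n_cols + 0.5) * pitch
        cy = (slot // n_cols + 0.5) * pitch
        slot += 1
        z0 = 0.5 * (box - (size - 1) * spacing)
        for j in range(size):
            center = np.array([cx, cy, z0 + j * spacing])
            if tilt_max > 0:
                tilt = rng.uniform(0.0, tilt_max)
                azim = rng.uniform(0.0, 2.0 * math.pi)
                normal = np.array([math.sin(tilt) * math.cos(azim),
                                   math.sin(tilt) * math.sin(azim),
                                   math.cos(tilt)])
            else:
                normal = axis
            ring = make_planar_ring(N, bond_length, center, normal)
            if jitter > 0:
                ring = ring + rng.normal(0.0, jitter, size=ring.shape)
            coords.append(ring)
            labels.append(s_idx)
            directors.append(axis)
    for d_idx in range(n_dangling):
        cx = (slot % n_cols + 0.5) * pitch
        cy = (slot // n_cols + 0.5) * pitch
        slot += 1
        center = np.array([cx, cy, 0.5 * box])
        normal = _random_unit(rng)
        ring = make_planar_ring(N, bond_length, center, normal)
        if jitter > 0:
            ring = ring + rng.normal(0.0, jitter, size=ring.shape)
        coords.append(ring)
        labels.append(n_stacks + d_idx)
        directors.append(normal)

    M = len(coords)
    positions = np.concatenate(coords)
    topo = RingTopology([np.arange(m * N, (m + 1) * N) for m in range(M)])
    config = Configuration(positions, np.zeros(M * N, dtype=np.int64),
                           np.zeros(M * N), box)
    truth = SceneTruth(cluster_labels=np.asarray(labels),
                       director_truth=np.asarray(directors))
    return config, topo, truth


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def make_threading_scene(kind: str, N: int = 50, bond_length: float = 0.96,
                         box: float = 60.0, offset: float = 0.0):
    """Scenes with exactly known threading counts.

    kinds:
      * ``rod_through_ring`` - straight open rod through a planar ring's
        centre (or displaced outside it by ``offset`` > ring radius).
      * ``ring_chain`` - a prolate ring passing through a planar ring's
        disk, giving two surface crossings.
      * ``unlinked`` - two distant planar rings, zero threadings.

    Returns ``(Configuration, RingTopology, SceneTruth)``.
    """
    center = np.full(3, box / 2.0)
    radius = bond_length / (2.0 * math.sin(math.pi / N))
    ring = make_planar_ring(N, bond_length, center, (0.0, 0.0, 1.0))
    if kind == "rod_through_ring":
        n_rod = max(N // 2, 8)
        n_rod += n_rod % 2  # even bead count: no bead sits exactly in the ring plane
        z = (np.arange(n_rod) - (n_rod - 1) / 2.0) * bond_length
        rod = np.column_stack([np.full(n_rod, center[0] + offset),
                               np.full(n_rod, center[1]),
                               center[2] + z])
        positions = np.concatenate([ring, rod])
        topo = RingTopology([np.arange(N), np.arange(N, N + n_rod)],
                            closed=[True, False])
        n_cross = 1 if abs(offset) < radius else 0
        truth = SceneTruth(threading_truth=(
            [(1, 0, 1)] if n_cross else []))
    elif kind == "ring_chain":
        prolate = make_prolate_ring(N, width=min(radius, 4.0),
                                    bond_length=bond_length, center=center,
                                    axis=(0.0, 0.0, 1.0))
        positions = np.concatenate([ring, prolate])
        topo = RingTopology([np.arange(N), np.arange(N, 2 * N)])
        truth = SceneTruth(threading_truth=[(1, 0, 2)])
    elif kind == "unlinked":
        far = make_planar_ring(N, bond_length,
                               center + np.array([0.0, 0.0, box / 4.0]),
                               (0.0, 0.0, 1.0))
        positions = np.concatenate([ring, far])
        topo = RingTopology([np.arange(N), np.arange(N, 2 * N)])
        truth = SceneTruth(threading_truth=[])
    else:
        raise ValueError(f"unknown threading scene kind {kind!r}")
    M = topo.n_rings
    n = len(positions)
    config = Configuration(positions, np.zeros(n, dtype=np.int64),
                           np.zeros(n), box)
    return config, topo, truth


def make_ion_cloud(ring_coords: np.ndarray, condensed_fraction: float,
                   shell_width: float, box: float, n_ions: int = 200,
                   species: int = ION_TRI, seed: int = 0):
    """Ion coordinates with a planted condensed fraction.

    The stated fraction is placed within ``shell_width`` of a randomly
    chosen monomer; the remainder is uniform in the box.  Returns
    ``(ion_positions, SceneTruth)``.
    """
    if not 0.0 <= condensed_fraction <= 1.0:
        raise ValueError("condensed_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    monomers = np.asarray(ring_coords, dtype=float).reshape(-1, 3)
    n_cond = int(round(condensed_fraction * n_ions))
    ions = []
    for _ in range(n_cond):
        host = monomers[rng.integers(len(monomers))]
        direction = _random_unit(rng)
        r = shell_width * (0.2 + 0.75 * rng.random())
        ions.append(host + r * direction)
    if n_ions - n_cond:
        ions.append(rng.uniform(0.0, box, size=(n_ions - n_cond, 3)))
    positions = (np.vstack([np.atleast_2d(i) for i in ions])
                 if ions else np.empty((0, 3)))
    truth = SceneTruth(condensed_fraction_truth=condensed_fraction)
    return positions, truth
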