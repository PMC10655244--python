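"""Minimal surfaces spanning ring contours and threading detection.

Each ring contour is spanned by a triangulated disk whose boundary
vertices coincide with (and stay pinned to) the monomer positions while
free interior "ghost" vertices are relaxed by gradient descent on the
total triangle area.  Relaxation stops once the relative area change over
a 240-step window falls below 0.1%.  A ring A threads ring B when one of
A's bond segments pierces a triangle of B's surface; crossing bonds cut
A's contour into segments whose monomer counts are the threading depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .conformation import ring_shape, unwrap_ring
from .model import Configuration, RingTopology, minimum_image

logger = logging.getLogger(__name__)

__all__ = [
    "MinimalSurface",
    "ThreadingRecord",
    "SurfaceConvergenceError",
    "build_minimal_surface",
    "segment_triangle_intersect",
    "segments_cross_triangles",
    "detect_threadings",
    "threading_statistics",
    "write_off",
]


class SurfaceConvergenceError(RuntimeError):
    """Raised when area minimisation exhausts its step budget."""


@dataclass
class MinimalSurface:
    vertices: np.ndarray        # (n_vertices, 3); first n_boundary are fixed
    triangles: np.ndarray       # (n_triangles, 3) vertex index triples
    n_boundary: int
    area: float
    n_steps: int = 0

    @property
    def boundary(self) -> np.ndarray:
        return self.vertices[: self.n_boundary]

    @property
    def ghosts(self) -> np.ndarray:
        return self.vertices[self.n_boundary:]


@dataclass
class ThreadingRecord:
    active_ring: int
    passive_ring: int
    crossings: list              # (active bond index, passive triangle index)
    depths: list                 # contour segment lengths in monomer counts

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)


# ---------------------------------------------------------------------------
# mesh construction and area minimisation
# ---------------------------------------------------------------------------

def _disk_mesh(contour: np.ndarray, n_layers: int):
    """Concentric-layer triangulation of a closed contour.

    Layer 0 is the boundary (N fixed vertices); each interior layer keeps N
    vertices interpolated toward the centroid, and the innermost layer is
    closed by a single central vertex.
    """
    N = len(contour)
    centroid = contour.mean(axis=0)
    vertices = [contour]
    for layer in range(1, n_layers + 1):
        t = layer / (n_layers + 1)
        vertices.append(contour * (1.0 - t) + centroid * t)
    vertices.append(centroid[None, :])
    vertices = np.concatenate(vertices)

    triangles = []
    for layer in range(n_layers):
        a = layer * N
        b = (layer + 1) * N
        for j in range(N):
            jn = (j + 1) % N
            triangles.append((a + j, a + jn, b + j))
            triangles.append((a + jn, b + jn, b + j))
    center = (n_layers + 1) * N
    a = n_layers * N
    for j in range(N):
        triangles.append((a + j, a + (j + 1) % N, center))
    return vertices, np.asarray(triangles, dtype=np.int64)


def _triangle_areas_normals(vertices: np.ndarray, triangles: np.ndarray):
    p0 = vertices[triangles[:, 0]]
    p1 = vertices[triangles[:, 1]]
    p2 = vertices[triangles[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n, axis=1)
    return 0.5 * norm, n, norm


def _area_gradient(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """d(total area)/d(vertex); grad at vertex a of triangle (a,b,c) is
    (b - c) x n_hat / 2."""
    p0 = vertices[triangles[:, 0]]
    p1 = vertices[triangles[:, 1]]
    p2 = vertices[triangles[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n, axis=1)
    good = norm > 1e-14
    nh = np.zeros_like(n)
    nh[good] = n[good] / norm[good, None]
    grad = np.zeros_like(vertices)
    np.add.at(grad, triangles[:, 0], 0.5 * np.cross(p1 - p2, nh))
    np.add.at(grad, triangles[:, 1], 0.5 * np.cross(p2 - p0, nh))
    np.add.at(grad, triangles[:, 2], 0.5 * np.cross(p0 - p1, nh))
    return grad


def build_minimal_surface(contour: np.ndarray, n_layers: Optional[int] = None,
                          rel_tol: float = 1e-3, window: int = 240,
                          max_steps: int = 20000) -> MinimalSurface:
    """Span an unwrapped ring contour and relax ghost vertices to minimal area.

    Gradient descent with backtracking keeps the area monotonically
    non-increasing; convergence requires the area to change by no more
    than ``rel_tol`` (0.1%) over ``window`` (240) consecutive steps.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 3 or len(contour) < 3:
        raise ValueError("contour must be an (N >= 3, 3) coordinate array")
    if n_layers is None:
        rel = contour - contour.mean(axis=0)
        radius = float(np.linalg.norm(rel, axis=1).mean())
        n_layers = max(int(round(radius)), 1)
    vertices, triangles = _disk_mesh(contour, n_layers)
    n_boundary = len(contour)

    areas, _, _ = _triangle_areas_normals(vertices, triangles)
    area = float(areas.sum())
    history = [area]
    mean_edge = float(np.linalg.norm(np.diff(contour, axis=0), axis=1).mean())
    step_size = 0.25 * mean_edge

    n_steps = 0
    for n_steps in range(1, max_steps + 1):
        grad = _area_gradient(vertices, triangles)
        grad[:n_boundary] = 0.0
        gmax = np.abs(grad).max()
        if gmax < 1e-12:
            break
        eta = step_size
        moved = False
        for _ in range(20):
            trial = vertices - eta * grad
            trial[:n_boundary] = contour
            t_areas, _, _ = _triangle_areas_normals(trial, triangles)
            t_area = float(t_areas.sum())
            if t_area <= area:
                vertices = trial
                area = t_area
                moved = True
                break
            eta *= 0.5
        history.append(area)
        if not moved:
            break
        if len(history) > window:
            past = history[-window - 1]
            if abs(past - area) <= rel_tol * max(past, 1e-300):
                break
    else:
        raise SurfaceConvergenceError(
            f"surface did not converge in {max_steps} steps (area {area:.4f})")
    return MinimalSurface(vertices=vertices, triangles=triangles,
                          n_boundary=n_boundary, area=area, n_steps=n_steps)


# ---------------------------------------------------------------------------
# segment / triangle intersection
# ---------------------------------------------------------------------------

_EPS = 1e-12


def segment_triangle_intersect(p0, p1, tri):
    """Exact parametric segment-triangle test (boundary hits inclusive).

    Returns ``(hit, point)``; degenerate triangles are excluded with a
    warning and never intersect.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    tri = np.asarray(tri, dtype=float)
    e1 = tri[1] - tri[0]
    e2 = tri[2] - tri[0]
    if np.linalg.norm(np.cross(e1, e2)) < _EPS:
        logger.warning("degenerate triangle excluded from intersection test")
        return False, None
    d = p1 - p0
    h = np.cross(d, e2)
    a = e1 @ h
    if abs(a) < _EPS:  # segment parallel to triangle plane
        return False, None
    f = 1.0 / a
    s = p0 - tri[0]
    u = f * (s @ h)
    if u < -_EPS or u > 1.0 + _EPS:
        return False, None
    q = np.cross(s, e1)
    v = f * (d @ q)
    if v < -_EPS or u + v > 1.0 + _EPS:
        return False, None
    t = f * (e2 @ q)
    if t < -_EPS or t > 1.0 + _EPS:
        return False, None
    return True, p0 + t * d


def segments_cross_triangles(seg_starts: np.ndarray, seg_ends: np.ndarray,
                             tri_verts: np.ndarray) -> np.ndarray:
    """Vectorised Moeller-Trumbore: (n_segments, n_triangles) boolean matrix.

    ``tri_verts`` has shape (n_triangles, 3, 3); boundary hits inclusive,
    degenerate triangles never hit.
    """
    p0 = seg_starts[:, None, :]
    d = (seg_ends - seg_starts)[:, None, :]
    t0 = tri_verts[None, :, 0, :]
    e1 = (tri_verts[:, 1] - tri_verts[:, 0])[None, :, :]
    e2 = (tri_verts[:, 2] - tri_verts[:, 0])[None, :, :]
    h = np.cross(d, e2)
    a = (e1 * h).sum(-1)
    degenerate = (np.linalg.norm(np.cross(e1[0], e2[0]), axis=-1) < _EPS)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 / a
        s = p0 - t0
        u = f * (s * h).sum(-1)
        q = np.cross(s, e1)
        v = f * (d * q).sum(-1)
        t = f * (e2 * q).sum(-1)
        hit = ((np.abs(a) >= _EPS) & ~degenerate
               & (u >= -_EPS) & (u <= 1.0 + _EPS)
               & (v >= -_EPS) & (u + v <= 1.0 + _EPS)
               & (t >= -_EPS) & (t <= 1.0 + _EPS))
    return hit


# ---------------------------------------------------------------------------
# threading detection and statistics
# ---------------------------------------------------------------------------

def _ring_bonds(coords: np.ndarray, closed: bool):
    if closed:
        starts = coords
        ends = np.roll(coords, -1, axis=0)
    else:
        starts = coords[:-1]
        ends = coords[1:]
    return starts, ends


def detect_threadings(config: Configuration, topo: RingTopology,
                      surfaces: Optional[Sequence[MinimalSurface]] = None,
                      box: Optional[float] = None) -> list:
    """All ordered threading records (active, passive) in one snapshot.

    Active-ring coordinates are shifted by the minimum-image lattice vector
    that brings their centre of mass closest to the passive ring before the
    bond-triangle tests, so threadings across the periodic boundary are
    caught.  One crossing is counted per (bond, surface) pair.
    """
    box = config.box_length if box is None else box
    rings = [unwrap_ring(config.positions[r], box) for r in topo.rings]
    if surfaces is None:
        surfaces = [build_minimal_surface(c) if topo.is_closed(i) else None
                    for i, c in enumerate(rings)]
    coms = np.array([c.mean(axis=0) for c in rings])
    records = []
    for a, ring_a in enumerate(rings):
        for b, surf in enumerate(surfaces):
            if a == b or surf is None:
                continue
            shift = minimum_image(coms[a] - coms[b], box) - (coms[a] - coms[b])
            coords = ring_a + shift
            starts, ends = _ring_bonds(coords, topo.is_closed(a))
            tri_verts = surf.vertices[surf.triangles]
            hits = segments_cross_triangles(starts, ends, tri_verts)
            bond_hits = np.nonzero(hits.any(axis=1))[0]
            if len(bond_hits) == 0:
                continue
            crossings = [(int(i), int(np.nonzero(hits[i])[0][0]))
                         for i in bond_hits]
            depths = _threading_depths(bond_hits, len(ring_a), topo.is_closed(a))
            if topo.is_closed(a) and len(bond_hits) % 2:
                logger.warning(
                    "odd crossing count (%d) for pair (%d, %d); "
                    "possible mesh artefact", len(bond_hits), a, b)
            records.append(ThreadingRecord(active_ring=a, passive_ring=b,
                                           crossings=crossings, depths=depths))
    return records


def _threading_depths(bond_indices: np.ndarray, n_monomers: int,
                      closed: bool) -> list:
    idx = np.sort(np.asarray(bond_indices))
    if closed:
        if len(idx) == 1:
            return [n_monomers]
        gaps = np.diff(np.concatenate([idx, [idx[0] + n_monomers]]))
        return [int(g) for g in gaps]
    cuts = np.concatenate([[-1], idx, [n_monomers - 1]])
    return [int(g) for g in np.diff(cuts) if g > 0]


def threading_statistics(records_per_frame: Sequence[Sequence[ThreadingRecord]],
                         shapes_per_frame: Sequence[Sequence],
                         count_bins: Optional[np.ndarray] = None,
                         prolateness_bins: Optional[np.ndarray] = None):
    """Joint densities of (prolateness x passive count) and (x active count).

    Returns a dict with normalised joint histograms and marginal
    distributions ``P(passive)`` and ``P(active)`` (each sums to 1).
    """
    if len(records_per_frame) != len(shapes_per_frame):
        raise ValueError("records and shapes must be frame-aligned")
    prol, active, passive = [], [], []
    for records, shapes in zip(records_per_frame, shapes_per_frame):
        M = len(shapes)
        act = np.zeros(M, dtype=int)
        pas = np.zeros(M, dtype=int)
        for rec in records:
            act[rec.active_ring] += 1
            pas[rec.passive_ring] += 1
        prol.extend(s.prolateness for s in shapes)
        active.extend(act)
        passive.extend(pas)
    prol = np.asarray(prol)
    active = np.asarray(active)
    passive = np.asarray(passive)
    cmax = int(max(active.max(initial=0), passive.max(initial=0))) + 1
    if count_bins is None:
        count_bins = np.arange(cmax + 1) - 0.5
    if prolateness_bins is None:
        prolateness_bins = np.linspace(-0.25, 2.0, 46)

    def _joint(counts):
        h, _, _ = np.histogram2d(prol, counts, bins=[prolateness_bins, count_bins])
        return h / h.sum() if h.sum() else h

    def _marginal(counts):
        h = np.bincount(counts, minlength=cmax).astype(float)
        return h / h.sum() if h.sum() else h

    return {
        "joint_passive": _joint(passive),
        "joint_active": _joint(active),
        "P_passive": _marginal(passive),
        "P_active": _marginal(active),
        "prolateness_bins": prolateness_bins,
        "count_bins": count_bins,
    }


def write_off(surface: MinimalSurface, path) -> None:
    """Export a mesh in OFF format for visual debugging."""
    lines = ["OFF", f"{len(surface.vertices)} {len(surface.triangles)} 0"]
    lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in surface.vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in surface.triangles]
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
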