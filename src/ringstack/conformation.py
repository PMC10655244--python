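"""Per-ring shape observables: gyration tensor, prolateness and director.

Rings in a periodic box are first reconstructed ("unwrapped") by walking
their bond sequence with minimum-image displacements, since the gyration
tensor of a wrapped, discontinuous contour is meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import Configuration, ForceField, RingTopology, minimum_image

__all__ = [
    "RingShape",
    "ReferenceScale",
    "DegenerateDirectorError",
    "WrappedRingError",
    "unwrap_ring",
    "ring_center_of_mass",
    "gyration_tensor",
    "director",
    "prolateness",
    "ring_shape",
    "frame_shapes",
    "shape_histogram",
    "measure_rg0",
    "bond_correlation",
    "persistence_length",
]

#: prolateness extremes of the normalised formula prod(lam_i - mean) / mean^3
PROLATENESS_MAX = 2.0    # thin rod  (lam, 0, 0)
PROLATENESS_MIN = -0.25  # thin disk (lam, lam, 0)


class DegenerateDirectorError(ValueError):
    """Raised when the two smallest gyration eigenvalues are degenerate."""


class WrappedRingError(ValueError):
    """Raised when a ring crosses the periodic boundary and auto-unwrap is off."""


@dataclass
class RingShape:
    gyration_eigenvalues: np.ndarray  # descending lam1 >= lam2 >= lam3
    rg: float
    prolateness: float
    director: np.ndarray
    com: np.ndarray
    degenerate: bool = False


@dataclass
class ReferenceScale:
    """Single-ring infinite-dilution radius of gyration R_g,0."""

    rg0: float
    stderr: float = 0.0

    def __post_init__(self) -> None:
        if self.rg0 <= 0:
            raise ValueError("rg0 must be positive")


def unwrap_ring(coords: np.ndarray, box: Optional[float]) -> np.ndarray:
    """Reconstruct a contiguous contour by chaining minimum-image bond steps."""
    coords = np.asarray(coords, dtype=float)
    if box is None:
        return coords.copy()
    steps = minimum_image(np.diff(coords, axis=0), box)
    out = np.empty_like(coords)
    out[0] = coords[0]
    out[1:] = coords[0] + np.cumsum(steps, axis=0)
    return out


def ring_center_of_mass(coords: np.ndarray, box: Optional[float] = None) -> np.ndarray:
    return unwrap_ring(coords, box).mean(axis=0)


def gyration_tensor(coords: np.ndarray, box: Optional[float] = None,
                    auto_unwrap: bool = True) -> np.ndarray:
    """G_ab = (1/N) sum_i (r_i,a - r_com,a)(r_i,b - r_com,b)."""
    coords = np.asarray(coords, dtype=float)
    if box is not None:
        jumps = np.abs(minimum_image(np.diff(coords, axis=0), box)
                       - np.diff(coords, axis=0))
        if np.any(jumps > 1e-9):
            if not auto_unwrap:
                raise WrappedRingError("ring crosses the periodic boundary")
            coords = unwrap_ring(coords, box)
    rel = coords - coords.mean(axis=0)
    return rel.T @ rel / len(coords)


def _sorted_eig(tensor: np.ndarray):
    vals, vecs = np.linalg.eigh(tensor)  # ascending
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def director(tensor: np.ndarray, degeneracy_rtol: float = 1e-8):
    """Unit eigenvector of the smallest gyration eigenvalue.

    The sign is fixed deterministically (first nonzero component positive);
    only |d_i . d_j| ever enters the stacking criteria.  Returns
    ``(vector, degenerate_flag)``.
    """
    vals, vecs = _sorted_eig(np.asarray(tensor, dtype=float))
    scale = max(vals[0], 1e-300)
    degenerate = (vals[1] - vals[2]) / scale < degeneracy_rtol
    d = vecs[:, 2].copy()
    for comp in d:
        if abs(comp) > 1e-12:
            if comp < 0:
                d = -d
            break
    return d / np.linalg.norm(d), bool(degenerate)


def prolateness(tensor: np.ndarray) -> float:
    """Normalised shape descriptor prod(lam_i - lam_mean) / lam_mean^3.

    Positive for cigar-like prolates (maximum +2 for a thin rod), negative
    for lentil-like oblates (minimum -1/4 for a thin disk) and zero for
    spherical symmetry; invariant under rotations and uniform scaling.
    """
    vals, _ = _sorted_eig(np.asarray(tensor, dtype=float))
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("undefined shape: zero gyration tensor")
    return float(np.prod(vals - mean) / mean ** 3)


def ring_shape(coords: np.ndarray, box: Optional[float] = None) -> RingShape:
    coords = np.asarray(coords, dtype=float)
    unwrapped = unwrap_ring(coords, box) if box is not None else coords
    tensor = gyration_tensor(unwrapped)
    vals, _ = _sorted_eig(tensor)
    d, degenerate = director(tensor)
    return RingShape(
        gyration_eigenvalues=vals,
        rg=float(np.sqrt(max(vals.sum(), 0.0))),
        prolateness=prolateness(tensor),
        director=d,
        com=unwrapped.mean(axis=0),
        degenerate=degenerate,
    )


def frame_shapes(config: Configuration, topo: RingTopology) -> list:
    """RingShape for every ring of one snapshot."""
    return [ring_shape(config.positions[ring], config.box_length)
            for ring in topo.rings]


def shape_histogram(shapes_per_frame: list, rg0: float,
                    rg_bins=None, prolateness_bins=None):
    """Joint probability mass over (rg / rg0, prolateness).

    Returns ``(hist, rg_edges, p_edges)`` with ``hist.sum() == 1``.
    """
    all_shapes = [s for frame in shapes_per_frame for s in frame]
    if not all_shapes:
        raise ValueError("empty trajectory: no shapes to histogram")
    if rg0 <= 0:
        raise ValueError("rg0 must be positive")
    x = np.array([s.rg / rg0 for s in all_shapes])
    y = np.array([s.prolateness for s in all_shapes])
    if rg_bins is None:
        rg_bins = np.linspace(0.0, max(1.5, x.max() * 1.01), 61)
    if prolateness_bins is None:
        prolateness_bins = np.linspace(PROLATENESS_MIN, PROLATENESS_MAX, 61)
    hist, xe, ye = np.histogram2d(x, y, bins=[rg_bins, prolateness_bins])
    total = hist.sum()
    if total == 0:
        raise ValueError("all samples fell outside the histogram range")
    return hist / total, xe, ye


def measure_rg0(ff: Optional[ForceField] = None, seed: int = 0,
                N: int = 50, equil_time: float = 50.0,
                sample_time: float = 200.0, dump_interval: float = 1.0,
                max_rounds: int = 8, target_rel_stderr: float = 0.01,
                charged: bool = False) -> ReferenceScale:
    """Time-averaged R_g of one isolated ring from a Langevin run.

    Sampling rounds are appended until the blocked standard error of the
    mean drops below ``target_rel_stderr`` (default 1%).
    """
    from .dynamics import make_ring_polygon, run_langevin
    ff = ff or ForceField()
    box = 40.0 * max(1.0, N / 50.0)
    coords = make_ring_polygon(N) + box / 2.0
    species = np.zeros(N, dtype=np.int64)
    charges = np.full(N, float(ff.z_mon)) if charged else np.zeros(N)
    config = Configuration(coords, species, charges, box)
    topo = RingTopology([np.arange(N)])
    mode = "explicit" if charged else "off"
    config = run_langevin(config, topo, ff, mode, duration=equil_time,
                          seed=seed).frames[-1]
    samples = []
    for round_idx in range(max_rounds):
        traj = run_langevin(config, topo, ff, mode, duration=sample_time,
                            seed=seed + 1 + round_idx,
                            dump_interval=dump_interval)
        config = traj.frames[-1]
        for frame in traj.frames[1:]:
            samples.append(ring_shape(frame.positions, frame.box_length).rg)
        arr = np.array(samples)
        # block over ~10 tau to decorrelate
        block = max(int(10.0 / dump_interval), 1)
        n_blocks = len(arr) // block
        if n_blocks >= 4:
            blocks = arr[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
            stderr = blocks.std(ddof=1) / np.sqrt(n_blocks)
            if stderr / arr.mean() < target_rel_stderr:
                return ReferenceScale(float(arr.mean()), float(stderr))
    arr = np.array(samples)
    raise RuntimeError(
        f"rg0 did not converge to {target_rel_stderr:.1%} relative standard "
        f"error within budget (last mean {arr.mean():.3f})")


# ---------------------------------------------------------------------------
# persistence length (open-chain reference measurement)
# ---------------------------------------------------------------------------

def bond_correlation(traj_frames, topo: RingTopology, max_sep: int = 20) -> np.ndarray:
    """<u_i . u_{i+s}> of unit bond vectors averaged over frames and positions."""
    acc = np.zeros(max_sep + 1)
    counts = np.zeros(max_sep + 1)
    for config in traj_frames:
        for ridx, ring in enumerate(topo.rings):
            closed = topo.is_closed(ridx)
            coords = unwrap_ring(config.positions[ring], config.box_length)
            bonds = np.diff(coords, axis=0)
            if closed:
                bonds = np.vstack([bonds, coords[0] - coords[-1]])
            u = bonds / np.linalg.norm(bonds, axis=1)[:, None]
            nb = len(u)
            for s in range(min(max_sep, nb - 1) + 1):
                if closed:
                    dots = (u * np.roll(u, -s, axis=0)).sum(axis=1)
                else:
                    dots = (u[: nb - s] * u[s:]).sum(axis=1)
                acc[s] += dots.sum()
                counts[s] += len(dots)
    return acc / np.maximum(counts, 1)


def persistence_length(correlation: np.ndarray, bond_length: float = 0.96,
                       fit_range: Optional[int] = None) -> float:
    """Exponential fit <u_0 . u_s> = exp(-s b / l_per) on the positive decay."""
    corr = np.asarray(correlation, dtype=float)
    if fit_range is None:
        positive = np.nonzero(corr <= 0.05)[0]
        fit_range = int(positive[0]) if len(positive) else len(corr)
    s = np.arange(fit_range)
    y = corr[:fit_range]
    if np.any(y <= 0):
        raise ValueError("correlation must stay positive over the fit range")
    slope = np.polyfit(s, np.log(y), 1)[0]
    if slope >= 0:
        raise ValueError("bond correlation does not decay")
    return float(-bond_length / slope)
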