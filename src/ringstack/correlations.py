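"""Static and dynamic correlation functions between ring centres of mass,
radial pair correlations and counterion-condensation diagnostics.

Only wavevectors commensurate with the cubic box, k = (2 pi / L) * n with
integer n, are ever used; shell averages collect all legal vectors whose
magnitude falls within half a lattice spacing (pi / L) of the target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import MONOMER, Configuration, minimum_image

logger = logging.getLogger(__name__)

__all__ = [
    "KGrid",
    "CorrelationSeries",
    "structure_factor",
    "peak_wavenumber",
    "pair_correlation",
    "isf",
    "relaxation_time",
    "condensed_fraction",
]


@dataclass
class KGrid:
    """Lattice-commensurate wavevectors of a cubic box up to n_max shells."""

    box_length: float
    n_max: int = 12
    kvecs: np.ndarray = field(init=False)
    n_sq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        rng = np.arange(-self.n_max, self.n_max + 1)
        grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"),
                        axis=-1).reshape(-1, 3)
        keep = ((grid[:, 0] > 0)
                | ((grid[:, 0] == 0) & (grid[:, 1] > 0))
                | ((grid[:, 0] == 0) & (grid[:, 1] == 0) & (grid[:, 2] > 0)))
        grid = grid[keep]
        n_sq = (grid * grid).sum(axis=1)
        inside = n_sq <= self.n_max ** 2
        self.kvecs = 2.0 * np.pi / self.box_length * grid[inside]
        self.n_sq = n_sq[inside]

    @property
    def magnitudes(self) -> np.ndarray:
        return 2.0 * np.pi / self.box_length * np.sqrt(self.n_sq)

    def shell(self, k_target: float, half_width: Optional[float] = None) -> np.ndarray:
        """All legal wavevectors with | |k| - k_target | <= half-width (default pi/L)."""
        hw = half_width if half_width is not None else np.pi / self.box_length
        mags = self.magnitudes
        sel = np.abs(mags - k_target) <= hw
        if not np.any(sel):
            raise ValueError(f"no legal wavevectors near k = {k_target:.3f}")
        return self.kvecs[sel]


@dataclass
class CorrelationSeries:
    lag_times: np.ndarray
    values: np.ndarray
    k_max: float
    mode: str  # "coherent" | "incoherent"


def structure_factor(coms, box_length: float, n_max: int = 12,
                     kgrid: Optional[KGrid] = None):
    """S(k) = (1/M) < |sum_a exp(i k . R_a)|^2 > grouped by exact shell magnitude.

    ``coms`` is (n_frames, M, 3) or (M, 3).  Returns ``(k, S)`` sorted by k,
    averaged over frames and over all legal wavevectors of each magnitude.
    """
    coms = np.asarray(coms, dtype=float)
    if coms.ndim == 2:
        coms = coms[None]
    n_frames, M, _ = coms.shape
    if M < 1 or n_frames < 1:
        raise ValueError("need at least one frame with at least one ring")
    grid = kgrid or KGrid(box_length, n_max)
    phases = coms.reshape(-1, 3) @ grid.kvecs.T  # (F*M, K)
    eik = np.exp(1j * phases).reshape(n_frames, M, -1)
    rho = eik.sum(axis=1)  # (F, K)
    s_per_vec = (np.abs(rho) ** 2).mean(axis=0) / M  # (K,)
    shells = np.unique(grid.n_sq)
    k_out = 2.0 * np.pi / box_length * np.sqrt(shells)
    s_out = np.array([s_per_vec[grid.n_sq == sh].mean() for sh in shells])
    return k_out, s_out


def peak_wavenumber(k: np.ndarray, S: np.ndarray,
                    k_min: float = 0.0, k_max: Optional[float] = None) -> float:
    """Wavenumber of the maximum of S(k) within [k_min, k_max]."""
    k = np.asarray(k)
    S = np.asarray(S)
    sel = k >= k_min
    if k_max is not None:
        sel &= k <= k_max
    if not np.any(sel):
        raise ValueError("empty wavenumber window")
    return float(k[sel][np.argmax(S[sel])])


def pair_correlation(frames_a: Sequence[np.ndarray], frames_b: Sequence[np.ndarray],
                     box_length: float, bin_width: float = 0.05,
                     r_max: Optional[float] = None, same_species: bool = False):
    """Radial distribution function g(r) with ideal-gas normalisation.

    ``frames_a``/``frames_b`` are matching-length sequences of (n, 3)
    coordinate arrays.  Returns ``(r_centers, g, pair_counts)``;
    ``pair_counts`` holds the raw per-bin pair tallies summed over frames.
    """
    if r_max is None:
        r_max = 0.5 * box_length
    if r_max > 0.5 * box_length + 1e-12:
        logger.warning("r_max beyond L/2; truncating to half the box")
        r_max = 0.5 * box_length
    n_bins = int(np.floor(r_max / bin_width + 1e-9))
    edges = np.arange(n_bins + 1) * bin_width  # last edge never exceeds r_max
    r_max = edges[-1]
    counts = np.zeros(n_bins)
    n_frames = len(frames_a)
    if n_frames == 0 or n_frames != len(frames_b):
        raise ValueError("need matching, non-empty frame sequences")
    na = nb = 0
    for pa, pb in zip(frames_a, frames_b):
        pa = np.asarray(pa, dtype=float)
        pb = np.asarray(pb, dtype=float)
        na, nb = len(pa), len(pb)
        d = pa[:, None, :] - pb[None, :, :]
        d = minimum_image(d, box_length)
        r = np.sqrt((d * d).sum(axis=-1))
        if same_species:
            np.fill_diagonal(r, np.inf)
        counts += np.histogram(r[r < r_max], bins=edges)[0]
    vol = box_length ** 3
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_ideal = n_frames * na * (nb - (1 if same_species else 0)) / vol * shell
    g = np.where(n_ideal > 0, counts / n_ideal, 0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g, counts


def _shell_phases(coms: np.ndarray, kvecs: np.ndarray) -> np.ndarray:
    """exp(i k . R) with shape (n_frames, M, n_k)."""
    n_frames, M, _ = coms.shape
    phases = coms.reshape(-1, 3) @ kvecs.T
    return np.exp(1j * phases).reshape(n_frames, M, -1)


def isf(coms, times, box_length: float, k_max: float, mode: str = "incoherent",
        lags: Optional[Sequence[int]] = None, shell_half_width: Optional[float] = None,
        kgrid: Optional[KGrid] = None) -> CorrelationSeries:
    """Intermediate scattering function at the k-shell |k| ~ k_max.

    The incoherent series keeps self terms only and equals 1 at zero lag;
    the coherent series is the full double sum normalised by its zero-lag
    value.  Averaging runs over all time origins, rings and shell vectors.
    """
    coms = np.asarray(coms, dtype=float)
    times = np.asarray(times, dtype=float)
    if coms.ndim != 3 or len(coms) < 2:
        raise ValueError("need at least two frames of centre-of-mass data")
    if mode not in ("coherent", "incoherent"):
        raise ValueError(f"unknown ISF mode {mode!r}")
    n_frames, M, _ = coms.shape
    grid = kgrid or KGrid(box_length,
                          int(np.ceil((k_max + np.pi / box_length)
                                      * box_length / (2 * np.pi))) + 1)
    kvecs = grid.shell(k_max, shell_half_width)
    eik = _shell_phases(coms, kvecs)  # (F, M, K)

    if lags is None:
        raw = np.unique(np.round(np.logspace(0, np.log10(n_frames - 1),
                                             40)).astype(int))
        lags = [0] + [int(l) for l in raw if 1 <= l <= n_frames - 1]
    values = []
    used_lags = []
    for lag in lags:
        if lag >= n_frames:
            logger.warning("lag %d dropped: too few origins", lag)
            continue
        a = eik[: n_frames - lag]
        b = eik[lag:]
        if mode == "incoherent":
            corr = np.real(np.conj(a) * b).mean()
        else:
            rho_a = a.sum(axis=1)  # (origins, K)
            rho_b = b.sum(axis=1)
            corr = np.real(np.conj(rho_a) * rho_b).mean() / M
        values.append(corr)
        used_lags.append(lag)
    values = np.asarray(values, dtype=float)
    used_lags = np.asarray(used_lags)
    if mode == "coherent":
        if used_lags[0] != 0:
            raise ValueError("coherent normalisation requires lag 0")
        values = values / values[0]
    dt_frame = float(np.mean(np.diff(times)))
    return CorrelationSeries(lag_times=used_lags * dt_frame, values=values,
                             k_max=float(k_max), mode=mode)


def relaxation_time(series: CorrelationSeries, threshold: float = math.exp(-1)):
    """First crossing of the 1/e level, interpolated linearly in log time.

    Returns ``(tau_R, resolved)``; ``resolved`` is False when the series
    never drops below the threshold inside the sampled window.
    """
    t = np.asarray(series.lag_times, dtype=float)
    f = np.asarray(series.values, dtype=float)
    below = np.nonzero(f <= threshold)[0]
    if len(below) == 0:
        return None, False
    idx = below[0]
    if idx == 0:
        return float(t[0]), True
    t1, t2 = t[idx - 1], t[idx]
    f1, f2 = f[idx - 1], f[idx]
    if np.any(np.diff((f[: idx + 1] > threshold).astype(int)) > 0):
        logger.warning("non-monotone crossing region; first crossing taken")
    frac = (f1 - threshold) / (f1 - f2)
    if t1 <= 0:
        return float(t1 + frac * (t2 - t1)), True
    return float(math.exp(math.log(t1) + frac * (math.log(t2) - math.log(t1)))), True


def condensed_fraction(frames: Sequence[Configuration], shell: float,
                       ion_species: Optional[Sequence[int]] = None) -> dict:
    """Time-averaged fraction of each ion species within ``shell`` of a monomer."""
    if shell <= 0:
        raise ValueError("shell width must be positive")
    totals: dict = {}
    counts: dict = {}
    for config in frames:
        L = config.box_length
        mono = np.mod(config.positions[config.species == MONOMER], L)
        if len(mono) == 0:
            raise ValueError("no monomers in configuration")
        tree = cKDTree(mono, boxsize=L)
        species_present = (np.unique(config.species[config.species != MONOMER])
                           if ion_species is None else ion_species)
        for sp in species_present:
            ions = np.mod(config.positions[config.species == sp], L)
            if len(ions) == 0:
                continue
            d, _ = tree.query(ions, k=1)
            totals[sp] = totals.get(sp, 0) + int(np.sum(d <= shell))
            counts[sp] = counts.get(sp, 0) + len(ions)
    return {int(sp): totals[sp] / counts[sp] for sp in totals}
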