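"""Langevin dynamics engine, initialisation and the compression protocol.

The integrator is velocity Verlet with Langevin friction and noise: the
random force has zero mean and variance 2 gamma m k_B T / dt per Cartesian
component per step, so that with the friction term the canonical ensemble
at temperature T is sampled.  Setting ``gamma = 0`` recovers plain NVE
velocity Verlet (used by the energy-drift checks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from . import electrostatics as es
from .model import (MONOMER, ION_MONO, ION_TRI, Configuration, ForceField,
                    OverstretchedBondError, RingTopology, minimum_image)

__all__ = [
    "RunProtocol",
    "Trajectory",
    "SimulationDivergedError",
    "ion_counts",
    "density_to_box",
    "make_ring_polygon",
    "initialize_lattice",
    "compress_step",
    "run_langevin",
    "run_protocol",
]


class SimulationDivergedError(RuntimeError):
    """Raised when the integrator produces non-finite coordinates."""


@dataclass
class RunProtocol:
    """Parameters of a full simulation run (desk-scale defaults)."""

    M_rings: int = 27
    N_monomers: int = 50
    ion_scenario: str = "none"  # {mono_only, tri_only, mixed, none}
    target_density: float = 0.1
    initial_box: Optional[float] = None
    compress_block: float = 5e3
    equil_time: float = 3e5
    production_time: float = 1e6
    dump_interval: float = 1e3
    seed: int = 0
    electro_mode: str = "off"  # {off, explicit, debye_huckel}
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.target_density <= 0:
            raise ValueError("target_density must be positive")
        if self.ion_scenario not in ("mono_only", "tri_only", "mixed", "none"):
            raise ValueError(f"unknown ion scenario {self.ion_scenario!r}")
        n_dumps = self.production_time / self.dump_interval
        if abs(n_dumps - round(n_dumps)) > 1e-9:
            raise ValueError("dump_interval must divide production_time")


@dataclass
class Trajectory:
    """Ordered snapshots with the topology and protocol that produced them."""

    frames: list
    topology: RingTopology
    protocol: Optional[RunProtocol] = None

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def box_length(self) -> float:
        return self.frames[0].box_length


def ion_counts(M: int, N: int, scenario: str) -> tuple[int, int]:
    """Counterion counts (monovalent, trivalent) that neutralise M rings of N (-3e) beads."""
    if M <= 0 or N <= 0:
        raise ValueError("M and N must be positive")
    if scenario == "mono_only":
        return 3 * N * M, 0
    if scenario == "tri_only":
        return 0, N * M
    if scenario == "mixed":
        if (N * M) % 2:
            raise ValueError("mixed scenario requires N*M even")
        return 3 * N * M // 2, N * M // 2
    if scenario == "none":
        return 0, 0
    raise ValueError(f"unknown ion scenario {scenario!r}")


def density_to_box(M: int, N: int, density: float) -> float:
    """Box edge L = (N M / rho)^(1/3); only monomers count toward rho."""
    if density <= 0:
        raise ValueError("density must be positive")
    return (N * M / density) ** (1.0 / 3.0)


def make_ring_polygon(N: int, bond_length: float = 0.96) -> np.ndarray:
    """Regular N-gon in the xy-plane, centred at the origin.

    Circumradius is b / (2 sin(pi / N)).
    """
    if N < 3:
        raise ValueError("a ring needs at least 3 monomers")
    radius = bond_length / (2.0 * math.sin(math.pi / N))
    theta = 2.0 * math.pi * np.arange(N) / N
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                            np.zeros(N)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def initialize_lattice(M: int, N: int, box: float, seed: int,
                       ff: Optional[ForceField] = None,
                       ion_scenario: str = "none",
                       bond_length: float = 0.96,
                       charged: bool = True):
    """Planar rings on a primitive cubic lattice plus randomly placed ions.

    Rings are regular polygons with random orientations placed at lattice
    sites whose spacing exceeds the ring diameter, which guarantees the
    initial state is unknotted and non-concatenated.  Ions are inserted
    uniformly at random, rejecting hard overlaps.
    """
    ff = ff or ForceField()
    rng = np.random.default_rng(seed)
    n_side = int(math.ceil(M ** (1.0 / 3.0)))
    spacing = box / n_side
    radius = bond_length / (2.0 * math.sin(math.pi / N))
    if spacing < 2.0 * radius * 1.02:
        raise ValueError(
            f"box too small for non-concatenation guarantee: lattice spacing "
            f"{spacing:.2f} < ring diameter {2 * radius:.2f}")

    template = make_ring_polygon(N, bond_length)
    sites = []
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                sites.append((ix, iy, iz))
    rng.shuffle(sites)
    positions = []
    rings = []
    for m in range(M):
        center = (np.array(sites[m], dtype=float) + 0.5) * spacing
        rot = _random_rotation(rng)
        positions.append(template @ rot.T + center)
        rings.append(np.arange(m * N, (m + 1) * N))
    positions = np.concatenate(positions)
    topo = RingTopology(rings)

    n_mono, n_tri = ion_counts(M, N, ion_scenario)
    species = [np.full(N * M, MONOMER)]
    if n_mono or n_tri:
        ion_species = np.concatenate([np.full(n_mono, ION_MONO),
                                      np.full(n_tri, ION_TRI)])
        ion_pos = _place_ions(positions, len(ion_species), box, ff, rng)
        positions = np.concatenate([positions, ion_pos])
        species.append(ion_species)
    species = np.concatenate(species)

    if charged:
        charge_of = {MONOMER: ff.z_mon, ION_MONO: ff.z_ion_mono,
                     ION_TRI: ff.z_ion_tri}
        charges = np.array([charge_of[s] for s in species], dtype=float)
    else:
        charges = np.zeros(len(species))
    config = Configuration(positions, species, charges, box, time=0.0)
    return config, topo


def _place_ions(monomer_pos: np.ndarray, n_ions: int, box: float,
                ff: ForceField, rng: np.random.Generator) -> np.ndarray:
    min_dist = 0.9 * ff.contact_distance(MONOMER, ION_MONO)
    accepted = np.empty((0, 3))
    guard = 0
    while len(accepted) < n_ions:
        guard += 1
        if guard > 200:
            raise RuntimeError("ion placement failed: box too crowded")
        batch = rng.uniform(0.0, box, size=(max(n_ions, 256), 3))
        ref = np.concatenate([monomer_pos, accepted]) if len(accepted) else monomer_pos
        tree = cKDTree(np.mod(ref, box), boxsize=box)
        d, _ = tree.query(np.mod(batch, box), k=1)
        ok = batch[d > min_dist]
        # also avoid intra-batch overlaps, cheaply: thin the batch
        accepted = np.concatenate([accepted, ok])[:n_ions]
    return accepted


# ---------------------------------------------------------------------------
# force engine
# ---------------------------------------------------------------------------

class _ForceEngine:
    """Caches species-dependent tables for repeated force evaluations."""

    def __init__(self, config: Configuration, topo: RingTopology, ff: ForceField,
                 electro_mode: str = "off", solver=None,
                 dh_screening_length: Optional[float] = None,
                 ewald_accuracy: float = 1e-4):
        self.ff = ff
        self.box = config.box_length
        self.topo = topo
        self.radii = np.where(config.species == MONOMER, ff.sigma_mon,
                              ff.sigma_ion).astype(float)
        self.bonds = topo.bonds()
        self.triples = topo.angles()
        self.charges = config.charges.copy()
        self.electro_mode = electro_mode
        self.solver = None
        if electro_mode != "off" and np.any(self.charges):
            if solver is not None:
                self.solver = solver
            elif electro_mode == "explicit":
                self.solver = es.EwaldSolver(self.box, ff.bjerrum,
                                             accuracy=ewald_accuracy)
            elif electro_mode == "debye_huckel":
                lam = dh_screening_length or 1.0
                self.solver = es.YukawaSolver(self.box, ff.bjerrum,
                                              screening_length=lam)
            else:
                raise ValueError(f"unknown electro_mode {electro_mode!r}")

    def forces(self, positions: np.ndarray) -> np.ndarray:
        ff = self.ff
        L = self.box
        if isinstance(self.solver, es.EwaldSolver):
            cmode = _kernels.COULOMB_EWALD_REAL
            alpha, screening, rcut = self.solver.alpha, 1.0, self.solver.r_cut
        elif isinstance(self.solver, es.YukawaSolver):
            cmode = _kernels.COULOMB_YUKAWA
            alpha, screening, rcut = 0.0, self.solver.screening_length, self.solver.r_cut
        else:
            cmode = _kernels.COULOMB_NONE
            alpha, screening, rcut = 0.0, 1.0, 0.0
        forces = _kernels.nonbonded_forces(
            positions, self.radii, self.charges, L, ff.epsilon, ff.bjerrum,
            cmode, alpha, screening, rcut)

        if len(self.bonds):
            bd = positions[self.bonds[:, 1]] - positions[self.bonds[:, 0]]
            bd -= L * np.round(bd / L)
            b2 = (bd * bd).sum(axis=1)
            if np.any(b2 >= ff.r0_fene ** 2):
                raise OverstretchedBondError("FENE bond reached maximal extension")
            coef = ff.k_fene / (1.0 - b2 / ff.r0_fene ** 2)  # -f(b)/b
            fvec = coef[:, None] * bd  # force on bonds[:,0] (attractive toward j)
            np.add.at(forces, self.bonds[:, 0], fvec)
            np.add.at(forces, self.bonds[:, 1], -fvec)

        if len(self.triples):
            t = self.triples
            u = positions[t[:, 1]] - positions[t[:, 0]]
            u -= L * np.round(u / L)
            v = positions[t[:, 2]] - positions[t[:, 1]]
            v -= L * np.round(v / L)
            nu = np.sqrt((u * u).sum(axis=1))
            nv = np.sqrt((v * v).sum(axis=1))
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            cosphi = np.clip((uh * vh).sum(axis=1), -1.0, 1.0)
            dcos_du = (vh - cosphi[:, None] * uh) / nu[:, None]
            dcos_dv = (uh - cosphi[:, None] * vh) / nv[:, None]
            k = ff.k_bend
            np.add.at(forces, t[:, 0], -k * dcos_du)
            np.add.at(forces, t[:, 1], k * (dcos_du - dcos_dv))
            np.add.at(forces, t[:, 2], k * dcos_dv)

        if isinstance(self.solver, es.EwaldSolver):
            forces += self.solver.recip_forces(positions, self.charges)
        return forces


def run_langevin(config: Configuration, topo: RingTopology, ff: ForceField,
                 electro_mode: str = "off", duration: float = 1.0,
                 seed: int = 0, dump_interval: Optional[float] = None,
                 temperature: float = 1.0, gamma: Optional[float] = None,
                 velocities: Optional[np.ndarray] = None,
                 solver=None, dh_screening_length: Optional[float] = None,
                 return_velocities: bool = False):
    """Integrate Langevin dynamics for ``duration`` (in tau) and dump snapshots.

    Snapshots are recorded at t = 0 and every ``dump_interval`` thereafter
    (default: only first and last frame).  Identical seeds reproduce
    trajectories bit-for-bit.
    """
    dt = ff.dt
    n_steps = int(round(duration / dt))
    if dump_interval is None:
        dump_every = max(n_steps, 1)
    else:
        dump_every = max(int(round(dump_interval / dt)), 1)
    gamma = ff.gamma if gamma is None else gamma
    m = ff.mass
    rng = np.random.default_rng(seed)

    engine = _ForceEngine(config, topo, ff, electro_mode, solver,
                          dh_screening_length)
    x = config.positions.astype(float).copy()
    if velocities is None:
        if temperature > 0 and gamma > 0:
            v = rng.normal(0.0, math.sqrt(temperature / m), size=x.shape)
        else:
            v = np.zeros_like(x)
    else:
        v = np.asarray(velocities, dtype=float).copy()

    # Gronbech-Jensen/Farago parametrisation of Langevin velocity Verlet:
    # impulse variance 2 gamma m kT dt (i.e. force variance 2 gamma m kT/dt),
    # exact configurational statistics for harmonic modes at finite dt,
    # and plain symplectic velocity Verlet when gamma = 0.
    noise_sigma = math.sqrt(2.0 * gamma * m * temperature * dt) if (
        gamma > 0 and temperature > 0) else 0.0
    gdth = 0.5 * gamma * dt / m
    a_coef = (1.0 - gdth) / (1.0 + gdth)
    b_coef = 1.0 / (1.0 + gdth)

    frames = [Configuration(x.copy(), config.species.copy(),
                            config.charges.copy(), config.box_length,
                            config.time)]
    f = engine.forces(x)
    for step in range(1, n_steps + 1):
        beta = rng.normal(0.0, noise_sigma, size=x.shape) if noise_sigma else 0.0
        x = x + b_coef * dt * v + b_coef * dt * dt / (2.0 * m) * f \
            + b_coef * dt / (2.0 * m) * beta
        f_new = engine.forces(x)
        v = a_coef * v + dt / (2.0 * m) * (a_coef * f + f_new) \
            + b_coef / m * beta
        f = f_new
        if step % dump_every == 0 or step == n_steps:
            if not np.all(np.isfinite(x)):
                raise SimulationDivergedError(
                    f"non-finite coordinates at step {step} "
                    f"(t = {config.time + step * dt:.3f} tau)")
            frames.append(Configuration(
                x.copy(), config.species.copy(), config.charges.copy(),
                config.box_length, config.time + step * dt))
    traj = Trajectory(frames, topo)
    if return_velocities:
        return traj, v
    return traj


def compress_step(config: Configuration, topo: RingTopology, ff: ForceField,
                  block_time: float = 5e3, electro_mode: str = "off",
                  seed: int = 0, temperature: float = 1.0,
                  dh_screening_length: Optional[float] = None) -> Configuration:
    """Shrink the box edge by one sigma, rescale coordinates affinely and relax.

    Coordinates are multiplied by 1 - sigma/L before a dynamics block of
    ``block_time`` tau is run at the new box size.
    """
    L = config.box_length
    new_L = L - ff.sigma_mon
    if new_L <= 0:
        raise ValueError("box cannot shrink below zero")
    factor = 1.0 - ff.sigma_mon / L
    scaled = Configuration(config.positions * factor, config.species,
                           config.charges, new_L, config.time)
    # scaling shrinks bonds, but verify nothing is overstretched regardless
    bonds = topo.bonds()
    bd = minimum_image(scaled.positions[bonds[:, 1]] - scaled.positions[bonds[:, 0]], new_L)
    if np.any((bd * bd).sum(axis=1) >= ff.r0_fene ** 2):
        raise OverstretchedBondError("compression produced an overstretched bond")
    if block_time <= 0:
        return scaled
    traj = run_langevin(scaled, topo, ff, electro_mode, duration=block_time,
                        seed=seed, temperature=temperature,
                        dh_screening_length=dh_screening_length)
    return traj.frames[-1]


def run_protocol(protocol: RunProtocol, ff: Optional[ForceField] = None,
                 bond_length: float = 0.96, charged: bool = True,
                 dh_screening_length: Optional[float] = None) -> Trajectory:
    """Full schedule: lattice init, stepwise compression, equilibration, production."""
    ff = ff or ForceField()
    M, N = protocol.M_rings, protocol.N_monomers
    target_L = density_to_box(M, N, protocol.target_density)
    if protocol.initial_box is not None:
        L0 = protocol.initial_box
    else:
        n_side = math.ceil(M ** (1.0 / 3.0))
        diameter = bond_length / math.sin(math.pi / N)
        L0 = max(target_L, n_side * diameter * 1.05)
        L0 = math.ceil(L0)
    config, topo = initialize_lattice(M, N, L0, protocol.seed, ff,
                                      protocol.ion_scenario, bond_length,
                                      charged=charged)
    seed = protocol.seed
    # initial relaxation block at L0
    if protocol.compress_block > 0:
        config = run_langevin(config, topo, ff, protocol.electro_mode,
                              duration=protocol.compress_block, seed=seed,
                              temperature=protocol.temperature,
                              dh_screening_length=dh_screening_length).frames[-1]
    while config.box_length - ff.sigma_mon >= target_L - 1e-9:
        seed += 1
        config = compress_step(config, topo, ff, protocol.compress_block,
                               protocol.electro_mode, seed=seed,
                               temperature=protocol.temperature,
                               dh_screening_length=dh_screening_length)
    if config.box_length > target_L + 1e-9:
        # final fractional rescale to hit the target density exactly
        factor = target_L / config.box_length
        config = Configuration(config.positions * factor, config.species,
                               config.charges, target_L, config.time)
    if protocol.equil_time > 0:
        seed += 1
        config = run_langevin(config, topo, ff, protocol.electro_mode,
                              duration=protocol.equil_time, seed=seed,
                              temperature=protocol.temperature,
                              dh_screening_length=dh_screening_length).frames[-1]
    config = Configuration(config.positions, config.species, config.charges,
                           config.box_length, time=0.0)
    traj = run_langevin(config, topo, ff, protocol.electro_mode,
                        duration=protocol.production_time, seed=seed + 1,
                        dump_interval=protocol.dump_interval,
                        temperature=protocol.temperature,
                        dh_screening_length=dh_screening_length)
    traj.protocol = protocol
    return traj
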