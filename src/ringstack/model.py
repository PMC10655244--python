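"""Domain types and interaction potentials of the coarse-grained charged ring model.

All quantities are expressed in reduced units: the monomer diameter sigma
(= 1 nm) sets the length scale, k_B T the energy scale and the monomer mass
the mass scale, so that the intrinsic time unit is tau = sigma * sqrt(m / k_B T).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import constants as _const

__all__ = [
    "MONOMER",
    "ION_MONO",
    "ION_TRI",
    "SPECIES_NAMES",
    "ForceField",
    "Configuration",
    "RingTopology",
    "EnergyBreakdown",
    "InvalidGeometryError",
    "OverstretchedBondError",
    "wca_energy",
    "wca_force_magnitude",
    "fene_energy",
    "fene_force_magnitude",
    "bend_energy",
    "coulomb_energy",
    "total_energy",
    "total_forces",
    "minimum_image",
    "bjerrum_length",
    "contour_charge_density",
    "manning_parameter",
]

# Species codes used in Configuration.species
MONOMER = 0
ION_MONO = 1
ION_TRI = 2
SPECIES_NAMES = {MONOMER: "M", ION_MONO: "I1", ION_TRI: "I3"}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}

_WCA_CUT = 2.0 ** (1.0 / 6.0)


class InvalidGeometryError(ValueError):
    """Raised for non-physical geometry (non-positive distances, ...)."""


class OverstretchedBondError(ValueError):
    """Raised when a FENE bond reaches or exceeds its maximal extension R0."""


@dataclass
class ForceField:
    """All interaction and integrator parameters of the microscopic model.

    Defaults correspond to the reference parametrisation of the model:
    unit-size monomers of charge number -3 (three nucleotides per bead),
    small counterions of diameter 0.355 sigma, FENE bonds with
    K = 30 kT/sigma^2 and R0 = 1.5 sigma, bending constant 30 kT and a
    Bjerrum length of 0.71 sigma (aqueous solvent at room temperature).
    """

    epsilon: float = 1.0
    sigma_mon: float = 1.0
    sigma_ion: float = 0.355
    k_fene: float = 30.0
    r0_fene: float = 1.5
    k_bend: float = 30.0
    bjerrum: float = 0.71
    z_mon: int = -3
    z_ion_mono: int = 1
    z_ion_tri: int = 3
    gamma: float = 1.0
    mass: float = 1.0
    dt: float = 0.005

    def __post_init__(self) -> None:
        for name in ("epsilon", "sigma_mon", "sigma_ion", "k_fene", "r0_fene",
                     "k_bend", "bjerrum", "gamma", "mass", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ForceField.{name} must be positive")
        if self.r0_fene <= self.contact_distance(MONOMER, MONOMER) * 0.5:
            raise ValueError("R0 must exceed pairwise contact distances")

    # -- species geometry -------------------------------------------------
    def species_diameter(self, species: int) -> float:
        return self.sigma_mon if species == MONOMER else self.sigma_ion

    def contact_distance(self, species_a: int, species_b: int) -> float:
        """Lorentz-Berthelot cross diameter (sigma_a + sigma_b) / 2."""
        return 0.5 * (self.species_diameter(species_a) + self.species_diameter(species_b))

    def species_charge(self, species: int) -> int:
        return {MONOMER: self.z_mon, ION_MONO: self.z_ion_mono,
                ION_TRI: self.z_ion_tri}[species]

    # -- serialisation -----------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ForceField":
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            ftypes = {f.name: f.type for f in dataclasses.fields(cls)}
            if key not in ftypes:
                raise KeyError(f"unknown force-field key {key!r}")
            caster = int if ftypes[key] == "int" else float
            kwargs[key] = caster(value.strip())
        return cls(**kwargs)


@dataclass
class Configuration:
    """One snapshot: positions, species labels, charges, box and time stamp."""

    positions: np.ndarray
    species: np.ndarray
    charges: np.ndarray
    box_length: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species, dtype=np.int64)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        n = len(self.positions)
        if len(self.species) != n or len(self.charges) != n:
            raise ValueError("species/charges length mismatch")
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.positions, self.box_length)

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.species.copy(),
                             self.charges.copy(), self.box_length, self.time)


@dataclass
class RingTopology:
    """Monomer index lists of the M rings, in cyclic bonding order.

    ``closed`` distinguishes rings (cyclic bonds) from open chains and may
    be a single flag or one flag per molecule; open chains are used by
    single-molecule reference measurements (persistence-length fit) and by
    rod-threading test scenes.
    """

    rings: list
    closed: bool | Sequence[bool] = True

    def __post_init__(self) -> None:
        self.rings = [np.asarray(r, dtype=np.int64) for r in self.rings]
        flat = np.concatenate(self.rings) if self.rings else np.empty(0, dtype=np.int64)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("ring index lists must be disjoint")
        if not isinstance(self.closed, (bool, np.bool_)):
            self.closed = list(self.closed)
            if len(self.closed) != len(self.rings):
                raise ValueError("need one closed flag per ring")

    def is_closed(self, i: int) -> bool:
        if isinstance(self.closed, (bool, np.bool_)):
            return bool(self.closed)
        return bool(self.closed[i])

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @property
    def n_monomers(self) -> int:
        return int(sum(len(r) for r in self.rings))

    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) bonded index pairs along every ring."""
        out = []
        for i, ring in enumerate(self.rings):
            pairs = np.column_stack([ring, np.roll(ring, -1)])
            if not self.is_closed(i):
                pairs = pairs[:-1]
            out.append(pairs)
        return np.concatenate(out) if out else np.empty((0, 2), dtype=np.int64)

    def angles(self) -> np.ndarray:
        """(n_angles, 3) consecutive index triples (i, j, k) along every ring."""
        out = []
        for i, ring in enumerate(self.rings):
            trip = np.column_stack([ring, np.roll(ring, -1), np.roll(ring, -2)])
            if not self.is_closed(i):
                trip = trip[:-2]
            out.append(trip)
        return np.concatenate(out) if out else np.empty((0, 3), dtype=np.int64)


@dataclass
class EnergyBreakdown:
    wca: float = 0.0
    fene: float = 0.0
    bend: float = 0.0
    electrostatic: float = 0.0

    @property
    def total(self) -> float:
        return self.wca + self.fene + self.bend + self.electrostatic


# ---------------------------------------------------------------------------
# pair potentials
# ---------------------------------------------------------------------------

def wca_energy(r, sigma_pair: float = 1.0, epsilon: float = 1.0):
    """Purely repulsive cut-and-shifted Lennard-Jones (WCA) energy.

    Returns 4 eps [(s/r)^12 - (s/r)^6] + eps for r < 2^(1/6) s and exactly
    zero beyond; the shift makes the energy continuous at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidGeometryError("interparticle distance must be positive")
    sr6 = (sigma_pair / r) ** 6
    e = np.where(r < _WCA_CUT * sigma_pair, 4.0 * epsilon * (sr6 * sr6 - sr6) + epsilon, 0.0)
    return float(e) if e.ndim == 0 else e


def wca_force_magnitude(r, sigma_pair: float = 1.0, epsilon: float = 1.0):
    """|dE/dr| signed as the radial force f(r) = -dE/dr (repulsive: > 0)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidGeometryError("interparticle distance must be positive")
    sr6 = (sigma_pair / r) ** 6
    f = np.where(r < _WCA_CUT * sigma_pair, 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r, 0.0)
    return float(f) if f.ndim == 0 else f


def fene_energy(b, k: float = 30.0, r0: float = 1.5):
    """Finitely extensible nonlinear elastic bond energy -K R0^2/2 ln(1-(b/R0)^2)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise InvalidGeometryError("bond length must be non-negative")
    if np.any(b >= r0):
        raise OverstretchedBondError(f"bond length >= R0 = {r0}")
    e = -0.5 * k * r0 * r0 * np.log1p(-((b / r0) ** 2))
    return float(e) if e.ndim == 0 else e


def fene_force_magnitude(b, k: float = 30.0, r0: float = 1.5):
    """Radial bond force f(b) = -dE/db = -K b / (1 - (b/R0)^2) (restoring: < 0)."""
    b = np.asarray(b, dtype=float)
    if np.any(b >= r0):
        raise OverstretchedBondError(f"bond length >= R0 = {r0}")
    f = -k * b / (1.0 - (b / r0) ** 2)
    return float(f) if f.ndim == 0 else f


def bend_energy(phi, k_bend: float = 30.0):
    """Harmonic-cosine bending energy K (1 - cos phi).

    ``phi`` is the angle between consecutive bond vectors, so a straight
    continuation (phi = 0) costs nothing and a full back-fold costs 2 K.
    """
    phi = np.asarray(phi, dtype=float)
    e = k_bend * (1.0 - np.cos(phi))
    return float(e) if e.ndim == 0 else e


def coulomb_energy(r, z_i, z_j, bjerrum: float = 0.71):
    """Unscreened Coulomb pair energy l_B z_i z_j / r in k_B T units."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidGeometryError("interparticle distance must be positive")
    e = bjerrum * np.asarray(z_i, dtype=float) * np.asarray(z_j, dtype=float) / r
    return float(e) if e.ndim == 0 else e


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def minimum_image(d: np.ndarray, box_length: float) -> np.ndarray:
    """Wrap displacement vectors into the nearest periodic image."""
    return d - box_length * np.round(d / box_length)


def bjerrum_length(temperature: float = 298.0, eps_r: float = 78.5) -> float:
    """Bjerrum length e^2/(4 pi eps0 eps_r kB T) in nanometres."""
    lb = _const.e ** 2 / (4.0 * np.pi * _const.epsilon_0 * eps_r
                          * _const.k * temperature)
    return lb * 1e9


def contour_charge_density(ff: ForceField) -> float:
    """Bare line charge density of the ring contour, in e per sigma (= e/nm)."""
    return abs(ff.z_mon) / ff.sigma_mon


def manning_parameter(ff: ForceField, valence: int) -> float:
    """Condensation parameter xi = valence * line-charge-density * l_B."""
    return valence * contour_charge_density(ff) * ff.bjerrum


# ---------------------------------------------------------------------------
# total energy / forces
# ---------------------------------------------------------------------------

def _pair_tables(config: Configuration, ff: ForceField):
    """Full minimum-image displacement/distance matrices and pair diameters."""
    pos = config.positions
    d = pos[:, None, :] - pos[None, :, :]
    d = minimum_image(d, config.box_length)
    r = np.sqrt((d * d).sum(axis=-1))
    radii = np.where(config.species == MONOMER, ff.sigma_mon, ff.sigma_ion)
    sig = 0.5 * (radii[:, None] + radii[None, :])
    return d, r, sig


def _wca_pair_energy_matrix(r, sig, eps):
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = (sig / r) ** 6
        e = np.where(r < _WCA_CUT * sig, 4.0 * eps * (sr6 * sr6 - sr6) + eps, 0.0)
    np.fill_diagonal(e, 0.0)
    return e


def _bond_geometry(config: Configuration, topo: RingTopology):
    bonds = topo.bonds()
    d = config.positions[bonds[:, 1]] - config.positions[bonds[:, 0]]
    d = minimum_image(d, config.box_length)
    return bonds, d, np.linalg.norm(d, axis=1)


def _angle_geometry(config: Configuration, topo: RingTopology):
    trip = topo.angles()
    u = minimum_image(config.positions[trip[:, 1]] - config.positions[trip[:, 0]],
                      config.box_length)
    v = minimum_image(config.positions[trip[:, 2]] - config.positions[trip[:, 1]],
                      config.box_length)
    return trip, u, v


def total_energy(config: Configuration, topo: RingTopology, ff: ForceField,
                 electro_mode: str = "off", electrostatics=None) -> EnergyBreakdown:
    """Per-term energy breakdown of a configuration.

    WCA uses the minimum-image convention with Lorentz-Berthelot mixing;
    FENE and bending act only along each ring's (cyclic) bond sequence.
    ``electro_mode`` is one of {"off", "explicit", "debye_huckel"}; for the
    charged modes an electrostatics solver from
    :mod:`ringstack.electrostatics` is constructed unless one is supplied.
    """
    _, r, sig = _pair_tables(config, ff)
    e_wca = 0.5 * float(_wca_pair_energy_matrix(r, sig, ff.epsilon).sum())

    _, _, blen = _bond_geometry(config, topo)
    e_fene = float(np.sum(fene_energy(blen, ff.k_fene, ff.r0_fene))) if len(blen) else 0.0

    _, u, v = _angle_geometry(config, topo)
    if len(u):
        cosphi = (u * v).sum(axis=1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        e_bend = float(np.sum(ff.k_bend * (1.0 - np.clip(cosphi, -1.0, 1.0))))
    else:
        e_bend = 0.0

    e_el = 0.0
    if electro_mode != "off" and np.any(config.charges != 0):
        solver = electrostatics or _default_solver(config, ff, electro_mode)
        e_el = solver.energy(config.positions, config.charges)

    return EnergyBreakdown(wca=e_wca, fene=e_fene, bend=e_bend, electrostatic=e_el)


def _default_solver(config: Configuration, ff: ForceField, electro_mode: str):
    from . import electrostatics as es
    if electro_mode == "explicit":
        return es.EwaldSolver(config.box_length, ff.bjerrum)
    if electro_mode == "debye_huckel":
        return es.YukawaSolver(config.box_length, ff.bjerrum)
    raise ValueError(f"unknown electro_mode {electro_mode!r}")


def total_forces(config: Configuration, topo: RingTopology, ff: ForceField,
                 electro_mode: str = "off", electrostatics=None) -> np.ndarray:
    """Deterministic forces -dE/dx on every particle, shape (n, 3)."""
    d, r, sig = _pair_tables(config, ff)
    np.fill_diagonal(r, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = (sig / r) ** 6
        fmag = np.where(r < _WCA_CUT * sig, 24.0 * ff.epsilon * (2.0 * sr6 * sr6 - sr6) / r, 0.0)
    # force on i from j acts along +d_ij = r_i - r_j
    forces = ((fmag / r)[:, :, None] * d).sum(axis=1)

    bonds, bd, blen = _bond_geometry(config, topo)
    if len(bonds):
        f = fene_force_magnitude(blen, ff.k_fene, ff.r0_fene)  # negative (restoring)
        fvec = (f / blen)[:, None] * (-bd)  # force on bond[:,0]
        np.add.at(forces, bonds[:, 0], fvec)
        np.add.at(forces, bonds[:, 1], -fvec)

    trip, u, v = _angle_geometry(config, topo)
    if len(trip):
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cosphi = np.clip((uh * vh).sum(axis=1), -1.0, 1.0)
        # E = K (1 - cos phi); dE/du = -K d(cos)/du etc.
        dcos_du = (vh - cosphi[:, None] * uh) / nu[:, None]
        dcos_dv = (uh - cosphi[:, None] * vh) / nv[:, None]
        k = ff.k_bend
        # u = r_j - r_i, v = r_k - r_j
        np.add.at(forces, trip[:, 0], -k * dcos_du)
        np.add.at(forces, trip[:, 1], k * (dcos_du - dcos_dv))
        np.add.at(forces, trip[:, 2], k * dcos_dv)

    if electro_mode != "off" and np.any(config.charges != 0):
        solver = electrostatics or _default_solver(config, ff, electro_mode)
        forces = forces + solver.forces(config.positions, config.charges)

    return forces
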