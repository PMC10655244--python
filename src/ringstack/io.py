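"""Trajectory readers/writers (extended XYZ, LAMMPS text dump, native HDF5)
and the run manifest.

Native files store coordinates unwrapped together with box metadata; the
LAMMPS dump dialect (``id type q x y z`` with box bounds) wraps
coordinates into the primary box on export.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from . import __version__
from .dynamics import RunProtocol, Trajectory
from .model import SPECIES_CODES, SPECIES_NAMES, Configuration, RingTopology

__all__ = [
    "TrajectoryFormatError",
    "write_xyz",
    "read_xyz",
    "write_lammps_dump",
    "read_lammps_dump",
    "write_native",
    "read_native",
    "read_trajectory",
    "write_trajectory",
    "RunManifest",
]


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file; the message names the offending frame."""


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_xyz(traj_or_frames, path) -> None:
    frames = getattr(traj_or_frames, "frames", traj_or_frames)
    lines = []
    for config in frames:
        L = config.box_length
        lines.append(str(config.n_particles))
        lines.append(
            f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
            f'Properties=species:S:1:pos:R:3:charge:R:1 Time={float(config.time)!r}')
        for pos, sp, q in zip(config.positions, config.species, config.charges):
            name = SPECIES_NAMES[int(sp)]
            lines.append(f"{name} {float(pos[0])!r} {float(pos[1])!r} {float(pos[2])!r} {float(q)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> list:
    text = Path(path).read_text().splitlines()
    frames = []
    i = 0
    frame_idx = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            n = int(text[i].strip())
            comment = text[i + 1]
            box = _parse_lattice(comment)
            time = _parse_keyval(comment, "Time", default=float(frame_idx))
            rows = text[i + 2: i + 2 + n]
            if len(rows) < n:
                raise ValueError("truncated frame")
            species, positions, charges = [], [], []
            for row in rows:
                parts = row.split()
                species.append(SPECIES_CODES[parts[0]])
                positions.append([float(v) for v in parts[1:4]])
                charges.append(float(parts[4]) if len(parts) > 4 else 0.0)
            frames.append(Configuration(np.array(positions), np.array(species),
                                        np.array(charges), box, time))
        except Exception as exc:
            raise TrajectoryFormatError(
                f"malformed XYZ frame {frame_idx} in {path}: {exc}") from exc
        i += 2 + n
        frame_idx += 1
    return frames


def _parse_lattice(comment: str) -> float:
    start = comment.index('Lattice="') + len('Lattice="')
    vals = [float(v) for v in comment[start: comment.index('"', start)].split()]
    return vals[0]


def _parse_keyval(comment: str, key: str, default: float) -> float:
    token = key + "="
    if token not in comment:
        return default
    tail = comment.split(token, 1)[1].split()[0]
    return float(tail.strip('"'))


# ---------------------------------------------------------------------------
# LAMMPS text dump (id type q x y z)
# ---------------------------------------------------------------------------

def write_lammps_dump(traj_or_frames, path, dt: float = 0.005) -> None:
    frames = getattr(traj_or_frames, "frames", traj_or_frames)
    lines = []
    for config in frames:
        L = config.box_length
        wrapped = config.wrapped_positions()
        lines += ["ITEM: TIME", repr(float(config.time)),
                  "ITEM: TIMESTEP", str(int(round(config.time / dt))),
                  "ITEM: NUMBER OF ATOMS", str(config.n_particles),
                  "ITEM: BOX BOUNDS pp pp pp",
                  f"0.0 {float(L)!r}", f"0.0 {float(L)!r}", f"0.0 {float(L)!r}",
                  "ITEM: ATOMS id type q x y z"]
        for idx, (pos, sp, q) in enumerate(
                zip(wrapped, config.species, config.charges), start=1):
            lines.append(f"{idx} {int(sp) + 1} {float(q)!r} "
                         f"{float(pos[0])!r} {float(pos[1])!r} {float(pos[2])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lammps_dump(path) -> list:
    text = Path(path).read_text().splitlines()
    frames = []
    i = 0
    frame_idx = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            time = None
            if text[i].startswith("ITEM: TIME") and "TIMESTEP" not in text[i]:
                time = float(text[i + 1])
                i += 2
            if not text[i].startswith("ITEM: TIMESTEP"):
                raise ValueError(f"expected TIMESTEP item, got {text[i]!r}")
            step = int(text[i + 1])
            if time is None:
                time = float(step)
            assert text[i + 2].startswith("ITEM: NUMBER OF ATOMS")
            n = int(text[i + 3])
            assert text[i + 4].startswith("ITEM: BOX BOUNDS")
            lo, hi = (float(v) for v in text[i + 5].split()[:2])
            box = hi - lo
            header = text[i + 8].split()[2:]
            rows = text[i + 9: i + 9 + n]
            if len(rows) < n:
                raise ValueError("truncated frame")
            cols = {name: header.index(name) for name in header}
            data = np.array([[float(v) for v in row.split()] for row in rows])
            order = np.argsort(data[:, cols["id"]])
            data = data[order]
            species = data[:, cols["type"]].astype(int) - 1
            charges = (data[:, cols["q"]] if "q" in cols
                       else np.zeros(n))
            positions = data[:, [cols["x"], cols["y"], cols["z"]]]
            frames.append(Configuration(positions, species, charges, box, time))
        except TrajectoryFormatError:
            raise
        except Exception as exc:
            raise TrajectoryFormatError(
                f"malformed dump frame {frame_idx} in {path}: {exc}") from exc
        i += 9 + n
        frame_idx += 1
    return frames


# ---------------------------------------------------------------------------
# native HDF5 container
# ---------------------------------------------------------------------------

def write_native(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as h5:
        frames = traj.frames
        h5.create_dataset("positions",
                          data=np.stack([f.positions for f in frames]))
        h5.create_dataset("species", data=frames[0].species)
        h5.create_dataset("charges", data=frames[0].charges)
        h5.create_dataset("box", data=np.array([f.box_length for f in frames]))
        h5.create_dataset("times", data=np.array([f.time for f in frames]))
        topo = h5.create_group("topology")
        for i, ring in enumerate(traj.topology.rings):
            topo.create_dataset(str(i), data=ring)
        topo.attrs["closed"] = json.dumps(
            traj.topology.closed if isinstance(traj.topology.closed, bool)
            else list(map(bool, traj.topology.closed)))
        if traj.protocol is not None:
            h5.attrs["protocol"] = json.dumps(dataclasses.asdict(traj.protocol))
        h5.attrs["version"] = __version__


def read_native(path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        positions = h5["positions"][...]
        species = h5["species"][...]
        charges = h5["charges"][...]
        box = h5["box"][...]
        times = h5["times"][...]
        rings = [h5["topology"][k][...]
                 for k in sorted(h5["topology"], key=int)]
        closed = json.loads(h5["topology"].attrs["closed"])
        protocol = None
        if "protocol" in h5.attrs:
            protocol = RunProtocol(**json.loads(h5.attrs["protocol"]))
    frames = [Configuration(positions[i], species, charges, float(box[i]),
                            float(times[i])) for i in range(len(positions))]
    return Trajectory(frames, RingTopology(rings, closed), protocol)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path, format: str = "native") -> None:
    if format == "native":
        write_native(traj, path)
    elif format == "xyz":
        write_xyz(traj, path)
    elif format == "lammps_dump":
        write_lammps_dump(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory(path, format: str = "native",
                    topology: Optional[RingTopology] = None) -> Trajectory:
    """Read a trajectory; non-native formats need the topology supplied."""
    if format == "native":
        return read_native(path)
    if format == "xyz":
        frames = read_xyz(path)
    elif format == "lammps_dump":
        frames = read_lammps_dump(path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    if topology is None:
        raise ValueError(f"{format} trajectories need an explicit ring topology")
    return Trajectory(frames, topology)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record tying every output artifact to its inputs."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    code_version: str = __version__
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, inputs: dict, outputs: list,
                  parameters: Optional[dict] = None) -> None:
        self.stages.append({"name": name, "inputs": inputs,
                            "outputs": list(outputs),
                            "parameters": parameters or {}})

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
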