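"""End-to-end orchestration: generate/simulate, then shape, cluster,
scattering and threading stages, each skippable, with a manifest tying
outputs to the configuration and seed that produced them."""

from __future__ import annotations

import logging
import time as _time
from pathlib import Path

import numpy as np

from . import clustering, conformation, correlations, threading as threading_mod
from .dynamics import RunProtocol, Trajectory, run_protocol
from .io import RunManifest, read_trajectory, write_trajectory, write_xyz
from .model import ForceField
from .scenes import make_stack_scene

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "shapes", "clusters", "scatter", "thread")


def _write_table(path: Path, header: list, rows) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(repr(v) if isinstance(v, float) else str(v)
                               for v in row))
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: dict, outdir) -> RunManifest:
    """Run the requested stages and write result tables plus a manifest.

    ``config`` keys: ``stages`` (list), ``seed``, ``protocol`` (RunProtocol
    fields) or ``scene`` (make_stack_scene kwargs), ``force_field``
    (ForceField fields), ``rg0``, ``k_max``, plus optional ``trajectory``
    pointing at an existing native file for analysis-only runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", DEFAULT_STAGES))
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=dict(config), seeds={"master": seed})
    ff = ForceField(**config.get("force_field", {}))

    traj: Trajectory | None = None
    if "trajectory" in config:
        traj = read_trajectory(config["trajectory"], format="native")

    for stage in stages:
        t0 = _time.perf_counter()
        try:
            traj = _run_stage(stage, config, outdir, seed, ff, traj, manifest)
        except Exception:
            logger.exception("pipeline stage %r failed", stage)
            raise
        logger.info("stage %s finished in %.2f s", stage,
                    _time.perf_counter() - t0)
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _require_traj(traj, stage):
    if traj is None:
        raise RuntimeError(
            f"stage {stage!r} needs a trajectory: run simulate/generate first "
            "or pass 'trajectory' in the config")
    return traj


def _run_stage(stage, config, outdir, seed, ff, traj, manifest):
    if stage == "generate":
        scene_cfg = dict(config.get("scene", {}))
        scene_cfg.setdefault("seed", seed)
        scene_cfg.setdefault("n_stacks", 2)
        scene_cfg.setdefault("sizes", [5, 5])
        scene_cfg.setdefault("box", 60.0)
        scene_cfg.setdefault("N", 30)
        cfg, topo, truth = make_stack_scene(**scene_cfg)
        traj = Trajectory([cfg], topo)
        write_xyz(traj, outdir / "scene.xyz")
        write_trajectory(traj, outdir / "scene.h5")
        if truth.cluster_labels is not None:
            _write_table(outdir / "scene_truth.tsv", ["ring_id", "label"],
                         enumerate(truth.cluster_labels.tolist()))
        manifest.add_stage("generate", {"seed": seed},
                           ["scene.xyz", "scene.h5", "scene_truth.tsv"],
                           scene_cfg)
        return traj

    if stage == "simulate":
        proto_cfg = dict(config.get("protocol", {}))
        proto_cfg.setdefault("seed", seed)
        protocol = RunProtocol(**proto_cfg)
        traj = run_protocol(protocol, ff)
        write_trajectory(traj, outdir / "trajectory.h5")
        write_xyz([traj.frames[-1]], outdir / "final.xyz")
        manifest.add_stage("simulate", {"seed": protocol.seed},
                           ["trajectory.h5", "final.xyz"], proto_cfg)
        return traj

    traj = _require_traj(traj, stage)
    shapes = [conformation.frame_shapes(f, traj.topology) for f in traj.frames]

    if stage == "shapes":
        rows = []
        for f_idx, frame in enumerate(shapes):
            for r_idx, s in enumerate(frame):
                rows.append((r_idx, f_idx, float(s.rg), float(s.prolateness),
                             float(s.director[0]), float(s.director[1]),
                             float(s.director[2])))
        _write_table(outdir / "shapes.tsv",
                     ["ring_id", "frame", "rg", "prolateness", "dx", "dy", "dz"],
                     rows)
        manifest.add_stage("shapes", {}, ["shapes.tsv"])
        return traj

    if stage == "clusters":
        criteria = clustering.StackCriteria(**config.get("criteria", {}))
        rows, w_acc, nw = [], {}, []
        for f_idx, frame in enumerate(shapes):
            part = clustering.build_partition(frame, criteria,
                                              traj.frames[f_idx].box_length)
            nw.append(part.Nw)
            for r_idx, lab in enumerate(part.labels):
                rows.append((f_idx, r_idx, int(lab)))
            for ns, w in part.W.items():
                w_acc[ns] = w_acc.get(ns, 0.0) + w / len(shapes)
        _write_table(outdir / "clusters.tsv", ["frame", "ring_id", "cluster_id"],
                     rows)
        _write_table(outdir / "cluster_weights.tsv", ["N_s", "W"],
                     sorted(w_acc.items()))
        _write_table(outdir / "cluster_summary.tsv", ["Nw_mean"],
                     [(float(np.mean(nw)),)])
        manifest.add_stage("clusters", {},
                           ["clusters.tsv", "cluster_weights.tsv",
                            "cluster_summary.tsv"],
                           {"criteria": config.get("criteria", {})})
        return traj

    if stage == "scatter":
        coms = np.array([[s.com for s in frame] for frame in shapes])
        box = traj.box_length
        k, S = correlations.structure_factor(coms, box)
        _write_table(outdir / "structure_factor.tsv", ["k", "S"],
                     zip(k.tolist(), S.tolist()))
        outputs = ["structure_factor.tsv"]
        if traj.n_frames >= 2:
            k_max = config.get("k_max") or correlations.peak_wavenumber(k, S)
            rows = None
            for mode in ("coherent", "incoherent"):
                series = correlations.isf(coms, traj.times, box, k_max, mode)
                if rows is None:
                    rows = {lt: [lt] for lt in series.lag_times}
                for lt, v in zip(series.lag_times, series.values):
                    rows[lt].append(float(v))
            _write_table(outdir / "isf.tsv", ["lag", "F_coh", "F_inc"],
                         [tuple(v) for v in rows.values()])
            outputs.append("isf.tsv")
        manifest.add_stage("scatter", {}, outputs)
        return traj

    if stage == "thread":
        rows = []
        for f_idx, frame in enumerate(traj.frames):
            records = threading_mod.detect_threadings(frame, traj.topology)
            for rec in records:
                rows.append((f_idx, rec.active_ring, rec.passive_ring,
                             rec.n_crossings,
                             ",".join(str(d) for d in rec.depths)))
        _write_table(outdir / "threadings.tsv",
                     ["frame", "active_id", "passive_id", "n_crossings",
                      "depths"], rows)
        manifest.add_stage("thread", {}, ["threadings.tsv"])
        return traj

    raise ValueError(f"unknown pipeline stage {stage!r}")
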