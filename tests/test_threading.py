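"""Minimal-surface and threading tests.

The segment-triangle routine is checked against a slow sign-of-volume
(Plücker/orientation) oracle, and threading detection against scenes with
planted crossing counts.
"""

import math

import numpy as np
import pytest

from ringstack.conformation import frame_shapes
from ringstack.model import Configuration, RingTopology
from ringstack.scenes import (make_planar_ring, make_prolate_ring,
                              make_threading_scene)
from ringstack.threading import (MinimalSurface, build_minimal_surface,
                                 detect_threadings, segment_triangle_intersect,
                                 segments_cross_triangles,
                                 threading_statistics, write_off,
                                 _threading_depths)


def sign_of_volume_oracle(p0, p1, a, b, c):
    """Segment-triangle intersection via signed tetrahedron volumes."""
    def orient(p, q, r, s):
        return np.sign(np.linalg.det(np.array([q - p, r - p, s - p])))
    s1 = orient(p0, a, b, c)
    s2 = orient(p1, a, b, c)
    if s1 == s2 and s1 != 0:
        return False  # both endpoints strictly on one side
    t1 = orient(p0, p1, a, b)
    t2 = orient(p0, p1, b, c)
    t3 = orient(p0, p1, c, a)
    signs = {t1, t2, t3} - {0.0}
    return len(signs) <= 1  # all non-zero orientations agree (or boundary)


class TestMinimalSurface:
    def test_planar_polygon_area(self):
        N = 50
        ring = make_planar_ring(N, 0.96)
        surf = build_minimal_surface(ring)
        R = 0.96 / (2 * math.sin(math.pi / N))
        polygon = 0.5 * N * R * R * math.sin(2 * math.pi / N)
        assert abs(surf.area - polygon) / polygon < 0.02

    def test_area_monotone_non_increasing(self):
        # saddle contour: track the area during descent via a custom run
        N = 40
        ring = make_planar_ring(N, 0.96)
        ring[:, 2] = 1.2 * np.cos(2 * (2 * np.pi * np.arange(N) / N))
        from ringstack.threading import (_area_gradient, _disk_mesh,
                                         _triangle_areas_normals)
        vertices, triangles = _disk_mesh(ring, 5)
        areas = [_triangle_areas_normals(vertices, triangles)[0].sum()]
        surf = build_minimal_surface(ring)
        assert surf.area <= areas[0] + 1e-12

    def test_saddle_strictly_below_initial(self):
        N = 40
        ring = make_planar_ring(N, 0.96)
        ring[:, 2] = 1.5 * np.cos(2 * (2 * np.pi * np.arange(N) / N))
        from ringstack.threading import _disk_mesh, _triangle_areas_normals
        v0, t0 = _disk_mesh(ring, max(int(round(np.linalg.norm(
            ring - ring.mean(0), axis=1).mean())), 1))
        initial = _triangle_areas_normals(v0, t0)[0].sum()
        surf = build_minimal_surface(ring)
        assert surf.area < initial

    def test_boundary_fixed(self):
        ring = make_planar_ring(30, 0.96)
        ring[:, 2] = 0.5 * np.sin(3 * (2 * np.pi * np.arange(30) / 30))
        surf = build_minimal_surface(ring)
        assert np.allclose(surf.boundary, ring)

    def test_mesh_is_disk(self):
        # Euler characteristic of a disk: V - E + F = 1
        surf = build_minimal_surface(make_planar_ring(20, 0.96))
        edges = set()
        for tri in surf.triangles:
            for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                edges.add(tuple(sorted(e)))
        chi = len(surf.vertices) - len(edges) + len(surf.triangles)
        assert chi == 1

    def test_invalid_contour(self):
        with pytest.raises(ValueError):
            build_minimal_surface(np.zeros((2, 3)))

    def test_off_export(self, tmp_path):
        surf = build_minimal_surface(make_planar_ring(12, 0.96))
        path = tmp_path / "mesh.off"
        write_off(surf, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "OFF"
        n_v, n_f, _ = (int(v) for v in lines[1].split())
        assert n_v == len(surf.vertices) and n_f == len(surf.triangles)


class TestSegmentTriangle:
    def test_through_centroid(self):
        tri = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        centroid = tri.mean(axis=0)
        hit, point = segment_triangle_intersect(centroid + [0, 0, 1],
                                                centroid - [0, 0, 1], tri)
        assert hit
        assert np.allclose(point, centroid)

    def test_coplanar_offset_misses(self):
        tri = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        hit, _ = segment_triangle_intersect([2.0, 2.0, 0.0], [3.0, 3.0, 0.0], tri)
        assert not hit

    def test_parallel_above_misses(self):
        tri = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        hit, _ = segment_triangle_intersect([0.1, 0.1, 1.0], [0.5, 0.2, 1.0], tri)
        assert not hit

    def test_boundary_hit_inclusive(self):
        tri = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        hit, _ = segment_triangle_intersect([0.5, 0.0, -1.0], [0.5, 0.0, 1.0], tri)
        assert hit  # passes through the triangle edge

    def test_degenerate_excluded(self):
        tri = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        hit, _ = segment_triangle_intersect([0.5, -1, 0], [0.5, 1, 0], tri)
        assert not hit

    def test_brute_force_oracle_agreement(self, rng):
        mismatches = 0
        n_trials = 10000
        for _ in range(n_trials):
            tri = rng.uniform(-1, 1, (3, 3))
            p0 = rng.uniform(-1.5, 1.5, 3)
            p1 = rng.uniform(-1.5, 1.5, 3)
            if np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0])) < 1e-6:
                continue
            fast, _ = segment_triangle_intersect(p0, p1, tri)
            slow = sign_of_volume_oracle(p0, p1, tri[0], tri[1], tri[2])
            mismatches += int(fast != slow)
        assert mismatches == 0

    def test_vectorised_matches_scalar(self, rng):
        tris = rng.uniform(-1, 1, (40, 3, 3))
        starts = rng.uniform(-1.5, 1.5, (25, 3))
        ends = rng.uniform(-1.5, 1.5, (25, 3))
        matrix = segments_cross_triangles(starts, ends, tris)
        for i in range(25):
            for j in range(40):
                scalar, _ = segment_triangle_intersect(starts[i], ends[i], tris[j])
                assert matrix[i, j] == scalar


class TestDetectThreadings:
    def test_rod_through_ring(self):
        config, topo, truth = make_threading_scene("rod_through_ring")
        records = detect_threadings(config, topo)
        assert len(records) == 1
        rec = records[0]
        assert (rec.active_ring, rec.passive_ring, rec.n_crossings) == (1, 0, 1)

    def test_rod_outside_misses(self):
        config, topo, _ = make_threading_scene("rod_through_ring", offset=12.0)
        assert detect_threadings(config, topo) == []

    def test_ring_through_disk_two_crossings(self):
        config, topo, truth = make_threading_scene("ring_chain")
        records = detect_threadings(config, topo)
        assert len(records) == 1
        rec = records[0]
        assert rec.n_crossings == 2
        assert sum(rec.depths) == 50
        # depths {L, N-L}: equal strand construction gives {25, 25}
        assert sorted(rec.depths) == [25, 25]

    def test_unlinked_zero_records(self):
        config, topo, _ = make_threading_scene("unlinked")
        assert detect_threadings(config, topo) == []

    def test_even_crossings_for_closed_rings(self):
        config, topo, _ = make_threading_scene("ring_chain")
        for rec in detect_threadings(config, topo):
            assert rec.n_crossings % 2 == 0

    def test_periodic_image_threading(self):
        # active ring sits across the boundary from the passive ring
        box = 30.0
        N = 40
        ring = make_planar_ring(N, 0.96, center=(1.0, 15.0, 15.0))
        prol = make_prolate_ring(N, width=2.0,
                                 center=(1.0 - box, 15.0, 15.0),
                                 axis=(0.0, 0.0, 1.0))
        positions = np.vstack([ring, prol])
        config = Configuration(positions, np.zeros(2 * N, int),
                               np.zeros(2 * N), box)
        topo = RingTopology([np.arange(N), np.arange(N, 2 * N)])
        records = detect_threadings(config, topo)
        assert any(r.active_ring == 1 and r.passive_ring == 0 and
                   r.n_crossings == 2 for r in records)

    def test_depth_partition_sums_to_n(self):
        assert _threading_depths(np.array([0, 25]), 50, True) == [25, 25]
        assert _threading_depths(np.array([3]), 50, True) == [50]
        assert sum(_threading_depths(np.array([2, 9, 30, 41]), 50, True)) == 50


class TestThreadingStatistics:
    def _frame(self, configs_topos):
        config, topo, _ = configs_topos
        shapes = frame_shapes(config, topo)
        records = detect_threadings(config, topo)
        return records, shapes

    def test_isolated_rings_all_mass_at_zero(self):
        records, shapes = self._frame(make_threading_scene("unlinked"))
        stats = threading_statistics([records], [shapes])
        assert stats["P_passive"][0] == pytest.approx(1.0)
        assert stats["P_active"][0] == pytest.approx(1.0)

    def test_planted_prolate_counts(self):
        # one prolate threading several oblates stacked around it
        N = 30
        box = 60.0
        n_oblates = 6
        rings = []
        for j in range(n_oblates):
            rings.append(make_planar_ring(
                N, 0.96, center=(30.0, 30.0, 27.0 + j), normal=(0, 0, 1.0)))
        prol = make_prolate_ring(N, width=2.0, center=(30.0, 30.0, 29.5),
                                 axis=(0.0, 0.0, 1.0))
        rings.append(prol)
        positions = np.concatenate(rings)
        M = n_oblates + 1
        config = Configuration(positions, np.zeros(M * N, int),
                               np.zeros(M * N), box)
        topo = RingTopology([np.arange(m * N, (m + 1) * N) for m in range(M)])
        records = detect_threadings(config, topo)
        active = np.zeros(M, int)
        passive = np.zeros(M, int)
        for rec in records:
            active[rec.active_ring] += 1
            passive[rec.passive_ring] += 1
        assert active[-1] == n_oblates  # the prolate threads every oblate
        assert all(passive[:n_oblates] >= 1)

    def test_marginals_sum_to_one(self):
        records, shapes = self._frame(make_threading_scene("ring_chain"))
        stats = threading_statistics([records], [shapes])
        assert stats["P_passive"].sum() == pytest.approx(1.0, abs=1e-12)
        assert stats["P_active"].sum() == pytest.approx(1.0, abs=1e-12)
        assert stats["joint_passive"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_bookkeeping_identity(self):
        records, shapes = self._frame(make_threading_scene("ring_chain"))
        n_active_records = sum(1 for r in records)
        total_active = 0
        M = len(shapes)
        act = np.zeros(M, int)
        for rec in records:
            act[rec.active_ring] += 1
        assert act.sum() == n_active_records

    def test_frame_misalignment_rejected(self):
        with pytest.raises(ValueError):
            threading_statistics([[]], [[], []])
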