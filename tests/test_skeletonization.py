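"""Voxelization, TEASAR-style skeletons, SWC serialization."""

import numpy as np
import pytest

from morpho3d import (
    LabelVolume,
    OpenMeshError,
    Skeleton,
    enclosed_volume,
    labels_to_meshes,
    read_swc,
    skeleton_length,
    skeletonize,
    voxelize,
    write_swc,
)
from morpho3d.synthetic import ShapeSpec, make_mesh


class TestVoxelize:
    def test_unit_cube_fill_count(self, unit_cube):
        cube, _ = unit_cube
        vol = voxelize(cube, (0.25, 0.25, 0.25))
        count = int((vol.data > 0).sum())
        assert abs(count - 64) <= 6  # 10% boundary jitter

    def test_sphere_count_within_5pct(self):
        sph, rec = make_mesh(ShapeSpec("icosphere", {"radius": 10, "subdivisions": 3}))
        vol = voxelize(sph, (1, 1, 1))
        count = int((vol.data > 0).sum())
        assert count == pytest.approx(4.0 / 3.0 * np.pi * 1000, rel=0.05)

    def test_round_trip_volume(self):
        sph, _ = make_mesh(ShapeSpec("icosphere", {"radius": 10, "subdivisions": 3}))
        vol = voxelize(sph, (1, 1, 1))
        back = labels_to_meshes(vol)[1]
        assert enclosed_volume(back) == pytest.approx(enclosed_volume(sph), rel=0.10)

    def test_open_mesh_rejected(self):
        from morpho3d.mesh_io import TriMesh

        strip = TriMesh(
            "open",
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            faces=[[0, 1, 2]],
        )
        with pytest.raises(OpenMeshError):
            voxelize(strip, (0.5, 0.5, 0.5))


class TestSkeletonize:
    def test_straight_tube_centered_path(self, tube_volume):
        vol, rec = tube_volume
        sk = skeletonize(vol)
        deg = sk.degrees()
        assert (deg == 1).sum() == 2  # single path
        assert (deg > 2).sum() == 0
        # centeredness relative to the true axis (x, y of any endpoint)
        axis_xy = rec.endpoints[0][:2]
        d = np.linalg.norm(sk.nodes[:, :2] - axis_xy, axis=1)
        assert d.mean() <= 1.0
        assert d.max() <= 2.0
        assert skeleton_length(sk) == pytest.approx(rec.axis_length, rel=0.15)

    def test_tube_radii_match_tube_radius(self, tube_volume):
        vol, rec = tube_volume
        sk = skeletonize(vol)
        interior = sk.radii[(sk.nodes[:, 2] > 10) & (sk.nodes[:, 2] < 54)]
        assert np.all(interior > 0)
        assert np.median(interior) == pytest.approx(rec.radius, rel=0.2)

    def test_ball_near_degenerate(self):
        from morpho3d.synthetic import make_volume

        vol, rec = make_volume(ShapeSpec("ball_volume", {"radius": 15.0}))
        sk = skeletonize(vol)
        assert skeleton_length(sk) < 2 * rec.radius
        # one component: one root
        assert len(sk.roots) == 1

    def test_y_tube_topology(self, y_tube_volume):
        vol, rec = y_tube_volume
        sk = skeletonize(vol)
        deg = sk.degrees()
        assert (deg == 1).sum() == 3
        assert (deg == 3).sum() == 1
        assert (deg > 3).sum() == 0
        junction = sk.nodes[np.flatnonzero(deg == 3)[0]]
        assert np.linalg.norm(junction - rec.junction) < 3 * max(vol.spacing)

    def test_nodes_inside_mask(self, tube_volume):
        vol, _ = tube_volume
        sk = skeletonize(vol)
        sz, sy, sx = vol.spacing
        iz = np.rint(sk.nodes[:, 2] / sz).astype(int)
        iy = np.rint(sk.nodes[:, 1] / sy).astype(int)
        ix = np.rint(sk.nodes[:, 0] / sx).astype(int)
        assert np.all(vol.data[iz, iy, ix] > 0)

    def test_monotone_invalidation(self, tube_volume):
        vol, _ = tube_volume
        counts = [skeletonize(vol, scale=s).n_nodes for s in (1.0, 2.0, 4.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_determinism(self, y_tube_volume):
        vol, _ = y_tube_volume
        a = skeletonize(vol)
        b = skeletonize(vol)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.edges, b.edges)
        assert np.array_equal(a.radii, b.radii)

    def test_empty_volume(self):
        vol = LabelVolume(np.zeros((4, 4, 4), dtype=np.int64), (1, 1, 1))
        sk = skeletonize(vol)
        assert sk.n_nodes == 0 and len(sk.edges) == 0

    def test_single_voxel(self):
        data = np.zeros((3, 3, 3), dtype=np.int64)
        data[1, 1, 1] = 1
        sk = skeletonize(LabelVolume(data, (1, 1, 1)))
        assert sk.n_nodes == 1 and len(sk.edges) == 0
        assert sk.radii[0] > 0

    def test_two_components_two_roots(self):
        data = np.zeros((3, 3, 9), dtype=np.int64)
        data[1, 1, 1] = 1
        data[1, 1, 7] = 1
        sk = skeletonize(LabelVolume(data, (1, 1, 1)))
        assert len(sk.roots) == 2

    def test_tree_invariant(self, y_tube_volume):
        vol, _ = y_tube_volume
        sk = skeletonize(vol)
        # forest: |E| = |V| - #components
        assert len(sk.edges) == sk.n_nodes - len(sk.roots)

    def test_anisotropic_spacing_scales_lengths(self, tube_volume):
        vol, rec = tube_volume
        stretched = LabelVolume(vol.data, spacing=(2.0, 1.0, 1.0))
        sk = skeletonize(stretched)
        assert skeleton_length(sk) == pytest.approx(2 * rec.axis_length, rel=0.15)


class TestSkeletonLength:
    def test_two_nodes(self):
        sk = Skeleton(
            nodes=[[0, 0, 0], [0, 0, 7]], radii=[1, 1], edges=[[0, 1]], roots=[0]
        )
        assert skeleton_length(sk) == pytest.approx(7.0)

    def test_empty(self):
        sk = Skeleton(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 2)), [])
        assert skeleton_length(sk) == 0.0


class TestSwc:
    def test_three_node_path(self, tmp_path):
        sk = Skeleton(
            nodes=[[0, 0, 0], [0, 0, 1], [0, 0, 2]],
            radii=[1, 1, 1],
            edges=[[0, 1], [1, 2]],
            roots=[0],
        )
        p = write_swc(sk, tmp_path / "p.swc")
        rows = [l.split() for l in p.read_text().splitlines() if not l.startswith("#")]
        assert [r[0] for r in rows] == ["1", "2", "3"]
        assert [r[6] for r in rows] == ["-1", "1", "2"]

    def test_one_root_per_component(self, tmp_path, y_tube_volume):
        vol, _ = y_tube_volume
        sk = skeletonize(vol)
        p = write_swc(sk, tmp_path / "y.swc")
        rows = [l.split() for l in p.read_text().splitlines() if not l.startswith("#")]
        assert sum(1 for r in rows if r[6] == "-1") == len(sk.roots)
        # children after parents
        seen = set()
        for r in rows:
            if r[6] != "-1":
                assert int(r[6]) in seen
            seen.add(int(r[0]))

    def test_round_trip_edges_exact(self, tmp_path, y_tube_volume):
        vol, _ = y_tube_volume
        sk = skeletonize(vol)
        back = read_swc(write_swc(sk, tmp_path / "y.swc"))
        # node order may change; compare as coordinate-pair edge sets
        # (coordinates rounded to the SWC printing precision)
        def edge_set(s):
            key = lambda i: tuple(np.round(s.nodes[i], 6))
            return {tuple(sorted((key(a), key(b)))) for a, b in s.edges}

        assert edge_set(back) == edge_set(sk)
        assert np.allclose(
            sorted(back.radii.tolist()), sorted(sk.radii.tolist()), rtol=1e-6
        )

    def test_cyclic_graph_rejected(self, tmp_path):
        sk = Skeleton(
            nodes=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            radii=[1, 1, 1],
            edges=[[0, 1], [1, 2], [0, 2]],
            roots=[0],
        )
        with pytest.raises(ValueError, match="forest"):
            write_swc(sk, tmp_path / "c.swc")
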