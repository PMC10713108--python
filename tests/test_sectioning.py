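"""Center lines, plane placement, plane-mesh intersection, section props.

The moment-based axis lengths are validated against an independent oracle
that rasterizes the polygonal region on a 2048x2048 grid and computes
discrete second moments.
"""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

from morpho3d import (
    CenterLine,
    DegeneracyError,
    MissesObjectError,
    SectionPlane,
    SectionPolygon,
    build_centerline,
    enclosed_volume,
    place_planes,
    plane_mesh_intersection,
    section_properties,
    slice_and_measure,
)
from conftest import random_rotation

DUMMY_PLANE = SectionPlane(origin=(0, 0, 0), normal=(0, 0, 1), station=0.0)


def make_polygon(rings, holes):
    """SectionPolygon from explicit 2D rings (CCW outer, CW holes)."""
    loops = []
    for r, h in zip(rings, holes):
        r = np.asarray(r, dtype=float)
        area = 0.5 * np.sum(
            r[:, 0] * np.roll(r[:, 1], -1) - np.roll(r[:, 0], -1) * r[:, 1]
        )
        if (h and area > 0) or (not h and area < 0):
            r = r[::-1]
        loops.append(r)
    return SectionPolygon(loops=loops, is_hole=list(holes), plane=DUMMY_PLANE)


def raster_moment_axes(rings, holes, n=2048):
    """Independent oracle: rasterize the region, compute discrete second
    central moments, return (minor, major) = 4*sqrt(eigenvalues)."""
    outer = [np.asarray(r) for r, h in zip(rings, holes) if not h]
    inner = [np.asarray(r) for r, h in zip(rings, holes) if h]
    poly = Polygon(outer[0], [list(map(tuple, r)) for r in inner])
    for extra in outer[1:]:
        poly = poly.union(Polygon(extra))
    x0, y0, x1, y1 = poly.bounds
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    X, Y = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    px, py = X[mask], Y[mask]
    cx, cy = px.mean(), py.mean()
    mu20 = ((px - cx) ** 2).mean()
    mu02 = ((py - cy) ** 2).mean()
    mu11 = ((px - cx) * (py - cy)).mean()
    evals = np.linalg.eigvalsh([[mu20, mu11], [mu11, mu02]])
    return 4 * math.sqrt(max(evals[0], 0)), 4 * math.sqrt(evals[1])


def ngon(r, n, center=(0.0, 0.0)):
    t = 2 * np.pi * np.arange(n) / n
    return np.stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)], axis=1)


class TestCenterLine:
    def test_arc_length(self):
        cl = CenterLine([[0, 0, 0], [0, 0, 10]])
        assert cl.arc_length.tolist() == [0.0, 10.0]

    def test_repeated_point_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            CenterLine([[0, 0, 0], [0, 0, 0], [1, 0, 0]])

    def test_principal_axis_of_cylinder(self, cylinder):
        mesh, rec = cylinder
        cl = build_centerline(mesh, method="principal-axis", n_points=10)
        direction = cl.points[-1] - cl.points[0]
        direction /= np.linalg.norm(direction)
        angle = math.degrees(
            math.acos(min(1.0, abs(float(direction @ rec.axis_direction))))
        )
        assert angle < 1.0
        assert cl.length == pytest.approx(rec.axis_length, rel=0.05)
        assert not cl.low_anisotropy

    def test_sphere_flagged_low_anisotropy(self, icosphere2):
        mesh, _ = icosphere2
        cl = build_centerline(mesh, method="principal-axis")
        assert cl.low_anisotropy

    def test_collinear_cloud_rejected(self):
        from morpho3d.mesh_io import TriMesh

        class FakeMesh:
            vertices = np.array([[0, 0, z] for z in np.linspace(0, 9, 10)])

        with pytest.raises(DegeneracyError):
            build_centerline(FakeMesh(), method="principal-axis")


class TestPlacePlanes:
    def test_arithmetic_progression_inside(self):
        cl = CenterLine([[0, 0, 0], [0, 0, 10]])
        planes = place_planes(cl, n_sections=3)
        stations = [p.station for p in planes]
        assert stations == pytest.approx([10 / 6, 5.0, 50 / 6])
        for p in planes:
            assert p.normal == pytest.approx([0, 0, 1])

    def test_corner_normal_is_mean_of_tangents(self):
        cl = CenterLine([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
        plane = SectionPlane(
            origin=cl.point_at(1.0), normal=cl.tangent_at(1.0), station=1.0
        )
        expected = np.array([1, 1, 0]) / math.sqrt(2)
        assert plane.normal == pytest.approx(expected)

    def test_step_floor_count(self):
        cl = CenterLine([[0, 0, 0], [0, 0, 10]])
        planes = place_planes(cl, step=4.0)
        assert len(planes) == 2
        assert len(planes) * 4.0 <= cl.length
        assert [p.station for p in planes] == pytest.approx([2.0, 6.0])

    def test_step_longer_than_line_gives_midpoint(self):
        cl = CenterLine([[0, 0, 0], [0, 0, 10]])
        planes = place_planes(cl, step=25.0)
        assert len(planes) == 1
        assert planes[0].station == pytest.approx(5.0)


class TestPlaneMeshIntersection:
    def test_cube_midplane_square(self, unit_cube):
        cube, _ = unit_cube
        plane = SectionPlane(origin=(0, 0, 0), normal=(0, 0, 1), station=0.0)
        sec = plane_mesh_intersection(cube, plane)
        assert len(sec.loops) == 1 and not sec.is_hole[0]
        props = section_properties(sec)
        assert props.area == pytest.approx(1.0, rel=1e-9)
        assert props.perimeter == pytest.approx(4.0, rel=1e-9)

    def test_cube_missed(self, unit_cube):
        cube, _ = unit_cube
        plane = SectionPlane(origin=(0, 0, 2), normal=(0, 0, 1), station=0.0)
        assert plane_mesh_intersection(cube, plane).is_empty

    def test_sphere_offset_circle(self, icosphere4):
        sph, _ = icosphere4
        plane = SectionPlane(origin=(0, 0, 6), normal=(0, 0, 1), station=0.0)
        sec = plane_mesh_intersection(sph, plane)
        assert len(sec.loops) == 1
        loop = sec.loops[0]
        radii = np.linalg.norm(loop - loop.mean(axis=0), axis=1)
        assert np.all(np.abs(radii - 8.0) < 0.08)

    def test_torus_axial_cut_two_loops(self, torus):
        tor, _ = torus
        plane = SectionPlane(origin=(0, 0, 0), normal=(0, 1, 0), station=0.0)
        sec = plane_mesh_intersection(tor, plane)
        assert len(sec.loops) == 2
        assert not any(sec.is_hole)

    def test_torus_transverse_cut_annulus(self, torus):
        """Plane z=0 through a torus -> concentric circles, inner is a hole."""
        tor, _ = torus
        plane = SectionPlane(origin=(0, 0, 0), normal=(0, 0, 1), station=0.0)
        sec = plane_mesh_intersection(tor, plane)
        assert len(sec.loops) == 2
        assert sorted(sec.is_hole) == [False, True]
        props = section_properties(sec)
        # annulus R=10, r=2: area = pi((R+r)^2 - (R-r)^2) = 4*pi*R*r/ ...
        assert props.area == pytest.approx(np.pi * (12**2 - 8**2), rel=0.02)
        assert props.convexity_area < 1.0


class TestSectionProperties:
    def test_unit_square_all_nine(self):
        sq = make_polygon([[(0, 0), (1, 0), (1, 1), (0, 1)]], [False])
        p = section_properties(sq)
        assert p.area == pytest.approx(1.0)
        assert p.perimeter == pytest.approx(4.0)
        assert p.convex_area == pytest.approx(1.0)
        assert p.convex_perimeter == pytest.approx(4.0)
        assert p.equivalent_diameter == pytest.approx(2 / math.sqrt(math.pi))
        assert p.convexity_area == pytest.approx(1.0)
        assert p.convexity_perimeter == pytest.approx(1.0)
        # closed form: square second moment 1/12 -> axis 4*sqrt(1/12)
        assert p.major_axis_length == pytest.approx(2 / math.sqrt(3), rel=1e-9)
        assert p.minor_axis_length == pytest.approx(p.major_axis_length, abs=1e-9)

    def test_unit_square_axes_vs_raster_oracle(self):
        rings = [[(0, 0), (1, 0), (1, 1), (0, 1)]]
        minor, major = raster_moment_axes(rings, [False])
        p = section_properties(make_polygon(rings, [False]))
        assert p.minor_axis_length == pytest.approx(minor, rel=0.01)
        assert p.major_axis_length == pytest.approx(major, rel=0.01)

    def test_l_shape(self):
        ring = [(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)]
        p = section_properties(make_polygon([ring], [False]))
        assert p.area == pytest.approx(3.0)
        assert p.convex_area == pytest.approx(3.5)  # hull cuts the notch corner
        assert p.convexity_area == pytest.approx(3.0 / 3.5)
        minor, major = raster_moment_axes([ring], [False])
        assert p.minor_axis_length == pytest.approx(minor, rel=0.01)
        assert p.major_axis_length == pytest.approx(major, rel=0.01)

    def test_square_with_centered_hole(self):
        outer = [(0, 0), (2, 0), (2, 2), (0, 2)]
        hole = [(0.5, 0.5), (1.5, 0.5), (1.5, 1.5), (0.5, 1.5)]
        p = section_properties(make_polygon([outer, hole], [False, True]))
        assert p.area == pytest.approx(3.0)
        assert p.perimeter == pytest.approx(12.0)  # outer 8 + hole 4
        assert p.convex_perimeter == pytest.approx(8.0)
        assert p.convexity_perimeter == pytest.approx(8.0 / 12.0)
        minor, major = raster_moment_axes([outer, hole], [False, True])
        assert p.minor_axis_length == pytest.approx(minor, rel=0.01)
        assert p.major_axis_length == pytest.approx(major, rel=0.01)

    def test_256gon_circle(self):
        ring = ngon(5.0, 256)
        p = section_properties(make_polygon([ring], [False]))
        assert p.major_axis_length == pytest.approx(10.0, rel=0.005)
        assert p.minor_axis_length == pytest.approx(10.0, rel=0.005)
        assert p.convexity_area == pytest.approx(1.0, abs=1e-6)
        assert p.convexity_perimeter == pytest.approx(1.0, abs=1e-6)
        assert p.equivalent_diameter == pytest.approx(10.0, rel=0.001)


class TestSliceAndMeasure:
    def test_cylinder_diameters(self, cylinder):
        mesh, rec = cylinder
        cl = CenterLine([[0, 0, -10], [0, 0, 10]])
        df = slice_and_measure(mesh, cl, n_sections=5)
        assert len(df) == 5
        assert np.allclose(df["equivalent_diameter"], 6.0, rtol=0.02)

    def test_sphere_profile(self, icosphere4):
        sph, _ = icosphere4
        cl = CenterLine([[0, 0, -10], [0, 0, 10]])
        df = slice_and_measure(sph, cl, n_sections=9)
        z = df["station"] - 10.0
        expected = np.pi * (100.0 - z**2)
        assert np.allclose(df["area"], expected, rtol=0.02)

    def test_misses_object(self, unit_cube):
        cube, _ = unit_cube
        cl = CenterLine([[10, 10, 0], [10, 10, 5]])
        with pytest.raises(MissesObjectError):
            slice_and_measure(cube, cl, n_sections=4)

    def test_convex_sections_have_unit_convexity(self, icosphere4, cylinder):
        for mesh, _ in (icosphere4, cylinder):
            cl = CenterLine([[0, 0, -9], [0, 0, 9]])
            df = slice_and_measure(mesh, cl, n_sections=6).dropna()
            assert (df["convexity_area"] >= 0.99).all()
            assert (df["convexity_perimeter"] >= 0.99).all()
            assert (df["convexity_area"] <= 1.0 + 1e-9).all()

    def test_rigid_invariance(self, cylinder):
        mesh, _ = cylinder
        cl = CenterLine([[0, 0, -10], [0, 0, 10]])
        df0 = slice_and_measure(mesh, cl, n_sections=4)
        rng = np.random.default_rng(11)
        R = random_rotation(rng)
        t = rng.uniform(-50, 50, 3)
        moved = mesh.copy()
        moved.vertices = moved.vertices @ R.T + t
        cl2 = CenterLine(cl.points @ R.T + t)
        df1 = slice_and_measure(moved, cl2, n_sections=4)
        for col in df0.columns:
            assert np.allclose(df0[col], df1[col], rtol=1e-6)

    def test_cavalieri_consistency(self, cylinder, icosphere4):
        """Integrated section area along a straight center line reproduces
        the enclosed volume (trapezoid rule, 200 stations)."""
        for mesh, lo, hi in (
            (cylinder[0], -10.0, 10.0),
            (icosphere4[0], -10.0, 10.0),
        ):
            cl = CenterLine([[0, 0, lo], [0, 0, hi]])
            df = slice_and_measure(mesh, cl, n_sections=200)
            areas = df["area"].fillna(0.0).to_numpy()
            integral = np.trapezoid(areas, df["station"].to_numpy())
            assert integral == pytest.approx(enclosed_volume(mesh), rel=0.02)
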