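"""Synthetic geometric fixtures with known analytic properties.

Every mesh and label volume used by the test suite and the documentation
comes from this module: spheres, cubes, cylinders and tori as meshes;
balls, straight tubes, Y-shaped tube unions and multi-label volumes as
voxel grids. Each generator returns the object together with an
:class:`AnalyticRecord` of its closed-form surface area, volume, axis and
(for volumes) its actual voxel count — the ground truth the rest of the
toolbox is checked against. Generators are deterministic for a given
spec (the seed only enters where placement is randomized).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import trimesh as _trimesh

from .mesh_io import TriMesh, orient_consistently
from .voxel_mesh import LabelVolume

__all__ = ["ShapeSpec", "AnalyticRecord", "make_mesh", "make_volume"]

MESH_KINDS = ("icosphere", "cube", "cylinder", "torus")
VOLUME_KINDS = ("ball_volume", "tube_volume", "y_tube_volume", "multilabel_volume")


@dataclass
class ShapeSpec:
    """Recipe for one synthetic shape: kind + kind-specific parameters."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


@dataclass
class AnalyticRecord:
    """Ground truth attached to a generated shape.

    Lengths in the same unit as the shape; ``tolerance`` is the relative
    discretization error expected of the generated representation at its
    refinement (measured once on the generator and frozen).
    """

    area: float | None = None
    volume: float | None = None
    axis_direction: np.ndarray | None = None
    axis_length: float | None = None
    tolerance: float = 0.0
    voxel_count: int | None = None
    label_voxel_counts: dict[int, int] | None = None
    endpoints: np.ndarray | None = None  # physical (x, y, z) rows
    junction: np.ndarray | None = None
    center: np.ndarray | None = None
    radius: float | None = None


def _from_trimesh(tm: "_trimesh.Trimesh", name: str) -> TriMesh:
    mesh = TriMesh(
        name=name,
        vertices=np.asarray(tm.vertices, dtype=np.float64),
        faces=np.asarray(tm.faces, dtype=np.int64),
        provenance=f"synthetic:{name}",
    )
    return orient_consistently(mesh)


def make_mesh(spec: ShapeSpec) -> tuple[TriMesh, AnalyticRecord]:
    """Generate a watertight, outward-oriented mesh plus its analytic record."""
    p = dict(spec.params)
    if spec.kind == "icosphere":
        r = float(p.get("radius", 10.0))
        sub = int(p.get("subdivisions", 4))
        tm = _trimesh.creation.icosphere(subdivisions=sub, radius=r)
        # relative discretization error of an inscribed icosphere by level
        # (volume deviates more than area; bounds measured once and frozen)
        tol = {0: 0.25, 1: 0.08, 2: 0.035, 3: 0.012, 4: 0.004}.get(sub, 0.004)
        rec = AnalyticRecord(
            area=4.0 * np.pi * r * r,
            volume=4.0 / 3.0 * np.pi * r**3,
            tolerance=max(tol, 1e-6),
            center=np.zeros(3),
            radius=r,
        )
    elif spec.kind == "cube":
        e = float(p.get("edge", 1.0))
        tm = _trimesh.creation.box(extents=(e, e, e))
        rec = AnalyticRecord(
            area=6.0 * e * e, volume=e**3, tolerance=1e-12, center=np.zeros(3)
        )
    elif spec.kind == "cylinder":
        r = float(p.get("radius", 3.0))
        h = float(p.get("height", 20.0))
        n = int(p.get("sections", 128))
        tm = _trimesh.creation.cylinder(radius=r, height=h, sections=n)
        # inscribed n-gon prism: cap area shrinks by sinc(2*pi/n), lateral by
        # sinc(pi/n); x^2 bounds both (volume error ~ 2x^2/3)
        x = np.pi / n
        rec = AnalyticRecord(
            area=2 * np.pi * r * h + 2 * np.pi * r * r,
            volume=np.pi * r * r * h,
            axis_direction=np.array([0.0, 0.0, 1.0]),
            axis_length=h,
            tolerance=max(x * x, 1e-6),
            center=np.zeros(3),
            radius=r,
        )
    elif spec.kind == "torus":
        R = float(p.get("major_radius", 10.0))
        r = float(p.get("minor_radius", 2.0))
        kw = {}
        if "major_sections" in p:
            kw["major_sections"] = int(p["major_sections"])
        if "minor_sections" in p:
            kw["minor_sections"] = int(p["minor_sections"])
        tm = _trimesh.creation.torus(major_radius=R, minor_radius=r, **kw)
        rec = AnalyticRecord(
            area=4 * np.pi**2 * R * r,
            volume=2 * np.pi**2 * R * r * r,
            axis_direction=np.array([0.0, 0.0, 1.0]),
            tolerance=0.05,
            center=np.zeros(3),
            radius=R,
        )
    else:
        raise ValueError(f"unknown mesh kind: {spec.kind!r} (one of {MESH_KINDS})")
    name = p.get("name", spec.kind)
    return _from_trimesh(tm, name), rec


def _grid_centers(shape, spacing):
    """Voxel-center coordinate grids (z, y, x order), physical units."""
    nz, ny, nx = shape
    sz, sy, sx = spacing
    z = np.arange(nz)[:, None, None] * sz
    y = np.arange(ny)[None, :, None] * sy
    x = np.arange(nx)[None, None, :] * sx
    return z, y, x


def _capsule_mask(shape, spacing, p0_xyz, p1_xyz, radius):
    """Voxels whose centers lie within `radius` of segment p0-p1."""
    z, y, x = _grid_centers(shape, spacing)
    p0 = np.asarray(p0_xyz, dtype=float)
    p1 = np.asarray(p1_xyz, dtype=float)
    d = p1 - p0
    L2 = float(d @ d)
    # vector from p0 to each voxel center
    vx, vy, vz = x - p0[0], y - p0[1], z - p0[2]
    if L2 == 0:
        dist2 = vx**2 + vy**2 + vz**2
    else:
        t = np.clip((vx * d[0] + vy * d[1] + vz * d[2]) / L2, 0.0, 1.0)
        dist2 = (vx - t * d[0]) ** 2 + (vy - t * d[1]) ** 2 + (vz - t * d[2]) ** 2
    return dist2 <= radius * radius


def make_volume(spec: ShapeSpec) -> tuple[LabelVolume, AnalyticRecord]:
    """Generate an integer label volume plus its analytic record."""
    p = dict(spec.params)
    spacing = tuple(float(s) for s in p.get("spacing", (1.0, 1.0, 1.0)))
    sz, sy, sx = spacing

    if spec.kind == "ball_volume":
        r = float(p.get("radius", 20.0))  # physical units
        margin = int(p.get("margin", 3))
        nz = int(np.ceil(2 * r / sz)) + 2 * margin + 1
        ny = int(np.ceil(2 * r / sy)) + 2 * margin + 1
        nx = int(np.ceil(2 * r / sx)) + 2 * margin + 1
        cz, cy, cx = ((nz - 1) / 2 * sz, (ny - 1) / 2 * sy, (nx - 1) / 2 * sx)
        z, y, x = _grid_centers((nz, ny, nx), spacing)
        mask = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r * r
        data = mask.astype(np.int64)
        rec = AnalyticRecord(
            volume=4.0 / 3.0 * np.pi * r**3,
            voxel_count=int(mask.sum()),
            center=np.array([cx, cy, cz]),
            radius=r,
        )
        return LabelVolume(data, spacing), rec

    if spec.kind == "tube_volume":
        r = float(p.get("radius", 4.0))
        length = float(p.get("length", 60.0))
        margin = int(p.get("margin", 4))
        nz = int(np.ceil(length / sz)) + 2 * margin + 1
        ny = int(np.ceil(2 * r / sy)) + 2 * margin + 1
        nx = int(np.ceil(2 * r / sx)) + 2 * margin + 1
        cy, cx = (ny - 1) / 2 * sy, (nx - 1) / 2 * sx
        z0 = margin * sz
        p0 = (cx, cy, z0)
        p1 = (cx, cy, z0 + length)
        mask = _capsule_mask((nz, ny, nx), spacing, p0, p1, r) & True
        # flat caps: clip to the slab between the endpoints
        z, _, _ = _grid_centers((nz, ny, nx), spacing)
        mask &= (z >= z0 - 1e-9) & (z <= z0 + length + 1e-9)
        data = mask.astype(np.int64)
        rec = AnalyticRecord(
            volume=np.pi * r * r * length,
            voxel_count=int(mask.sum()),
            axis_direction=np.array([0.0, 0.0, 1.0]),
            axis_length=length,
            endpoints=np.array([p0, p1], dtype=float),
            center=np.array([cx, cy, z0 + length / 2]),
            radius=r,
        )
        return LabelVolume(data, spacing), rec

    if spec.kind == "y_tube_volume":
        r = float(p.get("radius", 4.0))
        arm = float(p.get("arm_length", 30.0))
        margin = int(p.get("margin", 4))
        # junction at the center; one arm down (-z), two up at +/-45 deg in xz
        ext = arm / np.sqrt(2.0) + r + margin * max(spacing)
        nx = int(np.ceil(2 * ext / sx)) + 1
        ny = int(np.ceil((2 * r + 2 * margin * sy) / sy)) + 1
        nz = int(np.ceil((arm + arm / np.sqrt(2.0) + 2 * r) / sz)) + 2 * margin + 1
        cx, cy = (nx - 1) / 2 * sx, (ny - 1) / 2 * sy
        jz = margin * sz + arm  # junction height
        j = np.array([cx, cy, jz])
        tips = np.array(
            [
                [cx, cy, jz - arm],
                [cx - arm / np.sqrt(2), cy, jz + arm / np.sqrt(2)],
                [cx + arm / np.sqrt(2), cy, jz + arm / np.sqrt(2)],
            ]
        )
        mask = np.zeros((nz, ny, nx), dtype=bool)
        for tip in tips:
            mask |= _capsule_mask((nz, ny, nx), spacing, j, tip, r)
        data = mask.astype(np.int64)
        rec = AnalyticRecord(
            voxel_count=int(mask.sum()),
            endpoints=tips,
            junction=j,
            radius=r,
            axis_length=arm,
        )
        return LabelVolume(data, spacing), rec

    if spec.kind == "multilabel_volume":
        r = float(p.get("radius", 6.0))
        n_labels = int(p.get("n_labels", 3))
        gap = float(p.get("gap", 4.0))
        margin = 2
        pitch = 2 * r + gap
        nx = int(np.ceil((n_labels * pitch) / sx)) + 2 * margin
        ny = int(np.ceil(2 * r / sy)) + 2 * margin + 1
        nz = int(np.ceil(2 * r / sz)) + 2 * margin + 1
        cy, cz = (ny - 1) / 2 * sy, (nz - 1) / 2 * sz
        z, y, x = _grid_centers((nz, ny, nx), spacing)
        data = np.zeros((nz, ny, nx), dtype=np.int64)
        counts = {}
        centers = []
        for lab in range(1, n_labels + 1):
            cx = margin * sx + (lab - 0.5) * pitch
            mask = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r * r
            data[mask] = lab
            counts[lab] = int(mask.sum())
            centers.append([cx, cy, cz])
        rec = AnalyticRecord(
            volume=4.0 / 3.0 * np.pi * r**3,
            label_voxel_counts=counts,
            endpoints=np.array(centers),
            radius=r,
        )
        return LabelVolume(data, spacing), rec

    raise ValueError(f"unknown volume kind: {spec.kind!r} (one of {VOLUME_KINDS})")
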