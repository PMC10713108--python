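"""Cross-sectioning along a center line and section-property computation.

A center line (ordered 3D polyline) defines slicing stations; at each
station a plane is placed perpendicular to the local tangent, intersected
with the mesh, and the resulting planar polygons are reduced to nine
geometric properties: area, perimeter, convex area, convex perimeter,
equivalent diameter, convexity by area, convexity by perimeter, and minor/
major axis length.

Conventions
-----------
* Plane stations are equally spaced in arc length with half-step insets at
  both ends (avoids tangent ambiguity at the polyline endpoints); the
  normal at an interior polyline vertex is the mean of the adjacent
  segment directions.
* Perimeter includes hole boundaries (a section with an internal lumen has
  more boundary), and convexity-by-perimeter is hull-over-total so it
  stays <= 1.
* Axis lengths follow the moments-equivalent-ellipse convention used by
  standard 2D region-properties tools: 4*sqrt(eigenvalue) of the area-
  normalized second central moment matrix of the polygonal region (holes
  subtract).
* Intersection segments are chained into loops by shared mesh-edge
  identity, which is exact on a watertight mesh; vertices lying exactly on
  the plane are first nudged off it by 1e-9 x bounding-box diagonal to
  remove the in-plane-triangle degeneracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon

from .errors import DegeneracyError, DegenerateSectionError, MissesObjectError
from .mesh_io import TriMesh

logger = logging.getLogger(__name__)

__all__ = [
    "CenterLine",
    "SectionPlane",
    "SectionPolygon",
    "SectionProperties",
    "build_centerline",
    "place_planes",
    "plane_mesh_intersection",
    "section_properties",
    "slice_and_measure",
    "read_centerline_txt",
]

#: relative eigenvalue gap below which a principal axis is flagged ambiguous
LOW_ANISOTROPY_RATIO = 0.10


@dataclass
class CenterLine:
    """Ordered 3D polyline with cumulative arc length.

    ``points`` must hold >= 2 points with distinct consecutive entries.
    """

    points: np.ndarray
    low_anisotropy: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("center line needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if (seg == 0).any():
            raise ValueError("center line has repeated consecutive points")

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, station: float) -> np.ndarray:
        """Interpolated point at the given arc-length station."""
        al = self.arc_length
        s = float(np.clip(station, 0.0, al[-1]))
        i = int(np.searchsorted(al, s, side="right") - 1)
        i = min(i, len(al) - 2)
        t = (s - al[i]) / (al[i + 1] - al[i])
        return (1 - t) * self.points[i] + t * self.points[i + 1]

    def tangent_at(self, station: float, vertex_tol: float = 1e-9) -> np.ndarray:
        """Unit tangent at a station; at an interior polyline vertex, the
        normalized mean of the two adjacent segment directions."""
        al = self.arc_length
        s = float(np.clip(station, 0.0, al[-1]))
        dirs = np.diff(self.points, axis=0)
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        # on an interior vertex (within tolerance of a breakpoint)?
        scale = max(al[-1], 1.0)
        for j in range(1, len(al) - 1):
            if abs(s - al[j]) <= vertex_tol * scale:
                t = dirs[j - 1] + dirs[j]
                n = np.linalg.norm(t)
                if n == 0:  # exact U-turn: keep incoming direction
                    return dirs[j - 1]
                return t / n
        i = int(np.searchsorted(al, s, side="right") - 1)
        i = min(i, len(dirs) - 1)
        return dirs[i]


@dataclass
class SectionPlane:
    """Slicing plane: origin on the center line, unit normal (local
    tangent), and the arc-length station of the origin."""

    origin: np.ndarray
    normal: np.ndarray
    station: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("plane normal must be nonzero")
            self.normal = self.normal / n

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic orthonormal in-plane (u, v) frame."""
        n = self.normal
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(n)))] = 1.0
        u = np.cross(n, helper)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def project(self, pts: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        rel = np.asarray(pts, dtype=np.float64) - self.origin
        return np.stack([rel @ u, rel @ v], axis=-1)


@dataclass
class SectionPolygon:
    """One plane's intersection geometry in the local (u, v) frame.

    ``loops`` are closed rings (k, 2 arrays; not repeated-endpoint);
    ``is_hole`` classifies each ring by containment parity; outer rings are
    counter-clockwise and holes clockwise after normalization. Open chains
    (from meshes with boundary) are reported separately and excluded from
    property computation.
    """

    loops: list[np.ndarray]
    is_hole: list[bool]
    plane: SectionPlane
    open_chains: list[np.ndarray] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.loops


@dataclass
class SectionProperties:
    """The nine geometric properties of a planar cross-section."""

    area: float
    perimeter: float
    convex_area: float
    convex_perimeter: float
    equivalent_diameter: float
    convexity_area: float
    convexity_perimeter: float
    minor_axis_length: float
    major_axis_length: float

    FIELDS = (
        "area",
        "perimeter",
        "convex_area",
        "convex_perimeter",
        "equivalent_diameter",
        "convexity_area",
        "convexity_perimeter",
        "minor_axis_length",
        "major_axis_length",
    )

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}


def read_centerline_txt(path) -> CenterLine:
    """Read a plain-text point list: one whitespace-separated ``x y z``
    per line; blank lines and ``#`` comments ignored."""
    pts = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            pts.append([float(x) for x in parts[:3]])
    return CenterLine(np.array(pts))


def build_centerline(
    source,
    method: Literal["explicit", "principal-axis"] = "explicit",
    n_points: int = 2,
) -> CenterLine:
    """Build a center line from explicit points or a mesh's principal axis.

    ``principal-axis`` fits the dominant principal direction of the vertex
    cloud through its centroid, clipped to the extent of the vertex
    projections and discretized into ``n_points`` equally spaced stations.
    If the top two covariance eigenvalues differ by less than 10% the axis
    is ambiguous; the line is still built along the dominant axis but
    flagged ``low_anisotropy`` with a logged warning.
    """
    if method == "explicit":
        return CenterLine(np.asarray(source, dtype=np.float64))
    if method != "principal-axis":
        raise ValueError(f"unknown center-line method: {method!r}")

    mesh: TriMesh = source
    verts = np.asarray(mesh.vertices, dtype=np.float64)
    if len(verts) < 3:
        raise DegeneracyError("principal-axis center line needs >= 3 vertices")
    centroid = verts.mean(axis=0)
    cov = np.cov((verts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[-1] <= 0:
        raise DegeneracyError("vertex cloud is a single point")
    # collinearity: residual variance off the dominant axis ~ 0
    if evals[1] / evals[-1] < 1e-12 and evals[0] / evals[-1] < 1e-12:
        raise DegeneracyError("vertex cloud is collinear; sections undefined")
    low = (evals[-1] - evals[-2]) / evals[-1] < LOW_ANISOTROPY_RATIO
    if low:
        logger.warning(
            "principal axis is ambiguous (top eigenvalues within %.0f%%)",
            100 * LOW_ANISOTROPY_RATIO,
        )
    axis = evecs[:, -1]
    t = (verts - centroid) @ axis
    n_points = max(int(n_points), 2)
    stations = np.linspace(t.min(), t.max(), n_points)
    pts = centroid + stations[:, None] * axis
    return CenterLine(pts, low_anisotropy=bool(low))


def place_planes(
    cl: CenterLine,
    n_sections: int | None = None,
    step: float | None = None,
) -> list[SectionPlane]:
    """Place slicing planes equally spaced in arc length over the line.

    Exactly one of ``n_sections`` / ``step`` must be given. Stations sit at
    ``(i + 1/2) * spacing`` so both ends are inset by half a step. A step
    longer than the line yields a single mid-line plane with a warning.
    """
    if (n_sections is None) == (step is None):
        raise ValueError("give exactly one of n_sections or step")
    L = cl.length
    if n_sections is not None:
        if n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        spacing = L / n_sections
        stations = (np.arange(n_sections) + 0.5) * spacing
    else:
        if step <= 0:
            raise ValueError("step must be > 0")
        if step > L:
            logger.warning(
                "step %.4g exceeds center-line length %.4g; "
                "placing a single mid-line plane",
                step,
                L,
            )
            stations = np.array([L / 2.0])
        else:
            count = int(math.floor(L / step))
            stations = (np.arange(count) + 0.5) * step
    return [
        SectionPlane(origin=cl.point_at(s), normal=cl.tangent_at(s), station=float(s))
        for s in stations
    ]


def _chain_segments(
    segments: list[tuple[int, int]],
) -> tuple[list[list[int]], list[list[int]]]:
    """Chain segments (pairs of node ids) into closed loops and open chains.

    Nodes are mesh-edge ids; each segment is one triangle's crossing. On a
    watertight mesh every node has degree 2 and all chains close.
    Deterministic: walks start from the lowest available node id.
    """
    from collections import defaultdict

    incident: dict[int, list[int]] = defaultdict(list)
    for si, (a, b) in enumerate(segments):
        incident[a].append(si)
        incident[b].append(si)

    used = [False] * len(segments)

    def walk(start_node: int) -> list[int]:
        chain = [start_node]
        node = start_node
        while True:
            nxt_seg = None
            for si in incident[node]:
                if not used[si]:
                    nxt_seg = si
                    break
            if nxt_seg is None:
                break
            used[nxt_seg] = True
            a, b = segments[nxt_seg]
            node = b if a == node else a
            chain.append(node)
        return chain

    loops: list[list[int]] = []
    opens: list[list[int]] = []
    # open chains first: start at degree-1 (or odd-degree) nodes
    for node in sorted(incident):
        deg_free = sum(1 for si in incident[node] if not used[si])
        if deg_free % 2 == 1:
            chain = walk(node)
            if len(chain) > 1:
                opens.append(chain)
    # remaining segments form cycles
    for si in range(len(segments)):
        if used[si]:
            continue
        a, _ = segments[si]
        chain = walk(a)
        if chain[0] == chain[-1] and len(chain) > 3:
            loops.append(chain[:-1])
        elif len(chain) > 1:
            opens.append(chain)
    return loops, opens


def _ring_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(
        np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    )


def plane_mesh_intersection(mesh: TriMesh, plane: SectionPlane) -> SectionPolygon:
    """Intersect a mesh with a plane and chain the crossing segments into
    closed loops, projected into the plane's (u, v) frame.

    Loops are classified outer/hole by containment parity and normalized
    (outer counter-clockwise, holes clockwise). Open chains — possible only
    when the plane cuts a mesh boundary — are reported but excluded from
    property computation.
    """
    V, F = mesh.vertices, mesh.faces
    d = (V - plane.origin) @ plane.normal
    eps = 1e-9 * max(mesh.bbox_diagonal, 1.0)
    on_plane = np.abs(d) < eps
    if on_plane.any():
        d = d.copy()
        d[on_plane] = eps  # nudge on-plane vertices to the positive side
    sign = d > 0

    s0, s1, s2 = sign[F[:, 0]], sign[F[:, 1]], sign[F[:, 2]]
    crossing = ~((s0 & s1 & s2) | (~s0 & ~s1 & ~s2))
    fidx = np.flatnonzero(crossing)
    if not len(fidx):
        return SectionPolygon(loops=[], is_hole=[], plane=plane)

    nv = len(V)
    edge_point: dict[int, np.ndarray] = {}
    segments: list[tuple[int, int]] = []
    for fi in fidx:
        f = F[fi]
        nodes = []
        for k in range(3):
            i, j = int(f[k]), int(f[(k + 1) % 3])
            if sign[i] == sign[j]:
                continue
            key = min(i, j) * nv + max(i, j)  # undirected-edge id
            if key not in edge_point:
                t = d[i] / (d[i] - d[j])
                edge_point[key] = V[i] + t * (V[j] - V[i])
            nodes.append(key)
        if len(nodes) == 2:
            segments.append((nodes[0], nodes[1]))

    loop_keys, open_keys = _chain_segments(segments)
    if open_keys:
        logger.warning(
            "plane at station %.4g: %d open intersection chain(s) discarded "
            "from property computation",
            plane.station,
            len(open_keys),
        )

    loops2d = [
        plane.project(np.array([edge_point[k] for k in loop])) for loop in loop_keys
    ]
    opens2d = [
        plane.project(np.array([edge_point[k] for k in chain]))
        for chain in open_keys
    ]
    # drop numerically degenerate rings
    kept = [(r, abs(_ring_area(r))) for r in loops2d]
    loops2d = [r for r, a in kept if a > 0.0 and len(r) >= 3]

    # containment parity classification
    polys = [Polygon(r) for r in loops2d]
    is_hole: list[bool] = []
    for i, r in enumerate(loops2d):
        depth = sum(
            1
            for j, p in enumerate(polys)
            if j != i and p.contains(Point(r[0]))
        )
        is_hole.append(depth % 2 == 1)
    # normalize winding: outer CCW, hole CW
    normed = []
    for r, hole in zip(loops2d, is_hole):
        a = _ring_area(r)
        if (hole and a > 0) or (not hole and a < 0):
            r = r[::-1]
        normed.append(r)
    return SectionPolygon(
        loops=normed, is_hole=is_hole, plane=plane, open_chains=opens2d
    )


def _polygon_moments(loops: Sequence[np.ndarray]) -> tuple[float, np.ndarray, np.ndarray]:
    """Signed area, centroid and second central moment matrix of a polygonal
    region given as rings with orientation-encoded sign (CCW adds, CW
    subtracts). Closed-form Green's-theorem formulas."""
    A = 0.0
    Sx = Sy = 0.0
    Ixx = Iyy = Ixy = 0.0  # about the origin; Ixx = int y^2, Iyy = int x^2
    for ring in loops:
        x, y = ring[:, 0], ring[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        A += 0.5 * cross.sum()
        Sx += float(((x + xn) * cross).sum()) / 6.0
        Sy += float(((y + yn) * cross).sum()) / 6.0
        Iyy += float(((x * x + x * xn + xn * xn) * cross).sum()) / 12.0
        Ixx += float(((y * y + y * yn + yn * yn) * cross).sum()) / 12.0
        Ixy += float(
            ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum()
        ) / 24.0
    if A == 0:
        raise DegenerateSectionError("zero-area polygonal region")
    cx, cy = Sx / A, Sy / A
    mu20 = Iyy - A * cx * cx
    mu02 = Ixx - A * cy * cy
    mu11 = Ixy - A * cx * cy
    cov = np.array([[mu20, mu11], [mu11, mu02]]) / A
    return float(A), np.array([cx, cy]), cov


def section_properties(poly: SectionPolygon) -> SectionProperties:
    """Compute the nine properties of a cross-section.

    Area is outer minus holes (shoelace); perimeter sums all ring lengths
    including holes; the convex hull is taken over all ring vertices; axis
    lengths are those of the ellipse with the same normalized second
    central moments as the (hole-subtracted) region.
    """
    outer = [r for r, h in zip(poly.loops, poly.is_hole) if not h]
    if not outer:
        raise DegenerateSectionError("section has no closed outer loop")
    area, _, cov = _polygon_moments(poly.loops)
    if area <= 0:
        raise DegenerateSectionError(f"non-positive section area {area:.4g}")

    perimeter = 0.0
    for r in poly.loops:
        perimeter += float(np.linalg.norm(np.diff(
            np.vstack([r, r[:1]]), axis=0), axis=1).sum())

    allpts = np.vstack(poly.loops)
    hull = MultiPoint([tuple(p) for p in allpts]).convex_hull
    convex_area = float(hull.area)
    convex_perimeter = float(hull.length)

    evals = np.linalg.eigvalsh(cov)  # ascending
    evals = np.clip(evals, 0.0, None)
    minor = 4.0 * math.sqrt(evals[0])
    major = 4.0 * math.sqrt(evals[1])

    return SectionProperties(
        area=area,
        perimeter=perimeter,
        convex_area=convex_area,
        convex_perimeter=convex_perimeter,
        equivalent_diameter=math.sqrt(4.0 * area / math.pi),
        convexity_area=area / convex_area if convex_area > 0 else float("nan"),
        convexity_perimeter=(
            convex_perimeter / perimeter if perimeter > 0 else float("nan")
        ),
        minor_axis_length=minor,
        major_axis_length=major,
    )


def slice_and_measure(
    mesh: TriMesh,
    cl: CenterLine,
    n_sections: int | None = None,
    step: float | None = None,
) -> pd.DataFrame:
    """Slice a mesh along a center line and tabulate section properties.

    One row per plane, in station order; planes that miss the mesh yield
    NaN rows. Raises :class:`MissesObjectError` if every plane misses.
    """
    planes = place_planes(cl, n_sections=n_sections, step=step)
    rows = []
    any_hit = False
    for pl in planes:
        sec = plane_mesh_intersection(mesh, pl)
        rec: dict[str, float] = {"station": pl.station}
        if sec.is_empty:
            rec.update({f: np.nan for f in SectionProperties.FIELDS})
        else:
            any_hit = True
            rec.update(section_properties(sec).as_dict())
        rows.append(rec)
    if not any_hit:
        raise MissesObjectError(
            f"center line misses object: all {len(planes)} sections are empty"
        )
    return pd.DataFrame(rows, columns=["station", *SectionProperties.FIELDS])
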