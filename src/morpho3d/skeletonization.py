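"""Topology-preserving skeletons of voxelized objects, TEASAR-style.

The skeletonizer follows the penalized-shortest-path family of algorithms:

1. compute the Euclidean distance-to-boundary field (DBF) of the
   foreground, anisotropy-aware;
2. per connected component, find a root by two-pass farthest-point search
   (geodesic, 26-connectivity, physical edge lengths), recentered onto the
   DBF ridge by a bounded strict ascent;
3. repeatedly pick the farthest not-yet-invalidated voxel, recenter it,
   and trace the shortest path from it to the current skeleton through a
   penalty field that rewards staying near the DBF ridge
   (penalty ~ (1 - DBF/DBF_max)^p with p = 4); record the path as skeleton
   nodes with radius = DBF;
4. invalidate every voxel within ``scale * DBF(node) + const`` of each
   path node; stop when none remain;
5. prune leaf spurs shorter than ``max(2 * DBF(junction), const)``.

All tie-breaks go to the lowest linear voxel index, so identical input and
parameters give an identical skeleton. Node coordinates are physical
(x, y, z); radii are the DBF values (µm).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra
from scipy.spatial import cKDTree

from .errors import FormatError, OpenMeshError
from .mesh_core import watertight_info
from .mesh_io import TriMesh
from .voxel_mesh import LabelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "Skeleton",
    "voxelize",
    "skeletonize",
    "skeleton_length",
    "write_swc",
    "read_swc",
]

PENALTY_EXPONENT = 4  # sharpens ridge-following along the DBF crest
PENALTY_AMPLITUDE = 5000.0


@dataclass
class Skeleton:
    """Center-line graph: nodes with local radii, tree edges, roots.

    ``nodes``: (n, 3) physical (x, y, z); ``radii``: (n,) local
    distance-to-boundary; ``edges``: (m, 2) node-index pairs; ``roots``:
    one node index per connected component.
    """

    nodes: np.ndarray
    radii: np.ndarray
    edges: np.ndarray
    roots: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.float64).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=np.float64).reshape(-1)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if len(self.radii) != len(self.nodes):
            raise ValueError("radii/nodes length mismatch")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= len(self.nodes):
                raise ValueError("edge index out of range")
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("skeleton has a self-loop")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def skeleton_length(sk: Skeleton) -> float:
    """Total arc length: sum of Euclidean edge lengths (0 for empty)."""
    if not len(sk.edges):
        return 0.0
    d = sk.nodes[sk.edges[:, 0]] - sk.nodes[sk.edges[:, 1]]
    return float(np.linalg.norm(d, axis=1).sum())


# ---------------------------------------------------------------------------
# voxelization (mesh -> binary volume)


def voxelize(mesh: TriMesh, spacing) -> LabelVolume:
    """Voxelize a watertight mesh: a voxel is foreground iff its center is
    inside the surface (parity of triangle crossings along +x).

    ``spacing`` is (z, y, x) physical voxel size. The grid covers the mesh
    bounding box padded by 2 voxels on every side.
    """
    info = watertight_info(mesh)
    if not info.is_watertight:
        raise OpenMeshError(
            f"cannot voxelize open mesh '{mesh.name}'",
            boundary_edge_count=info.boundary_edge_count,
        )
    sz, sy, sx = (float(s) for s in spacing)
    if min(sz, sy, sx) <= 0:
        raise ValueError("spacing must be positive")
    lo = mesh.vertices.min(axis=0)  # (x, y, z)
    hi = mesh.vertices.max(axis=0)
    nx = int(np.ceil((hi[0] - lo[0]) / sx)) + 5
    ny = int(np.ceil((hi[1] - lo[1]) / sy)) + 5
    nz = int(np.ceil((hi[2] - lo[2]) / sz)) + 5
    origin = (lo[0] - 2 * sx, lo[1] - 2 * sy, lo[2] - 2 * sz)  # (x, y, z)

    xs = origin[0] + np.arange(nx) * sx
    ys = origin[1] + np.arange(ny) * sy
    zs = origin[2] + np.arange(nz) * sz
    # tiny irrational offsets push rays off edges/vertices (deterministic)
    ys_r = ys + 1.003641e-7 * sy
    zs_r = zs + 1.007213e-7 * sz

    # crossing x-locations per (z, y) ray, accumulated per triangle
    crossings: list[list[float]] = [[] for _ in range(nz * ny)]
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    for t in tri:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = t
        ymin, ymax = min(y0, y1, y2), max(y0, y1, y2)
        zmin, zmax = min(z0, z1, z2), max(z0, z1, z2)
        j0 = int(np.searchsorted(ys_r, ymin))
        j1 = int(np.searchsorted(ys_r, ymax))
        k0 = int(np.searchsorted(zs_r, zmin))
        k1 = int(np.searchsorted(zs_r, zmax))
        yy = ys_r[j0:j1]
        zz = zs_r[k0:k1]
        if not len(yy) or not len(zz):
            continue
        # barycentric coordinates in the (y, z) projection
        det = (y1 - y0) * (z2 - z0) - (y2 - y0) * (z1 - z0)
        if det == 0.0:
            continue  # triangle parallel to the ray direction
        Y, Z = np.meshgrid(yy, zz, indexing="ij")
        w1 = ((Y - y0) * (z2 - z0) - (y2 - y0) * (Z - z0)) / det
        w2 = ((y1 - y0) * (Z - z0) - (Y - y0) * (z1 - z0)) / det
        inside = (w1 >= 0) & (w2 >= 0) & (w1 + w2 <= 1)
        if not inside.any():
            continue
        Xc = x0 + w1 * (x1 - x0) + w2 * (x2 - x0)
        jj, kk = np.nonzero(inside)
        for j, k in zip(jj, kk):
            crossings[(k + k0) * ny + (j + j0)].append(float(Xc[j, k]))

    data = np.zeros((nz, ny, nx), dtype=np.int64)
    for k in range(nz):
        for j in range(ny):
            xc = crossings[k * ny + j]
            if not xc:
                continue
            xc = np.sort(np.array(xc))
            # parity of crossings to the right of each voxel center
            n_right = len(xc) - np.searchsorted(xc, xs)
            data[k, j, :] = (n_right % 2).astype(np.int64)
    return LabelVolume(data=data, spacing=(sz, sy, sx), origin=origin)


# ---------------------------------------------------------------------------
# skeletonization


def _neighbor_offsets(spacing) -> tuple[np.ndarray, np.ndarray]:
    """26-connectivity offsets (z, y, x) and their physical lengths."""
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                offs.append((dz, dy, dx))
    offs = np.array(offs, dtype=np.int64)
    sz, sy, sx = spacing
    lens = np.linalg.norm(offs * np.array([sz, sy, sx]), axis=1)
    return offs, lens


def _component_graph(comp_idx: np.ndarray, shape, spacing, weights_per_node=None):
    """Sparse undirected graph over component voxels (26-connectivity).

    ``comp_idx``: sorted linear indices of component voxels. Edge weight is
    the physical center distance, optionally multiplied by the mean of the
    two endpoint node weights.
    """
    nz, ny, nx = shape
    pos = -np.ones(nz * ny * nx, dtype=np.int64)
    pos[comp_idx] = np.arange(len(comp_idx))
    zyx = np.stack(np.unravel_index(comp_idx, shape), axis=1)
    offs, lens = _neighbor_offsets(spacing)
    rows, cols, vals = [], [], []
    for o, L in zip(offs, lens):
        nb = zyx + o
        ok = (
            (nb[:, 0] >= 0) & (nb[:, 0] < nz)
            & (nb[:, 1] >= 0) & (nb[:, 1] < ny)
            & (nb[:, 2] >= 0) & (nb[:, 2] < nx)
        )
        src = np.flatnonzero(ok)
        lin = np.ravel_multi_index(tuple(nb[ok].T), shape)
        tgt = pos[lin]
        hit = tgt >= 0
        src = src[hit]
        tgt = tgt[hit]
        w = np.full(len(src), L)
        if weights_per_node is not None:
            w = w * 0.5 * (weights_per_node[src] + weights_per_node[tgt])
        rows.append(src)
        cols.append(tgt)
        vals.append(w)
    n = len(comp_idx)
    return csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def skeletonize(
    vol: LabelVolume,
    scale: float = 2.0,
    const: float | None = None,
    prune_spurs: bool = True,
) -> Skeleton:
    """Skeletonize the foreground of a label volume (all labels > 0).

    Parameters
    ----------
    scale, const
        Invalidation ball radius around each accepted path node is
        ``scale * DBF(node) + const``. ``const`` defaults to one mean
        voxel length (physical units).
    prune_spurs
        Remove leaf branches shorter than ``max(2 * DBF(junction), const)``
        — voxelization whiskers.
    """
    mask = vol.data > 0
    if not mask.any():
        return Skeleton(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 2)), [])
    spacing = vol.spacing
    if const is None:
        const = float(np.mean(spacing))
    const = float(const)
    scale = float(scale)

    # anisotropy-aware DBF; pad so the array border counts as background
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dbf_full = ndimage.distance_transform_edt(padded, sampling=spacing)
    dbf_full = dbf_full[1:-1, 1:-1, 1:-1]

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    lab, n_comp = ndimage.label(mask, structure=structure)

    all_nodes: list[np.ndarray] = []
    all_radii: list[float] = []
    all_edges: list[tuple[int, int]] = []
    roots: list[int] = []

    for c in range(1, n_comp + 1):
        comp_idx = np.flatnonzero((lab == c).ravel())  # sorted = lowest-first
        n = len(comp_idx)
        dbf = dbf_full.ravel()[comp_idx]
        zyx = np.stack(np.unravel_index(comp_idx, vol.shape), axis=1)
        coords = vol.voxel_centers_xyz(zyx)  # physical (x, y, z)

        if n == 1:
            node_id = len(all_radii)
            all_nodes.append(coords[0])
            all_radii.append(float(dbf[0]))
            roots.append(node_id)
            continue

        graph_eucl = _component_graph(comp_idx, vol.shape, spacing)
        # two-pass farthest point: seed = lowest linear index
        d0 = _sp_dijkstra(graph_eucl, directed=False, indices=0)
        root = int(np.argmax(d0))  # ties -> lowest index

        # bounded DBF ascent: recenter endpoints onto the local ridge, never
        # travelling farther than the endpoint's own invalidation radius
        nz_, ny_, nx_ = vol.shape
        pos = -np.ones(nz_ * ny_ * nx_, dtype=np.int64)
        pos[comp_idx] = np.arange(n)
        offs, off_lens = _neighbor_offsets(spacing)

        def recenter(v: int) -> int:
            # strict DBF ascent; total travel may not exceed the invalidation
            # radius earned at the voxel reached (scale * DBF + const), so the
            # original endpoint always falls inside the final node's ball
            travelled = 0.0
            while True:
                nb = zyx[v] + offs
                ok = (
                    (nb[:, 0] >= 0) & (nb[:, 0] < nz_)
                    & (nb[:, 1] >= 0) & (nb[:, 1] < ny_)
                    & (nb[:, 2] >= 0) & (nb[:, 2] < nx_)
                )
                cand = pos[np.ravel_multi_index(tuple(nb[ok].T), vol.shape)]
                lens_ok = off_lens[ok]
                good = cand >= 0
                cand, lens_ok = cand[good], lens_ok[good]
                if not len(cand):
                    break
                gain = dbf[cand] - dbf[v]
                afford = travelled + lens_ok <= scale * dbf[cand] + const
                score = np.where((gain > 0) & afford, gain, -np.inf)
                best = int(np.argmax(score))  # first (lowest-index offset) on ties
                if not np.isfinite(score[best]):
                    break
                travelled += float(lens_ok[best])
                v = int(cand[best])
            return v

        root = recenter(root)
        d_root = _sp_dijkstra(graph_eucl, directed=False, indices=root)

        dbf_max = float(dbf.max())
        penalty = 1.0 + PENALTY_AMPLITUDE * (1.0 - dbf / dbf_max) ** PENALTY_EXPONENT
        graph_pen = _component_graph(
            comp_idx, vol.shape, spacing, weights_per_node=penalty
        )

        tree = cKDTree(coords)
        valid = np.ones(n, dtype=bool)
        node_id_of: dict[int, int] = {}
        comp_edges: list[tuple[int, int]] = []
        skeleton_voxels: list[int] = [root]
        skeleton_set = {root}

        def add_node(v: int) -> int:
            if v in node_id_of:
                return node_id_of[v]
            nid = len(all_radii)
            all_nodes.append(coords[v])
            all_radii.append(float(dbf[v]))
            node_id_of[v] = nid
            return nid

        add_node(root)
        while valid.any():
            dmask = np.where(valid, d_root, -np.inf)
            raw_target = int(np.argmax(dmask))
            target = recenter(raw_target)
            # penalized search from the current skeleton; the new path ends
            # where it first touches an already-skeletonized voxel
            _, pred, _ = _sp_dijkstra(
                graph_pen,
                directed=False,
                indices=skeleton_voxels,
                return_predecessors=True,
                min_only=True,
            )
            path = [target]
            v = target
            while pred[v] >= 0:
                v = int(pred[v])
                path.append(v)
            # record nodes/edges
            prev_nid = None
            for v in path:
                nid = add_node(v)
                if prev_nid is not None and prev_nid != nid:
                    comp_edges.append((min(prev_nid, nid), max(prev_nid, nid)))
                prev_nid = nid
            # invalidate neighborhoods of the whole path
            radii_ball = scale * dbf[path] + const
            for v, rad in zip(path, radii_ball):
                for w in tree.query_ball_point(coords[v], rad):
                    valid[w] = False
            valid[path] = False
            valid[raw_target] = False  # guarantee progress
            for v in path:
                if v not in skeleton_set:
                    skeleton_set.add(v)
                    skeleton_voxels.append(v)

        comp_edges = sorted(set(comp_edges))
        all_edges.extend(comp_edges)
        roots.append(node_id_of[root])

    sk = Skeleton(
        nodes=np.array(all_nodes, dtype=np.float64).reshape(-1, 3),
        radii=np.array(all_radii, dtype=np.float64),
        edges=np.array(sorted(set(all_edges)), dtype=np.int64).reshape(-1, 2),
        roots=roots,
    )
    if prune_spurs:
        sk = _prune_spurs(sk, const)
    return sk


def _prune_spurs(sk: Skeleton, const: float) -> Skeleton:
    """Iteratively delete leaf branches shorter than
    ``max(2 * DBF(junction), const)``. Pure paths (no junction) are kept."""
    nodes, radii = sk.nodes, sk.radii
    edges = {tuple(e) for e in sk.edges.tolist()}
    roots = set(sk.roots)

    def neighbors(adjacency, v):
        return adjacency.get(v, set())

    changed = True
    while changed:
        changed = False
        adjacency: dict[int, set[int]] = {}
        for a, b in edges:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
        deg = {v: len(s) for v, s in adjacency.items()}
        leaves = sorted(v for v, d in deg.items() if d == 1)
        for leaf in leaves:
            if deg.get(leaf, 0) != 1:
                continue  # may have changed this sweep
            # walk toward the first junction
            branch = [leaf]
            prev, cur = None, leaf
            while True:
                nxt = [w for w in neighbors(adjacency, cur) if w != prev]
                if deg.get(cur, 0) >= 3 or not nxt:
                    break
                prev, cur = cur, nxt[0]
                branch.append(cur)
            junction = branch[-1]
            if deg.get(junction, 0) < 3:
                continue  # pure path component: keep
            length = float(
                np.linalg.norm(np.diff(nodes[branch], axis=0), axis=1).sum()
            )
            threshold = max(2.0 * radii[junction], const)
            if length < threshold:
                doomed = branch[:-1]
                for a, b in list(edges):
                    if a in doomed or b in doomed:
                        edges.discard((a, b))
                for v in doomed:
                    adjacency.pop(v, None)
                    deg.pop(v, None)
                for v, s in adjacency.items():
                    s.difference_update(doomed)
                deg.update({v: len(s) for v, s in adjacency.items()})
                changed = True

    # compact node ids (keep roots and every node still referenced)
    used = sorted(roots | {v for e in edges for v in e})
    remap = {v: i for i, v in enumerate(used)}
    new_edges = np.array(
        sorted((remap[a], remap[b]) for a, b in edges), dtype=np.int64
    ).reshape(-1, 2)
    return Skeleton(
        nodes=nodes[used],
        radii=radii[used],
        edges=new_edges,
        roots=[remap[r] for r in sk.roots if r in remap],
    )


# ---------------------------------------------------------------------------
# SWC serialization


def write_swc(sk: Skeleton, path: str | os.PathLike) -> Path:
    """Write a skeleton as SWC: ``id type x y z radius parent``, 1-based
    ids, roots with parent -1, children after parents."""
    adjacency: dict[int, list[int]] = {}
    for a, b in sk.edges:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))
    n = sk.n_nodes
    order: list[int] = []
    parent: dict[int, int] = {}
    seen = np.zeros(n, dtype=bool)
    starts = list(sk.roots) + [v for v in range(n)]
    for s in starts:
        if s >= n or seen[s]:
            continue
        parent[s] = -1
        stack = [s]
        seen[s] = True
        while stack:
            v = stack.pop()
            order.append(v)
            for w in sorted(adjacency.get(v, []), reverse=True):
                if not seen[w]:
                    seen[w] = True
                    parent[w] = v
                    stack.append(w)
    if len(order) != n:
        raise ValueError("skeleton graph inconsistent with node count")
    # detect cycles: a tree/forest has |E| = |V| - #components
    n_comp = sum(1 for v in order if parent[v] == -1)
    if len(sk.edges) != n - n_comp:
        raise ValueError("skeleton is not a forest; cannot serialize as SWC")

    swc_id = {v: i + 1 for i, v in enumerate(order)}
    p = Path(path)
    with open(p, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for v in order:
            x, y, z = sk.nodes[v]
            par = parent[v]
            fh.write(
                f"{swc_id[v]} 0 {x:.9g} {y:.9g} {z:.9g} "
                f"{sk.radii[v]:.9g} {swc_id[par] if par >= 0 else -1}\n"
            )
    return p


def read_swc(path: str | os.PathLike) -> Skeleton:
    """Parse an SWC file back into a :class:`Skeleton`."""
    nodes, radii, parents, ids = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 7:
                raise FormatError(f"{path}:{lineno}: SWC row needs 7 fields")
            ids.append(int(parts[0]))
            nodes.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
    index = {i: k for k, i in enumerate(ids)}
    edges = []
    roots = []
    for k, par in enumerate(parents):
        if par == -1:
            roots.append(k)
        else:
            if par not in index:
                raise FormatError(f"{path}: parent id {par} not defined")
            a, b = index[par], k
            edges.append((min(a, b), max(a, b)))
    return Skeleton(
        nodes=np.array(nodes).reshape(-1, 3),
        radii=np.array(radii),
        edges=np.array(sorted(edges), dtype=np.int64).reshape(-1, 2),
        roots=roots,
    )
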