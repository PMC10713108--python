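"""Straight-line and on-surface distances between points on a mesh.

The surface distance is the shortest path over the mesh's vertex–edge
graph (Dijkstra, edge weights = Euclidean edge lengths). Restricting paths
to mesh edges — no Steiner points, no exact polyhedral geodesics — makes
the result an upper bound on the true surface geodesic and keeps it
exactly reproducible. Points are attached to the surface by nearest-vertex
snapping; the snap distance is surfaced so bad picks are detectable.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .errors import UnreachableError
from .mesh_io import TriMesh

__all__ = [
    "SurfacePoint",
    "DistanceResult",
    "snap_to_surface",
    "straight_distance",
    "surface_distance",
    "vertex_adjacency",
]


@dataclass
class SurfacePoint:
    """A user point snapped to the nearest mesh vertex."""

    mesh_name: str
    vertex_index: int
    raw_point: np.ndarray
    snapped_point: np.ndarray
    snap_distance: float


@dataclass
class DistanceResult:
    """Straight and on-surface distance plus the realizing edge path."""

    straight: float
    surface: float
    path: list[int]


def snap_to_surface(mesh: TriMesh, p) -> SurfacePoint:
    """Snap a 3D point to the nearest mesh vertex (ties -> lowest index)."""
    p = np.asarray(p, dtype=np.float64).reshape(3)
    if not mesh.n_vertices:
        raise ValueError("cannot snap to an empty mesh")
    d = np.linalg.norm(mesh.vertices - p, axis=1)
    idx = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
    return SurfacePoint(
        mesh_name=mesh.name,
        vertex_index=idx,
        raw_point=p,
        snapped_point=mesh.vertices[idx].copy(),
        snap_distance=float(d[idx]),
    )


def straight_distance(a: SurfacePoint, b: SurfacePoint) -> float:
    """Euclidean distance between the snapped vertex positions (works
    across different meshes)."""
    return float(np.linalg.norm(a.snapped_point - b.snapped_point))


def vertex_adjacency(mesh: TriMesh) -> list[list[tuple[int, float]]]:
    """Adjacency list of the vertex–edge graph with Euclidean weights,
    neighbor lists sorted by index (deterministic iteration order)."""
    f = mesh.faces
    pairs = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0)
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    w = np.linalg.norm(
        mesh.vertices[pairs[:, 0]] - mesh.vertices[pairs[:, 1]], axis=1
    )
    adj: list[list[tuple[int, float]]] = [[] for _ in range(mesh.n_vertices)]
    for (i, j), L in zip(pairs, w):
        adj[i].append((int(j), float(L)))
        adj[j].append((int(i), float(L)))
    for lst in adj:
        lst.sort()
    return adj


def _vertex_components(mesh: TriMesh) -> np.ndarray:
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    n = mesh.n_vertices
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return _cc(adj, directed=False)[1]


def surface_distance(
    mesh: TriMesh, a: SurfacePoint, b: SurfacePoint
) -> DistanceResult:
    """Shortest path between two snapped points over the mesh edge graph.

    Dijkstra with deterministic tie-breaking: among equal-length paths the
    one with the lexicographically smallest predecessor is kept. Raises
    :class:`UnreachableError` if the points lie in different connected
    components.
    """
    src, dst = a.vertex_index, b.vertex_index
    if src == dst:
        return DistanceResult(0.0, 0.0, [src])

    adj = vertex_adjacency(mesh)
    n = mesh.n_vertices
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=np.int64)
    dist[src] = 0.0
    heap: list[tuple[float, int]] = [(0.0, src)]
    done = np.zeros(n, dtype=bool)
    while heap:
        d, v = heapq.heappop(heap)
        if done[v]:
            continue
        done[v] = True
        if v == dst:
            break
        for w, L in adj[v]:
            nd = d + L
            if nd < dist[w]:
                dist[w] = nd
                pred[w] = v
                heapq.heappush(heap, (nd, w))
            elif nd == dist[w] and pred[w] > v:
                pred[w] = v  # lexicographic predecessor tie-break

    if not np.isfinite(dist[dst]):
        comps = _vertex_components(mesh)
        raise UnreachableError(
            f"vertices {src} and {dst} of mesh '{mesh.name}' are in different "
            f"components ({comps[src]} vs {comps[dst]})",
            component_a=int(comps[src]),
            component_b=int(comps[dst]),
        )
    path = [dst]
    v = dst
    while v != src:
        v = int(pred[v])
        path.append(v)
    path.reverse()
    return DistanceResult(
        straight=straight_distance(a, b),
        surface=float(dist[dst]),
        path=path,
    )
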