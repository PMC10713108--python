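"""Wavefront OBJ input/output and the internal triangle-mesh type.

The OBJ dialect consumed is deliberately small: ``v`` and ``f`` records
carry the geometry; ``o``/``g`` names attach to the mesh; ``vt``/``vn``
components of face tokens (``i/t``, ``i//n``, ``i/t/n``) are parsed and
discarded; materials and all other records are ignored. Indices are 1-based
in the file and 0-based in memory; negative (relative) indices are resolved
against the vertices defined so far, per the OBJ standard.

On load, faces with repeated vertex indices or zero area are dropped (with
a logged count), windings are made consistent per connected component, and
closed components are flipped so their enclosed volume is non-negative.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError

logger = logging.getLogger(__name__)

__all__ = ["TriMesh", "read_obj", "write_obj", "bulk_import", "BulkImportResult"]


@dataclass
class TriMesh:
    """Indexed triangle surface in physical units.

    Parameters
    ----------
    name : str
        Identifier, usually the source file stem or a generator tag.
    vertices : (n, 3) float array
        Vertex coordinates (x, y, z), physical units (µm by convention).
    faces : (m, 3) int array
        Vertex-index triples, 0-based.
    provenance : str
        Source path or generator tag.

    Degenerate faces (repeated indices or zero area) are dropped at
    construction; the count is logged and stored in ``dropped_faces``.
    """

    name: str
    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""
    dropped_faces: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise ValueError(f"mesh '{self.name}': non-finite vertex coordinates")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError(
                f"mesh '{self.name}': face index out of range [0, {n})"
            )
        keep = _nondegenerate_mask(self.vertices, self.faces)
        dropped = int(len(self.faces) - keep.sum())
        if dropped:
            logger.warning(
                "mesh '%s': dropped %d degenerate face(s)", self.name, dropped
            )
            self.faces = self.faces[keep]
        self.dropped_faces += dropped

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bbox_diagonal(self) -> float:
        if not len(self.vertices):
            return 0.0
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.name, self.vertices.copy(), self.faces.copy(), self.provenance
        )


def _nondegenerate_mask(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """True for faces with three distinct indices and nonzero area."""
    if not len(faces):
        return np.ones(0, dtype=bool)
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    a, b, c = (vertices[faces[:, k]] for k in range(3))
    area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
    return distinct & (area2 > 0.0)


def orient_consistently(mesh: TriMesh) -> TriMesh:
    """Enforce consistent winding per connected component; flip closed
    components whose signed enclosed volume is negative.

    Returns a new mesh; face order is preserved, only windings may flip.
    """
    faces = mesh.faces.copy()
    m = len(faces)
    if m == 0:
        return mesh.copy()

    # undirected-edge -> incident faces
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi in range(m):
        f = faces[fi]
        for k in range(3):
            e = (f[k], f[(k + 1) % 3])
            key = (min(e), max(e))
            edge_faces.setdefault(key, []).append(fi)

    visited = np.zeros(m, dtype=bool)
    verts = mesh.vertices
    for start in range(m):
        if visited[start]:
            continue
        comp: list[int] = []
        stack = [start]
        visited[start] = True
        while stack:
            fi = stack.pop()
            comp.append(fi)
            f = faces[fi]
            directed = {(f[k], f[(k + 1) % 3]) for k in range(3)}
            for k in range(3):
                e = (f[k], f[(k + 1) % 3])
                key = (min(e), max(e))
                for fj in edge_faces[key]:
                    if fj == fi or visited[fj]:
                        continue
                    g = faces[fj]
                    neighbor_dir = {(g[kk], g[(kk + 1) % 3]) for kk in range(3)}
                    # consistent winding: shared edge traversed in opposite
                    # directions by the two faces
                    if directed & neighbor_dir:
                        faces[fj] = g[::-1]
                    visited[fj] = True
                    stack.append(fj)
        comp_arr = np.array(comp)
        cf = faces[comp_arr]
        # closed component check: every undirected edge used exactly twice
        closed = True
        for fi in comp:
            f = faces[fi]
            for k in range(3):
                e = (f[k], f[(k + 1) % 3])
                if len(edge_faces[(min(e), max(e))]) != 2:
                    closed = False
                    break
            if not closed:
                break
        if closed:
            a, b, c = verts[cf[:, 0]], verts[cf[:, 1]], verts[cf[:, 2]]
            vol6 = np.einsum("ij,ij->i", a, np.cross(b, c)).sum()
            if vol6 < 0:
                faces[comp_arr] = cf[:, ::-1]
    out = mesh.copy()
    out.faces = faces
    return out


def _parse_face_token(tok: str, n_vertices: int, lineno: int, path: str) -> int:
    idx_str = tok.split("/")[0]
    try:
        idx = int(idx_str)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: bad face token '{tok}'") from exc
    if idx > 0:
        out = idx - 1
    elif idx < 0:
        out = n_vertices + idx  # relative to vertices defined so far
    else:
        raise FormatError(f"{path}:{lineno}: OBJ face index 0 is invalid")
    if not (0 <= out < n_vertices):
        raise FormatError(
            f"{path}:{lineno}: face index {idx} out of range "
            f"(only {n_vertices} vertices defined)"
        )
    return out


def read_obj(path: str | os.PathLike) -> TriMesh:
    """Read a Wavefront OBJ file into a :class:`TriMesh`.

    Polygon faces are fan-triangulated from their first vertex. The mesh
    name is the first ``o``/``g`` record, else the file stem.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"OBJ file not found: {p}")
    vertices: list[list[float]] = []
    tris: list[tuple[int, int, int]] = []
    name: str | None = None
    with open(p, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            rec = parts[0]
            if rec == "v":
                if len(parts) < 4:
                    raise FormatError(f"{p}:{lineno}: vertex needs 3 coordinates")
                try:
                    vertices.append([float(x) for x in parts[1:4]])
                except ValueError as exc:
                    raise FormatError(f"{p}:{lineno}: bad vertex coordinate") from exc
            elif rec == "f":
                if len(parts) < 4:
                    raise FormatError(f"{p}:{lineno}: face needs >= 3 vertices")
                idx = [
                    _parse_face_token(t, len(vertices), lineno, str(p))
                    for t in parts[1:]
                ]
                for k in range(1, len(idx) - 1):  # fan triangulation
                    tris.append((idx[0], idx[k], idx[k + 1]))
            elif rec in ("o", "g") and len(parts) > 1 and name is None:
                name = parts[1]
    if not vertices:
        raise FormatError(f"{p}: no vertex records")
    if not tris:
        raise FormatError(f"{p}: no face records")
    mesh = TriMesh(
        name=name or p.stem,
        vertices=np.array(vertices, dtype=np.float64),
        faces=np.array(tris, dtype=np.int64),
        provenance=str(p),
    )
    return orient_consistently(mesh)


def write_obj(mesh: TriMesh, path: str | os.PathLike) -> Path:
    """Write a mesh as ASCII Wavefront OBJ (1-based indices, >=6 significant
    digits per coordinate). The output is parseable by :func:`read_obj`."""
    p = Path(path)
    with open(p, "w") as fh:
        fh.write(f"o {mesh.name or 'object'}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    return p


class BulkImportResult(list):
    """List of :class:`TriMesh` plus a record of files skipped on error.

    ``skipped`` holds ``(path, reason)`` pairs for files that failed to
    parse; one bad file never aborts the batch.
    """

    def __init__(self, meshes: Iterable[TriMesh] = (), skipped: Sequence = ()):
        super().__init__(meshes)
        self.skipped: list[tuple[str, str]] = list(skipped)


def bulk_import(folder: str | os.PathLike) -> BulkImportResult:
    """Import every ``*.obj`` file in *folder* (case-insensitive extension),
    sorted lexicographically by filename. Unreadable files are skipped with
    a logged warning and recorded in the result's ``skipped`` metadata."""
    d = Path(folder)
    if not d.is_dir():
        raise FileNotFoundError(f"not a directory: {d}")
    files = sorted(
        (f for f in d.iterdir() if f.is_file() and f.suffix.lower() == ".obj"),
        key=lambda f: f.name,
    )
    meshes: list[TriMesh] = []
    skipped: list[tuple[str, str]] = []
    for f in files:
        try:
            mesh = read_obj(f)
            mesh.name = f.stem
            meshes.append(mesh)
        except (FormatError, OSError) as exc:
            logger.warning("bulk import: skipping %s (%s)", f, exc)
            skipped.append((str(f), str(exc)))
    return BulkImportResult(meshes, skipped)
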