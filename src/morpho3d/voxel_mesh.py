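"""Label volumes from TIFF stacks and their conversion to surface meshes.

A :class:`LabelVolume` is a 3D grid of non-negative integer labels indexed
``(z, y, x)`` with per-axis physical voxel spacing (same order). Voxel
``(z, y, x) = i`` has its *center* at ``origin + i * spacing`` (voxel-center
convention); extracted meshes live in a right-handed ``(x, y, z)`` physical
frame.

Meshes are produced by marching cubes at iso-level 0.5 on the binary mask
of each label, after padding the mask by one background voxel on every
face so that objects touching the stack border still close up. The raw
marching-cubes surface is exported without smoothing or decimation, which
keeps area and volume deterministic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from skimage.measure import marching_cubes

from .errors import FormatError, MissingLabelError
from .mesh_io import TriMesh, orient_consistently

__all__ = ["LabelVolume", "read_label_stack", "labels_to_meshes"]


@dataclass
class LabelVolume:
    """3D integer-label grid with physical voxel spacing.

    Parameters
    ----------
    data : (nz, ny, nx) integer array
        Label per voxel; 0 is background.
    spacing : 3-sequence of float
        Physical voxel size per axis, order ``(z, y, x)``, all > 0.
    origin : 3-sequence of float
        Physical ``(x, y, z)`` coordinate of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("label volume must be 3D with >=1 voxel per axis")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume data must be integer-typed")
        if (self.data < 0).any():
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive components (z, y, x)")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def unique_labels(self) -> np.ndarray:
        """Labels present in the volume, background (0) excluded."""
        u = np.unique(self.data)
        return u[u != 0]

    def voxel_centers_xyz(self, indices_zyx: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) centers of the given (z, y, x) voxel indices."""
        idx = np.asarray(indices_zyx, dtype=np.float64).reshape(-1, 3)
        sz, sy, sx = self.spacing
        ox, oy, oz = self.origin
        out = np.empty_like(idx)
        out[:, 0] = ox + idx[:, 2] * sx
        out[:, 1] = oy + idx[:, 1] * sy
        out[:, 2] = oz + idx[:, 0] * sz
        return out


def _read_one_tiff(path: Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr


def read_label_stack(
    path: str | os.PathLike,
    spacing: Sequence[float],
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> LabelVolume:
    """Read a multi-page TIFF, or a directory of equally sized single-page
    TIFFs (slice order = lexicographic filename order), into a LabelVolume
    with z = slice index."""
    p = Path(path)
    if p.is_dir():
        files = sorted(
            f
            for f in p.iterdir()
            if f.is_file() and f.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise FormatError(f"no TIFF slices found in directory {p}")
        slices = [_read_one_tiff(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1 or slices[0].ndim != 2:
            raise FormatError(
                f"inconsistent slice shapes in {p}: {sorted(shapes)}"
            )
        data = np.stack(slices, axis=0)
    elif p.is_file():
        data = _read_one_tiff(p)
        if data.ndim == 2:
            data = data[None, ...]
        if data.ndim != 3:
            raise FormatError(f"{p}: expected 2D slices or a 3D stack")
    else:
        raise FileNotFoundError(f"no such file or directory: {p}")

    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=0, rtol=0):
            raise FormatError(
                f"{p}: non-integer pixel values cannot be interpreted as labels"
            )
        data = rounded.astype(np.int64)
    else:
        data = data.astype(np.int64)
    return LabelVolume(data=data, spacing=tuple(spacing), origin=tuple(origin))


def labels_to_meshes(
    vol: LabelVolume, labels: Sequence[int] | None = None
) -> dict[int, TriMesh]:
    """Convert each label's binary mask to a closed triangle mesh.

    Each mask is padded by one background voxel on every face (guaranteeing
    closed surfaces even at the stack border), marching cubes is run at
    iso-level 0.5, and vertices are scaled to physical units under the
    voxel-center convention. Returned meshes are watertight and oriented
    with non-negative enclosed volume.
    """
    present = set(int(l) for l in vol.unique_labels())
    if labels is None:
        wanted = sorted(present)
    else:
        wanted = sorted(int(l) for l in labels)
        missing = [l for l in wanted if l not in present]
        if missing:
            raise MissingLabelError(missing)
    if not wanted:
        raise ValueError("no foreground labels to mesh")

    sz, sy, sx = vol.spacing
    ox, oy, oz = vol.origin
    out: dict[int, TriMesh] = {}
    for lab in wanted:
        mask = np.pad(vol.data == lab, 1, mode="constant", constant_values=False)
        verts_zyx, faces, _, _ = marching_cubes(
            mask.astype(np.float32),
            level=0.5,
            spacing=(sz, sy, sx),
            allow_degenerate=False,
        )
        # undo the 1-voxel pad, map (z,y,x) -> (x,y,z), apply origin
        verts = np.empty_like(verts_zyx)
        verts[:, 0] = verts_zyx[:, 2] - sx + ox
        verts[:, 1] = verts_zyx[:, 1] - sy + oy
        verts[:, 2] = verts_zyx[:, 0] - sz + oz
        mesh = TriMesh(
            name=f"label_{lab}",
            vertices=verts,
            faces=faces,
            provenance=f"marching_cubes(label={lab})",
        )
        out[lab] = orient_consistently(mesh)
    return out
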