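"""Labelled voxel grid: the simulation domain.

The grid mirrors the T1-weighted MRI geometry: an integer tissue label per
voxel plus a voxel-index -> world-mm affine (voxel-center convention, 0-based
indices).  The transport engine requires an axis-aligned affine (diagonal
spacing, arbitrary translation), which is what the MRI-derived label volumes
and the synthetic phantoms provide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import nibabel as nib
import numpy as np

from .errors import GeometryError, OutOfGridError


@dataclass
class VoxelGrid:
    """3D label volume with world-coordinate bookkeeping.

    Parameters
    ----------
    labels : ndarray of int, shape (nx, ny, nz)
        Tissue label per voxel.
    affine : ndarray, shape (4, 4)
        Voxel-index (center) to world-mm transform.
    """

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be a 3D array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        self._inv_affine = np.linalg.inv(self.affine)

    # ------------------------------------------------------------ geometry

    @classmethod
    def from_spacing(cls, labels: np.ndarray, voxel_size_mm=1.0, origin_mm=(0.0, 0.0, 0.0)):
        """Axis-aligned grid: voxel (0,0,0) centered at ``origin_mm``."""
        vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
        affine = np.eye(4)
        affine[:3, :3] = np.diag(vs)
        affine[:3, 3] = origin_mm
        return cls(labels=np.asarray(labels), affine=affine)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis spacing in mm (requires an axis-aligned affine)."""
        self.require_axis_aligned()
        return np.diag(self.affine[:3, :3]).copy()

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def require_axis_aligned(self) -> None:
        m = self.affine[:3, :3]
        if not np.allclose(m, np.diag(np.diag(m))) or np.any(np.diag(m) <= 0):
            raise GeometryError(
                "this operation requires an axis-aligned affine with positive spacing"
            )

    @property
    def corner_origin_mm(self) -> np.ndarray:
        """World coordinates of the low corner of voxel (0, 0, 0)."""
        return self.affine[:3, 3] - 0.5 * self.voxel_size_mm

    @property
    def world_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        """(low, high) world corners of the grid (half-voxel margins included)."""
        lo = self.corner_origin_mm
        hi = lo + np.asarray(self.shape) * self.voxel_size_mm
        return lo, hi

    def world_to_continuous(self, point) -> np.ndarray:
        """Fractional voxel coordinates of a world point (center convention)."""
        p = np.append(np.asarray(point, dtype=float), 1.0)
        return (self._inv_affine @ p)[:3]

    def world_to_voxel(self, point) -> Tuple[int, int, int]:
        """Nearest voxel index of a world point; errors when out of bounds."""
        cont = self.world_to_continuous(point)
        idx = np.rint(cont).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise OutOfGridError(
                f"point {tuple(np.round(np.asarray(point, dtype=float), 3))} mm "
                f"is outside the grid (shape {self.shape})"
            )
        return tuple(int(i) for i in idx)

    def voxel_to_world(self, index) -> np.ndarray:
        idx = np.append(np.asarray(index, dtype=float), 1.0)
        return (self.affine @ idx)[:3]

    def contains_world(self, point) -> bool:
        cont = self.world_to_continuous(point)
        return bool(np.all(cont >= -0.5) and np.all(cont <= np.asarray(self.shape) - 0.5))

    def contains_segment(self, p0, p1, n_check: int = 64) -> bool:
        ts = np.linspace(0.0, 1.0, n_check)[:, None]
        pts = np.asarray(p0, dtype=float) + ts * (np.asarray(p1, dtype=float) - np.asarray(p0, dtype=float))
        return all(self.contains_world(p) for p in pts)

    # ----------------------------------------------------------------- I/O

    @classmethod
    def from_nifti(cls, path) -> "VoxelGrid":
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int16)
        return cls(labels=labels, affine=np.asarray(img.affine, dtype=float))

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.affine)
        nib.save(img, str(path))

    def map_to_nifti(self, values: np.ndarray, path) -> None:
        """Write a per-voxel scalar map (e.g. fluence) on this grid's geometry."""
        if values.shape != self.shape:
            raise ValueError(f"map shape {values.shape} != grid shape {self.shape}")
        img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), self.affine)
        nib.save(img, str(path))


def traverse_voxels(origin, direction, grid: VoxelGrid, max_length_mm: float | None = None
                    ) -> List[Tuple[Tuple[int, int, int], float]]:
    """Exact ray-voxel traversal: consecutive voxels and chord lengths (mm).

    Walks the ray ``origin + t * direction`` from a world point inside the
    grid until it leaves (or ``max_length_mm`` is reached), returning each
    crossed voxel with the chord length inside it.  Chord lengths sum to the
    in-grid ray length.
    """
    grid.require_axis_aligned()
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise GeometryError("direction vector must be non-zero")
    direction = direction / norm
    if not grid.contains_world(origin):
        raise OutOfGridError(f"ray origin {tuple(origin)} mm is outside the grid")

    vs = grid.voxel_size_mm
    pos = origin - grid.corner_origin_mm  # corner-frame coordinates
    idx = np.floor(pos / vs).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    out: List[Tuple[Tuple[int, int, int], float]] = []
    travelled = 0.0
    shape = np.asarray(grid.shape)
    while np.all(idx >= 0) and np.all(idx < shape):
        t_exit = np.inf
        axis, step = -1, 0
        for a in range(3):
            if direction[a] > 0:
                t = ((idx[a] + 1) * vs[a] - pos[a]) / direction[a]
                s = 1
            elif direction[a] < 0:
                t = (idx[a] * vs[a] - pos[a]) / direction[a]
                s = -1
            else:
                continue
            if t < t_exit:
                t_exit, axis, step = t, a, s
        t_exit = max(t_exit, 0.0)
        if max_length_mm is not None and travelled + t_exit >= max_length_mm:
            chord = max_length_mm - travelled
            if chord > 0:
                out.append((tuple(int(i) for i in idx), float(chord)))
            return out
        if axis < 0:  # zero direction (cannot happen after normalization)
            break
        out.append((tuple(int(i) for i in idx), float(t_exit)))
        pos = pos + direction * t_exit
        travelled += t_exit
        idx[axis] += step
    return out
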