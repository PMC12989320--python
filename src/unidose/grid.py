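"""Canonical volume grid and resampling.

Every array in a case (masks, channels, doses) lives on one shared isotropic
grid. Voxel indices are 0-based; world coordinates are in millimetres; the
centre of voxel ``(i, j, k)`` sits at ``origin_mm + index * spacing_mm``.
The canonical production spacing is 2 mm isotropic; all downstream modules
assume volumes have already been resampled to a single shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

CANONICAL_SPACING_MM = 2.0


@dataclass
class VolumeGrid:
    """A 3D scalar field with isotropic spacing and a world origin.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar field. Masks use {0, 1}; doses are in Gy or relative units.
    spacing_mm : float
        Isotropic voxel edge length in mm; must be positive.
    origin_mm : array-like of 3 floats
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D data")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """New grid with the same geometry but different values."""
        if values.shape != self.values.shape:
            raise ValueError(f"shape mismatch: {values.shape} vs {self.values.shape}")
        return VolumeGrid(values, self.spacing_mm, self.origin_mm.copy())

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing_mm - other.spacing_mm) <= atol
            and bool(np.allclose(self.origin_mm, other.origin_mm, atol=atol))
        )

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of fractional voxel indices, shape (..., 3)."""
        return self.origin_mm + np.asarray(indices, dtype=float) * self.spacing_mm

    def index_coords(self, points_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points, shape (..., 3)."""
        return (np.asarray(points_mm, dtype=float) - self.origin_mm) / self.spacing_mm

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape (nx, ny, nz, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.world_coords(idx)

    def center_mm(self) -> np.ndarray:
        """World coordinate of the geometric centre of the grid."""
        return self.world_coords((np.asarray(self.shape) - 1) / 2.0)


def zeros_like_grid(template: VolumeGrid) -> VolumeGrid:
    return template.like(np.zeros(template.shape))


def resample_isotropic(
    v: VolumeGrid, target_mm: float, mode: str = "linear"
) -> VolumeGrid:
    """Resample a volume to a new isotropic spacing.

    The field extent is preserved within one voxel: the output covers the same
    world-space region, with its first voxel centre at the input origin.
    ``mode='nearest'`` must be used for binary masks so they stay binary;
    ``mode='linear'`` interpolates trilinearly and is used for doses/channels.
    """
    if not target_mm > 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    if mode not in ("nearest", "linear"):
        raise ValueError(f"mode must be 'nearest' or 'linear', got {mode!r}")
    if abs(target_mm - v.spacing_mm) < 1e-12:
        return VolumeGrid(v.values.copy(), v.spacing_mm, v.origin_mm.copy())

    scale = v.spacing_mm / target_mm
    new_shape = tuple(max(1, int(np.ceil(n * scale))) for n in v.shape)
    # new voxel centres, expressed in input index coordinates
    axes = [np.arange(n) * target_mm / v.spacing_mm for n in new_shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        v.values, np.stack(mesh), order=order, mode="nearest"
    )
    return VolumeGrid(out.reshape(new_shape), target_mm, v.origin_mm.copy())
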