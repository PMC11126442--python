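"""Axis-aligned 3D image grids with world (mm) coordinates and NIfTI-1 I/O.

Convention used throughout the package: RAS-like axes, affine = diag(spacing)
with the origin at the volume corner; voxel indices are 0-based and the center
of voxel ``i`` sits at ``i * spacing + origin`` (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3D scalar grid plus the affine mapping voxel indices to world mm.

    Parameters
    ----------
    data:
        3D array of voxel values (any numeric dtype; masks are uint8).
    spacing:
        Voxel edge lengths in mm, one per axis. Must be positive.
    origin:
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.array([0.65] * 3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal by construction)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to world mm."""
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map world mm points (..., 3) to fractional voxel indices."""
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of voxel centers as an open meshgrid."""
        axes = [
            np.arange(n) * s + o
            for n, s, o in zip(self.shape, self.spacing, self.origin)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume on this grid carrying ``data``."""
        if data.shape != self.shape:
            raise ValueError(f"shape {data.shape} != grid shape {self.shape}")
        return ImageVolume(data, self.spacing.copy(), self.origin.copy())

    # -- I/O ----------------------------------------------------------------

    def save_nifti(self, path: str) -> None:
        img = nib.Nifti1Image(np.asanyarray(self.data), self.affine)
        img.header.set_zooms(tuple(self.spacing))
        nib.save(img, path)

    @classmethod
    def load_nifti(cls, path: str) -> "ImageVolume":
        img = nib.load(path)
        aff = img.affine
        lin = aff[:3, :3]
        if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
            raise ValueError(
                f"{path}: only axis-aligned (diagonal-affine) volumes are supported"
            )
        spacing = np.diag(lin).copy()
        origin = aff[:3, 3].copy()
        # fold negative axis scalings into the data so spacing stays positive
        data = np.asanyarray(img.dataobj)
        for ax in range(3):
            if spacing[ax] < 0:
                data = np.flip(data, axis=ax)
                origin[ax] = origin[ax] + spacing[ax] * (data.shape[ax] - 1)
                spacing[ax] = -spacing[ax]
        return cls(data, spacing, origin)
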