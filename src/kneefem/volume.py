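"""Voxel volumes in Hounsfield units (HU) with physical spacing and origin."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib


@dataclass
class CTVolume:
    """A CT-like scalar volume.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values in Hounsfield units. Axis order is (x, y, z).
    spacing : ndarray, shape (3,)
        Voxel edge length per axis, mm.
    origin : ndarray, shape (3,)
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm) to fractional voxel indices."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.origin) / self.spacing

    def sample_hu(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel HU lookup at world coordinates.

        Raises
        ------
        ValueError
            If any point falls outside the volume.
        """
        idx = np.rint(self.world_to_voxel(points)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise ValueError("sample point outside volume bounds")
        return self.data[idx[:, 0], idx[:, 1], idx[:, 2]]

    def contains(self, points: np.ndarray) -> np.ndarray:
        idx = np.rint(self.world_to_voxel(points)).astype(int)
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "CTVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        origin = affine[:3, 3]
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), spacing, origin)
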