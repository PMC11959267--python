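"""Lightweight 3D image container with world-coordinate metadata.

Volumes are stored as ``data[i, j, k]`` with world coordinates
``origin + (i, j, k) * spacing`` (axis-aligned, RAS-like, no rotation);
this matches how the voxelizer and the registration stage exchange
frames, and maps onto a diagonal NIfTI affine on disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Image3D"]


@dataclass
class Image3D:
    data: np.ndarray            # (nx, ny, nz) scalar volume
    spacing: tuple[float, float, float]   # mm
    origin: tuple[float, float, float]    # mm, world coordinate of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("Image3D requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "Image3D", atol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]

    # -- SimpleITK bridge ---------------------------------------------------

    def to_sitk(self):
        import SimpleITK as sitk

        # sitk indexes (x, y, z) from arrays ordered (z, y, x)
        img = sitk.GetImageFromArray(np.ascontiguousarray(
            self.data.transpose(2, 1, 0)).astype(np.float64))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img) -> "Image3D":
        import SimpleITK as sitk

        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()))

    # -- NIfTI I/O ----------------------------------------------------------

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag((*self.spacing, 1.0))
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "Image3D":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise ValueError(f"{path}: only axis-aligned volumes are supported")
        spacing = np.diag(rot)
        if np.any(spacing <= 0):
            raise ValueError(f"{path}: negative or zero voxel spacing")
        return cls(np.asanyarray(img.dataobj), tuple(spacing),
                   tuple(affine[:3, 3]))
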