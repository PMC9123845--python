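"""Grid-aligned 3D image and mask containers with NIfTI round-tripping.

Arrays are indexed ``(x, y, z)`` with the axial plane spanned by axes 0 and 1
and slices stacked along axis 2.  All downstream texture and morphology
operations are two-dimensional within axial slices, matching the strongly
anisotropic acquisition geometry (in-plane ~0.43 mm, 4 mm slices).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "MaskVolume",
    "check_aligned",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
]


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar intensity grid with voxel-spacing metadata."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.43, 0.43, 4.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"image data must be 3D, got shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive reals, got {vs}")
        self.voxel_size_mm = vs
        if self.affine is None:
            self.affine = np.diag([vs[0], vs[1], vs[2], 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        """New volume sharing this volume's grid metadata."""
        return ImageVolume(np.asarray(data, dtype=np.float64),
                           self.voxel_size_mm, self.affine.copy())


@dataclasses.dataclass
class MaskVolume:
    """A binary 3D grid aligned with an :class:`ImageVolume`.

    ``role`` records what the mask delineates (brain, wm, gm, csf, wmh,
    nawm, layer-k); it is carried as metadata only.
    """

    data: np.ndarray
    role: str = "generic"
    voxel_size_mm: tuple[float, float, float] = (0.43, 0.43, 4.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    f"mask '{self.role}' is non-binary: values {vals[:10]}")
            arr = arr.astype(bool)
        self.data = arr
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be positive, got {vs}")
        self.voxel_size_mm = vs
        if self.affine is None:
            self.affine = np.diag([vs[0], vs[1], vs[2], 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.voxel_size_mm))

    def copy_with(self, data: np.ndarray, role: str | None = None) -> "MaskVolume":
        return MaskVolume(np.asarray(data, dtype=bool), role or self.role,
                          self.voxel_size_mm, self.affine.copy())


def check_aligned(a, b, name_a: str = "image", name_b: str = "mask") -> None:
    """Raise if two volumes do not share a grid (shape + affine)."""
    if a.data.shape != b.data.shape:
        raise ValueError(
            f"grid mismatch between {name_a} {a.data.shape} and "
            f"{name_b} {b.data.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-4):
        raise ValueError(f"affine mismatch between {name_a} and {name_b}")


def _zooms(img: nib.Nifti1Image) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return (float(z[0]), float(z[1]), float(z[2]))


def read_image(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64),
                       _zooms(img), np.asarray(img.affine))


def read_mask(path: str | Path, role: str = "generic") -> MaskVolume:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask file {path} is non-binary: values {vals[:10]}")
    return MaskVolume(arr.astype(bool), role, _zooms(img), np.asarray(img.affine))


def write_image(vol: ImageVolume, path: str | Path) -> None:
    # float64 on disk so that write -> read round-trips bit-identically
    nii = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    nii.header.set_zooms(vol.voxel_size_mm)
    nib.save(nii, str(path))


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    nii = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nii.header.set_zooms(mask.voxel_size_mm)
    nib.save(nii, str(path))
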