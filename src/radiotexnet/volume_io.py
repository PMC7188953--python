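"""Reading, validating and cropping 3D volumes and tumor masks.

Volumes carry Hounsfield-unit intensities on a regular grid with per-axis
spacing in millimetres.  All internal coordinates are 0-based voxel indices
in (x, y, z) order, fixed at read time.  Physical spacing is carried for
provenance but the texture features downstream are spacing-agnostic, so no
resampling is performed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


class VolumeError(ValueError):
    """Raised for unreadable, mis-shaped or otherwise invalid image input."""


@dataclass
class VoxelVolume:
    """A 3D intensity grid (HU) with voxel spacing and physical origin (mm)."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise VolumeError(
                f"volume must be 3D, got {self.intensities.ndim} dimensions"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise VolumeError("volume contains non-finite intensities")
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class ROIMask:
    """A binary tumor mask aligned with a :class:`VoxelVolume` grid."""

    flags: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags).astype(bool)
        if self.flags.ndim != 3:
            raise VolumeError(f"mask must be 3D, got {self.flags.ndim} dimensions")
        if not self.flags.any():
            raise VolumeError("empty mask: no foreground voxels")

    @property
    def voxel_count(self) -> int:
        return int(self.flags.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape


def read_volume(path: str | os.PathLike) -> VoxelVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD volume.

    Intensities are preserved exactly apart from the format's own affine
    intensity rule (NIfTI scl_slope/scl_inter), which is applied.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeError(f"no such file: {path}")
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        if len(img.shape) != 3:
            raise VolumeError(f"expected a 3D image, got shape {img.shape}")
        data = np.asarray(img.get_fdata(dtype=np.float64))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif low.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        if img.GetDimension() != 3:
            raise VolumeError(f"expected a 3D image, got {img.GetDimension()}D")
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
        zooms = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
    else:
        raise VolumeError(f"unsupported volume format: {path}")
    if not np.all(np.isfinite(data)):
        raise VolumeError(f"volume contains NaN/inf voxels: {path}")
    return VoxelVolume(data, spacing=zooms, origin=origin)


def read_mask(path: str | os.PathLike, reference: VoxelVolume) -> ROIMask:
    """Read a mask image; any nonzero voxel is foreground.

    The mask grid must match the reference volume's shape exactly.
    """
    vol = read_volume(path)
    if vol.shape != reference.shape:
        raise VolumeError(
            f"mask shape {vol.shape} does not match volume shape {reference.shape}"
        )
    return ROIMask(vol.intensities != 0)


def write_volume(volume: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with a diagonal spacing affine."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.intensities, affine), os.fspath(path))


def write_mask(mask: ROIMask, path: str | os.PathLike,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.flags.astype(np.uint8), affine), os.fspath(path))


def extract_roi(volume: VoxelVolume, mask: ROIMask, pad: int = 0
                ) -> tuple[VoxelVolume, ROIMask]:
    """Crop to the tight bounding box of the mask, expanded by ``pad`` voxels.

    The padding is clipped at the grid boundary; the mask is cropped with the
    same slices, so its voxel count is preserved exactly.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if volume.shape != mask.shape:
        raise VolumeError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    slices = []
    for axis in range(3):
        proj = mask.flags.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        lo = max(int(idx[0]) - pad, 0)
        hi = min(int(idx[-1]) + 1 + pad, mask.shape[axis])
        slices.append(slice(lo, hi))
    slices = tuple(slices)
    new_origin = tuple(
        o + s.start * sp
        for o, s, sp in zip(volume.origin, slices, volume.spacing)
    )
    sub = VoxelVolume(volume.intensities[slices].copy(), spacing=volume.spacing,
                      origin=new_origin)
    return sub, ROIMask(mask.flags[slices].copy())
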