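"""Binary voxel masks and segmentation I/O (NIfTI, MetaImage).

A :class:`VoxelMask` is an axis-aligned binary occupancy grid with an isotropic
voxel size; it is the operand of the Dice similarity coefficient and the entry
point for user-supplied prostate segmentations. Anisotropic input images are
resampled (nearest neighbour) to their finest spacing on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["VoxelMask", "read_mask", "write_mask"]


@dataclass
class VoxelMask:
    """Binary occupancy grid on an axis-aligned domain.

    Attributes
    ----------
    data : ndarray of bool, shape (nx, ny, nz)
        Occupancy; nonzero means foreground (prostate).
    origin : ndarray, shape (3,)
        World coordinates in mm of the centre of voxel (0, 0, 0).
    voxel_size : float
        Isotropic voxel edge length in mm.
    """

    data: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    voxel_size: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.voxel_size = float(self.voxel_size)
        if self.data.ndim != 3 or self.data.size == 0:
            raise InputError("mask must be a non-empty 3D grid")
        if self.voxel_size <= 0:
            raise InputError("voxel size must be positive")

    @property
    def shape(self):
        return self.data.shape

    def volume(self) -> float:
        """Foreground volume in mm^3."""
        return float(self.data.sum()) * self.voxel_size**3

    def count(self) -> int:
        return int(self.data.sum())

    def world_bounds(self):
        """(lo, hi) world coordinates of the grid's outer voxel faces."""
        lo = self.origin - 0.5 * self.voxel_size
        hi = self.origin + (np.array(self.shape) - 0.5) * self.voxel_size
        return lo, hi

    def voxel_centers(self):
        """World coordinates of foreground voxel centres, shape (k, 3)."""
        idx = np.argwhere(self.data)
        return self.origin + idx * self.voxel_size


def _resample_isotropic(data: np.ndarray, spacing, origin) -> VoxelMask:
    spacing = np.asarray(spacing, dtype=float)
    vs = float(spacing.min())
    if np.allclose(spacing, vs, rtol=1e-6):
        return VoxelMask(data, origin, vs)
    # nearest-neighbour resampling onto the finest spacing
    shape = np.maximum(1, np.round((np.array(data.shape) - 1) * spacing / vs).astype(int) + 1)
    grids = [np.round(np.arange(n) * vs / spacing[k]).astype(int).clip(0, data.shape[k] - 1)
             for k, n in enumerate(shape)]
    out = data[np.ix_(grids[0], grids[1], grids[2])]
    return VoxelMask(out, origin, vs)


def read_mask(path) -> VoxelMask:
    """Read a binary segmentation from NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    Any nonzero voxel is treated as foreground. Orientation matrices are ignored
    apart from the translation; the voxel lattice is taken as axis aligned.
    """
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asanyarray(img.dataobj) != 0
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
    elif path.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        # sitk arrays are (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0) != 0
        spacing = np.asarray(img.GetSpacing(), dtype=float)
        origin = np.asarray(img.GetOrigin(), dtype=float)
    else:
        raise InputError(f"unsupported mask format: {path}")
    if data.size == 0 or data.ndim != 3:
        raise InputError(f"mask in {path} is not a 3D image")
    return _resample_isotropic(data, spacing, origin)


def write_mask(path, mask: VoxelMask) -> None:
    """Write a mask to NIfTI or MetaImage, matching the extension of ``path``."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        affine[0, 0] = affine[1, 1] = affine[2, 2] = mask.voxel_size
        affine[:3, 3] = mask.origin
        nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), path)
    elif path.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(mask.data.astype(np.uint8).transpose(2, 1, 0))
        img.SetSpacing((mask.voxel_size,) * 3)
        img.SetOrigin(tuple(mask.origin))
        sitk.WriteImage(img, path)
    else:
        raise InputError(f"unsupported mask format: {path}")
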