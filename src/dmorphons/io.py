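"""Volume and displacement-field file I/O.

NIfTI (.nii/.nii.gz) via nibabel and MetaImage (.mhd/.mha) via SimpleITK,
preserving voxel spacing.  Arrays are kept in index order (axis 0 first);
SimpleITK's z-y-x memory layout is transposed on the way in/out so both
backends agree.  Displacement fields are written as multi-component NIfTI
with the vector dimension last, in voxel units.
"""
from __future__ import annotations

import os

import numpy as np
import nibabel as nib
import SimpleITK as sitk

from .fields import DisplacementField, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
]

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mhd", ".mha")


def _ext(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(p)[1]


def read_volume(path) -> Volume:
    ext = _ext(path)
    if ext in _NIFTI_EXT:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return Volume(data, spacing)
    if ext in _META_EXT:
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).T  # zyx -> xyz index order
        spacing = tuple(float(s) for s in img.GetSpacing())
        return Volume(np.asarray(data, dtype=float), spacing)
    raise ValueError(f"unsupported volume format: {path}")


def write_volume(v: Volume, path, dtype=None):
    ext = _ext(path)
    data = v.data if dtype is None else v.data.astype(dtype)
    if ext in _NIFTI_EXT:
        affine = np.diag(list(v.spacing) + [1.0] * (4 - v.ndim))
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return
    if ext in _META_EXT:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
        img.SetSpacing(tuple(v.spacing))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path}")


def read_field(path) -> DisplacementField:
    """Read a multi-component NIfTI displacement field (vector axis last)."""
    if _ext(path) not in _NIFTI_EXT:
        raise ValueError("displacement fields are stored as NIfTI")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    # squeeze a singleton time axis written by some tools: (X,Y,Z,1,nd)
    if data.ndim >= 4 and data.shape[-2] == 1 and data.ndim - 2 == data.shape[-1]:
        data = data[..., 0, :]
    return DisplacementField(data)


def write_field(D: DisplacementField, path, spacing=None):
    if _ext(path) not in _NIFTI_EXT:
        raise ValueError("displacement fields are stored as NIfTI")
    spacing = (1.0,) * D.ndim if spacing is None else tuple(spacing)
    affine = np.diag(list(spacing) + [1.0] * (4 - D.ndim))
    nib.save(nib.Nifti1Image(D.vectors, affine), str(path))
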