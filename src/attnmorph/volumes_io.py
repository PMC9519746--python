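"""Core grid types and NIfTI / CSV input-output.

Arrays are stored in on-disk index order; the three axes are referred to as
(D, H, W) throughout the package.  Displacement fields are in *voxel units*
with component order matching the grid axes; ``world_displacement`` converts
to millimetres when needed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelMap",
    "DeformationField",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_field",
    "write_field",
]

FIELD_DESCRIP = b"displacement field, voxel units, components (axis0,axis1,axis2)"


class FormatError(ValueError):
    """Raised when a file's layout does not match the expected grid format."""


@dataclass
class ImageVolume:
    """Scalar 3D intensity grid.

    Attributes
    ----------
    data : float32 array, shape (D, H, W)
    spacing : mm per axis, default 1 mm isotropic
    origin : world offset in mm
    orig_dtype : dtype of the file the volume was read from (round-trip info)
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    orig_dtype: np.dtype | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise FormatError(f"ImageVolume requires a 3D grid, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageVolume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class LabelMap:
    """Integer segmentation grid; label 0 is background."""

    labels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise FormatError(f"LabelMap requires a 3D grid, got {arr.ndim}D")
        if np.any(arr < 0):
            raise ValueError("labels must be non-negative")
        self.labels = arr.astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.labels.shape

    def label_set(self) -> tuple:
        return tuple(int(v) for v in np.unique(self.labels))


@dataclass
class DeformationField:
    """Dense displacement u(p) in voxel units, shape (3, D, H, W).

    The mapping is phi(p) = p + u(p); u == 0 is the identity registration.
    """

    u: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float32)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise FormatError(
                f"DeformationField requires shape (3, D, H, W), got {self.u.shape}"
            )
        if not np.all(np.isfinite(self.u)):
            raise ValueError("DeformationField contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.u.shape[1:]

    def world_displacement(self) -> np.ndarray:
        """Displacements in mm (voxel units scaled by spacing per axis)."""
        sp = np.asarray(self.spacing, dtype=np.float32).reshape(3, 1, 1, 1)
        return self.u * sp


# ---------------------------------------------------------------------------
# NIfTI IO
# ---------------------------------------------------------------------------

def _load(path):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return nib.load(str(path))


def _spacing_origin(img):
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return tuple(float(z) for z in zooms), origin


def read_volume(path, rescale: str = "auto") -> ImageVolume:
    """Read a scalar 3D NIfTI image.

    rescale : {"auto", "always", "never"}
        "always" min-max rescales intensities to [0, 1] (a constant image
        maps to all zeros).  "auto" (default) rescales only when values fall
        outside [0, 1], so that volumes written by :func:`write_volume`
        round-trip exactly.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D image, got {data.ndim}D: {path}")
    orig_dtype = data.dtype
    data = data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    do_rescale = rescale == "always" or (rescale == "auto" and (lo < 0.0 or hi > 1.0))
    if do_rescale:
        data = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)
    spacing, origin = _spacing_origin(img)
    return ImageVolume(data, spacing, origin, orig_dtype=orig_dtype)


def write_volume(vol: ImageVolume, path) -> None:
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D label map, got {data.ndim}D: {path}")
    spacing, origin = _spacing_origin(img)
    return LabelMap(np.rint(data).astype(np.int32), spacing, origin)


def write_labels(lab: LabelMap, path) -> None:
    aff = np.diag(list(lab.spacing) + [1.0])
    aff[:3, 3] = lab.origin
    img = nib.Nifti1Image(lab.labels.astype(np.int16), aff)
    img.header.set_zooms(lab.spacing)
    nib.save(img, str(path))


def read_field(path) -> DeformationField:
    """Read a 4D NIfTI vector field; last dimension must have size 3."""
    img = _load(path)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(
            f"expected a 4D field with vector dimension 3, got shape {data.shape}"
        )
    spacing, origin = _spacing_origin(img)
    return DeformationField(np.moveaxis(data, -1, 0), spacing, origin)


def write_field(fld: DeformationField, path) -> None:
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    aff = np.diag(list(fld.spacing) + [1.0])
    aff[:3, 3] = fld.origin
    data = np.moveaxis(fld.u.astype(np.float32), 0, -1)
    img = nib.Nifti1Image(data, aff)
    img.header["descrip"] = FIELD_DESCRIP
    nib.save(img, str(path))
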