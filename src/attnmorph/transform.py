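"""Spatial transformation m∘φ and Jacobian analysis of φ.

φ(p) = p + u(p) in voxel units.  ``warp`` resamples an image (trilinear,
differentiable) or a label map (nearest) at the displaced positions;
``jacobian_determinants`` evaluates det(∇φ) per voxel with central finite
differences (one-sided at the boundary), and ``nonpositive_jacobian_fraction``
summarizes folding as the percentage of voxels with det ≤ 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .volumes_io import DeformationField, ImageVolume, LabelMap

__all__ = [
    "WarpSettings",
    "warp",
    "warp_array",
    "jacobian_determinants",
    "nonpositive_jacobian_fraction",
]


@dataclass(frozen=True)
class WarpSettings:
    """interpolation: 'trilinear' or 'nearest'; boundary: 'border' or 'zeros'."""

    interpolation: str = "trilinear"
    boundary: str = "border"

    def __post_init__(self):
        if self.interpolation not in ("trilinear", "nearest"):
            raise ValueError(f"unknown interpolation: {self.interpolation}")
        if self.boundary not in ("border", "zeros"):
            raise ValueError(f"unknown boundary mode: {self.boundary}")


def _field_array(field):
    if isinstance(field, DeformationField):
        return field.u
    return field


def warp_array(m, u, settings: WarpSettings = WarpSettings()):
    """Array-level warp; accepts autodiff Tensors for the trilinear mode."""
    md, ud = ad.value_of(m), ad.value_of(u)
    if md.shape != ud.shape[1:]:
        raise ValueError(f"image {md.shape} and field {ud.shape[1:]} shapes differ")
    return ad.warp3(m, u, mode=settings.interpolation, boundary=settings.boundary)


def warp(m, field, settings: WarpSettings | None = None):
    """Warp an ImageVolume or LabelMap by a deformation field.

    Label maps are always resampled with nearest-neighbour interpolation so
    label values are preserved exactly.
    """
    u = _field_array(field)
    if isinstance(m, LabelMap):
        st = settings or WarpSettings(interpolation="nearest")
        if st.interpolation != "nearest":
            raise ValueError("label maps must be warped with nearest interpolation")
        out = warp_array(m.labels.astype(np.float32), u, st)
        return LabelMap(np.rint(out).astype(np.int32), m.spacing, m.origin)
    if isinstance(m, ImageVolume):
        st = settings or WarpSettings()
        out = warp_array(m.data, u, st)
        return ImageVolume(np.asarray(out, dtype=np.float32), m.spacing, m.origin)
    raise TypeError(f"cannot warp object of type {type(m)!r}")


def jacobian_determinants(field) -> np.ndarray:
    """det(∇φ) at every voxel, φ = Id + u.

    Central differences in the interior, one-sided stencils at the
    boundary (numpy.gradient convention).  Requires extent >= 3 per axis.
    """
    u = np.asarray(_field_array(field), dtype=np.float64)
    shape = u.shape[1:]
    if min(shape) < 3:
        raise ValueError(f"grid too small for Jacobian analysis: {shape}")
    J = np.empty((3, 3) + shape)
    for c in range(3):
        grads = np.gradient(u[c], axis=(0, 1, 2))
        for a in range(3):
            J[c, a] = grads[a] + (1.0 if a == c else 0.0)
    det = (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )
    return det


def nonpositive_jacobian_fraction(field, mask=None, strict: bool = False) -> float:
    """Percentage of (masked) voxels where det(∇φ) is non-positive.

    mask : LabelMap or boolean array or None
        None counts every voxel; a LabelMap counts its non-background
        (non-zero) voxels.  ``strict=True`` tests det < 0 instead of <= 0.
    """
    det = jacobian_determinants(field)
    if mask is None:
        sel = np.ones(det.shape, dtype=bool)
    elif isinstance(mask, LabelMap):
        sel = mask.labels > 0
    else:
        sel = np.asarray(mask).astype(bool)
    if sel.shape != det.shape:
        raise ValueError(f"mask shape {sel.shape} does not match grid {det.shape}")
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty mask")
    bad = det[sel] < 0 if strict else det[sel] <= 0
    return 100.0 * float(bad.sum()) / n
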