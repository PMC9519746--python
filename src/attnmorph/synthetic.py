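"""Synthetic phantoms and guaranteed-diffeomorphic random deformation fields.

The generator emulates the shape class of labeled brain-MRI volumes at
reduced scale: a large ellipsoidal "head" containing smaller offset
ellipsoidal structures with distinct mean intensities plus Gaussian noise,
and smooth random deformations built from a coarse control-point grid
upsampled by cubic interpolation.  Every accepted field is verified to have
strictly positive Jacobian determinants everywhere (no folding), so a
generated registration case comes with a known, topology-preserving ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .transform import WarpSettings, nonpositive_jacobian_fraction, warp
from .volumes_io import DeformationField, ImageVolume, LabelMap

__all__ = [
    "PhantomSpec",
    "FieldSpec",
    "generate_phantom",
    "generate_smooth_field",
    "make_registration_case",
]

MAX_RESCALE_RETRIES = 20


@dataclass(frozen=True)
class PhantomSpec:
    """shape: grid extents; n_structures: number of non-background labels;
    intensity_noise_sd: SD of additive Gaussian intensity noise; seed."""

    shape: tuple = (32, 32, 32)
    n_structures: int = 3
    intensity_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_structures < 1:
            raise ValueError("need at least one structure")
        if self.intensity_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class FieldSpec:
    """amplitude: max |u| in voxels; smoothness: control-point spacing in
    voxels (larger = smoother); seed."""

    shape: tuple = (32, 32, 32)
    amplitude: float = 4.0
    smoothness: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.indices(shape, dtype=np.float64)
    q = np.zeros(shape)
    for g, c, s in zip(grids, center, semiaxes):
        q += ((g - c) / s) ** 2
    return q <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Multi-label ellipsoid phantom: (ImageVolume, LabelMap), seeded.

    Label 1 is a large central ellipsoid; labels 2..k are smaller
    ellipsoids at seeded offsets inside it, overwriting the host region so
    labels stay mutually disjoint.  Intensities are one distinct level per
    label plus optional Gaussian noise, clipped to [0, 1]; with zero noise
    the image is piecewise constant.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    k = spec.n_structures
    labels = np.zeros(shape, dtype=np.int32)
    center = np.array(shape) / 2.0
    outer_axes = np.array(shape) * 0.38
    labels[_ellipsoid_mask(shape, center, outer_axes)] = 1
    inner_axes = outer_axes * (0.45 / max(1, k - 1) ** 0.35 if k > 1 else 0.45)
    for lab in range(2, k + 1):
        # seeded offset inside the host ellipsoid
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(0.25, 0.6)
        c = center + direction * radius * outer_axes
        axes = inner_axes * rng.uniform(0.7, 1.0)
        mask = _ellipsoid_mask(shape, c, np.maximum(axes, 1.2))
        labels[mask] = lab
    present = set(np.unique(labels))
    missing = [lab for lab in range(1, k + 1) if lab not in present]
    if missing:
        raise ValueError(
            f"infeasible packing: structures {missing} are empty on grid {shape}"
        )
    levels = np.linspace(0.35, 0.95, k)
    intensity = np.zeros(shape, dtype=np.float64)
    for lab in range(1, k + 1):
        intensity[labels == lab] = levels[lab - 1]
    if spec.intensity_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.intensity_noise_sd, shape)
    intensity = np.clip(intensity, 0.0, 1.0).astype(np.float32)
    return ImageVolume(intensity), LabelMap(labels)


def generate_smooth_field(spec: FieldSpec) -> DeformationField:
    """Smooth random field with guaranteed positive Jacobians.

    Control-point displacements (one per ``smoothness`` voxels) are drawn
    from a standard normal, cubically interpolated to the full grid and
    scaled so max |u| equals the requested amplitude.  If the folding check
    fails the field is shrunk by 0.8 and re-checked, up to a bounded number
    of retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    if spec.amplitude == 0:
        return DeformationField(np.zeros((3,) + shape, dtype=np.float32))
    n_ctrl = [max(int(np.ceil(s / spec.smoothness)) + 1, 2) for s in shape]
    ctrl = rng.standard_normal((3, *n_ctrl))
    coords = np.meshgrid(
        *[
            np.linspace(0.0, n - 1, s)
            for n, s in zip(n_ctrl, shape)
        ],
        indexing="ij",
    )
    u = np.stack(
        [
            ndimage.map_coordinates(ctrl[c], coords, order=3, mode="nearest")
            for c in range(3)
        ]
    )
    peak = np.abs(u).max()
    u = u * (spec.amplitude / peak)
    for _ in range(MAX_RESCALE_RETRIES):
        if nonpositive_jacobian_fraction(u) == 0.0:
            return DeformationField(u.astype(np.float32))
        u = u * 0.8
    raise ValueError(
        "could not generate a fold-free field; increase smoothness or "
        "reduce amplitude"
    )


def make_registration_case(phantom_spec: PhantomSpec, field_spec: FieldSpec):
    """Fixed/moving pair with known ground-truth deformation.

    Returns ``(fixed, moving, true_field, fixed_labels, moving_labels)``:
    the moving image and labels are the fixed phantom warped by the
    generated field (trilinear for intensities, nearest for labels).
    """
    if tuple(phantom_spec.shape) != tuple(field_spec.shape):
        raise ValueError("phantom and field shapes must agree")
    fixed, fixed_labels = generate_phantom(phantom_spec)
    true_field = generate_smooth_field(field_spec)
    moving = warp(fixed, true_field, WarpSettings("trilinear", "border"))
    moving_labels = warp(fixed_labels, true_field, WarpSettings("nearest", "border"))
    return fixed, moving, true_field, fixed_labels, moving_labels
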