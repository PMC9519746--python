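"""Unsupervised registration objective: local cross-correlation + bending penalty.

The similarity term is the windowed (local) squared normalized
cross-correlation: for each voxel p, local means over an n^3 window are
removed and the squared covariance is normalized by the two local variances;
the scalar CC is the *sum* of these per-voxel terms over the grid, so a
perfectly aligned non-degenerate pair scores |Ω|.  The training loss uses
the per-voxel mean, -CC/|Ω|, optionally plus alpha times the bending
penalty P: the mean over
interior voxels of the squared second spatial derivatives of the
transformation (pure terms once, mixed terms twice).  P vanishes exactly on
affine transformations, so the regularizer pushes the field towards local
affinity without penalizing global linear trends.

All functions are dual dispatch: numpy arrays in → numpy scalar out;
autodiff Tensors in → Tensor out (differentiable, used by the trainer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .transform import WarpSettings, warp_array
from .volumes_io import DeformationField, ImageVolume

__all__ = [
    "LossConfig",
    "local_cross_correlation",
    "similarity_loss",
    "bending_penalty",
    "gradient_penalty",
    "total_loss",
]

BENDING_MARGIN = 2  # boundary voxels excluded from the penalty integral


@dataclass(frozen=True)
class LossConfig:
    """window_n: odd edge length of the n^3 CC window; alpha: bending weight;
    eps: stabilizer added to both CC denominator factors."""

    window_n: int = 9
    alpha: float = 0.05
    eps: float = 1e-5

    def __post_init__(self):
        if self.window_n % 2 != 1 or self.window_n < 1:
            raise ValueError("window_n must be odd and positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


def _as_image_array(x):
    if isinstance(x, ImageVolume):
        return x.data
    return x


def _as_field(x):
    if isinstance(x, DeformationField):
        return x.u
    return x


def local_cross_correlation(f, w, cfg: LossConfig = LossConfig()):
    """Windowed squared-normalized cross-correlation, summed over the grid.

    Each local term lies in [0, 1]; the total lies in [0, |Ω|] and reaches
    |Ω| when ``w`` equals ``f`` (up to eps) wherever local variance is
    non-degenerate.  Invariant to affine intensity rescaling of either
    image.
    """
    f = _as_image_array(f)
    w = _as_image_array(w)
    n = cfg.window_n
    fv, wv = ad.value_of(f), ad.value_of(w)
    if fv.shape != wv.shape:
        raise ValueError(f"shapes differ: {fv.shape} vs {wv.shape}")
    if min(fv.shape) < n:
        raise ValueError(f"window {n} larger than volume {fv.shape}")
    if not (ad.is_tensor(f) or ad.is_tensor(w)):
        f = np.asarray(fv, dtype=np.float64)
        w = np.asarray(wv, dtype=np.float64)
    # local statistics over the intersection of each window with the grid:
    # the per-window sample count shrinks near the boundary instead of
    # padding in artificial zeros (which would fake boundary correlation)
    inv_n = 1.0 / ad.boxsum(np.ones(fv.shape), n)
    sf = ad.boxsum(f, n)
    sw = ad.boxsum(w, n)
    sff = ad.boxsum(ad.mul(f, f), n)
    sww = ad.boxsum(ad.mul(w, w), n)
    sfw = ad.boxsum(ad.mul(f, w), n)
    cross = ad.add(sfw, ad.mul(ad.mul(sf, sw), -inv_n))
    var_f = ad.add(sff, ad.mul(ad.mul(sf, sf), -inv_n))
    var_w = ad.add(sww, ad.mul(ad.mul(sw, sw), -inv_n))
    num = ad.mul(cross, cross)
    den = ad.mul(ad.add(var_f, cfg.eps), ad.add(var_w, cfg.eps))
    return ad.sum_all(ad.div(num, den))


def similarity_loss(f, m, field, cfg: LossConfig = LossConfig()):
    """-CC(f, m∘φ)/|Ω|: lower is better alignment; -1 at a perfect match.

    The per-voxel normalization puts the similarity term on the same scale
    as the (per-voxel) bending penalty, so the alpha weight is meaningful
    independent of grid size.  Differentiable w.r.t. the field.
    """
    f = _as_image_array(f)
    m = _as_image_array(m)
    u = _as_field(field)
    warped = warp_array(m, u, WarpSettings("trilinear", "border"))
    n_vox = int(np.prod(ad.value_of(f).shape))
    return ad.mul(local_cross_correlation(f, warped, cfg), -1.0 / n_vox)


def _second_derivative_terms(u_c):
    """Squared-second-derivative energy of one displacement component.

    Evaluated on the interior (BENDING_MARGIN voxels stripped per face):
    pure second derivatives by the compact [1, -2, 1] stencil, mixed
    partials by nested central first differences.
    """
    m = BENDING_MARGIN

    def core(d0=0, d1=0, d2=0):
        shp = ad.value_of(u_c).shape
        return u_c[
            m + d0 : shp[0] - m + d0,
            m + d1 : shp[1] - m + d1,
            m + d2 : shp[2] - m + d2,
        ]

    c = core()
    acc = None
    offs = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for o in offs:  # pure terms
        plus = core(*o)
        minus = core(*(-v for v in o))
        d2 = ad.add(ad.add(plus, minus), ad.mul(c, -2.0))
        term = ad.mul(d2, d2)
        acc = term if acc is None else ad.add(acc, term)
    for i in range(3):  # mixed terms, counted twice
        for j in range(i + 1, 3):
            oi, oj = offs[i], offs[j]
            pp = core(*(a + b for a, b in zip(oi, oj)))
            pm = core(*(a - b for a, b in zip(oi, oj)))
            mp = core(*(b - a for a, b in zip(oi, oj)))
            mm = core(*(-a - b for a, b in zip(oi, oj)))
            dij = ad.mul(
                ad.add(ad.add(pp, mm), ad.mul(ad.add(pm, mp), -1.0)), 0.25
            )
            acc = ad.add(acc, ad.mul(ad.mul(dij, dij), 2.0))
    return acc


def bending_penalty(field):
    """Bending energy P of the transformation, discretized as a mean.

    P = (1/V) Σ_p Σ_c [T_xx² + T_yy² + T_zz² + 2T_xy² + 2T_xz² + 2T_yz²]
    where T = φ = Id + u per component c; since Id has vanishing second
    derivatives the penalty is evaluated on u directly.  V is the number of
    interior voxels.  P >= 0 and P = 0 exactly on affine fields.
    """
    u = _as_field(field)
    shape = ad.value_of(u).shape
    if min(shape[1:]) < 2 * BENDING_MARGIN + 1:
        raise ValueError(
            f"grid {shape[1:]} too small for the bending stencil "
            f"(needs >= {2 * BENDING_MARGIN + 1} per axis)"
        )
    if not ad.is_tensor(u):
        u = np.asarray(ad.value_of(u), dtype=np.float64)
    acc = None
    for c in range(3):
        t = _second_derivative_terms(u[c])
        acc = t if acc is None else ad.add(acc, t)
    v = int(np.prod(ad.value_of(acc).shape))
    return ad.mul(ad.sum_all(acc), 1.0 / v)


def gradient_penalty(field):
    """First-order (diffusion) regularizer: mean squared forward difference
    of u.  Provided as an ablation alternative to the bending penalty."""
    u = _as_field(field)
    if not ad.is_tensor(u):
        u = np.asarray(ad.value_of(u), dtype=np.float64)
    shape = ad.value_of(u).shape
    acc, count = None, 0
    for axis in range(1, 4):
        n = shape[axis]
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_hi[axis] = slice(1, n)
        sl_lo[axis] = slice(0, n - 1)
        d = ad.add(u[tuple(sl_hi)], ad.mul(u[tuple(sl_lo)], -1.0))
        term = ad.sum_all(ad.mul(d, d))
        acc = term if acc is None else ad.add(acc, term)
        count += int(np.prod(ad.value_of(d).shape))
    return ad.mul(acc, 1.0 / count)


def total_loss(f, m, field, cfg: LossConfig = LossConfig()):
    """L = -CC(f, m∘φ)/|Ω| + alpha * P(φ).

    Returns ``(total, similarity, smooth)`` so the decomposition can be
    logged; total == similarity + smooth exactly.
    """
    sim = similarity_loss(f, m, field, cfg)
    if cfg.alpha > 0:
        smooth = ad.mul(bending_penalty(field), cfg.alpha)
        total = ad.add(sim, smooth)
    else:
        smooth = 0.0
        total = sim
    return total, sim, smooth
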