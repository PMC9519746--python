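"""Coordinate attention and gated spatial attention for 3D feature maps.

Coordinate attention compresses a (C, D, H, W) feature map with three 1D
global poolings (one per spatial axis), passes the concatenated descriptors
through a shared reduced-width 1x1 transform, and emits one sigmoid gate per
axis; the block output is the input scaled by the outer product of the three
directional gates.  This keeps channel attention while retaining positional
information along every axis — the natural 3D extension of the usual 2D
two-axis formulation, with a third pooled direction and a three-factor gate
product.

The spatial attention gate fuses an encoder skip feature ``x_l`` with a
decoder gating signal ``g`` through additive 1x1x1 projections, a rectifier,
and a single-channel sigmoid head, producing per-voxel coefficients
alpha in (0, 1) that rescale the skip features: irrelevant regions are
suppressed, salient ones pass through.

All functions accept plain numpy arrays (returning arrays) or autodiff
Tensors (returning Tensors wired into the training graph).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

__all__ = [
    "CoordinateAttentionParams",
    "SpatialAttentionParams",
    "squeeze_pool",
    "directional_pool",
    "coordinate_attention",
    "spatial_attention_gate",
    "reduced_channels",
]


def reduced_channels(c: int, r: int) -> int:
    """Intermediate width of the coordinate-attention bottleneck."""
    return max(c // r, 4)


@dataclass
class CoordinateAttentionParams:
    """Weights of a coordinate attention block for C input channels.

    w1/b1: shared (C_r, C) transform applied to the concatenated directional
    descriptors; wd/wh/ww (+ biases): per-direction (C, C_r) gate transforms,
    one for each spatial axis.  r is the channel reduction ratio.
    """

    r: int
    w1: object
    b1: object
    wd: object
    bd: object
    wh: object
    bh: object
    ww: object
    bw: object

    @classmethod
    def init(cls, c: int, r: int, rng: np.random.Generator) -> "CoordinateAttentionParams":
        cr = reduced_channels(c, r)
        s1 = np.sqrt(2.0 / c)
        s2 = np.sqrt(1.0 / cr)
        return cls(
            r=r,
            w1=rng.normal(0, s1, (cr, c)).astype(np.float32),
            b1=np.zeros(cr, dtype=np.float32),
            wd=rng.normal(0, s2, (c, cr)).astype(np.float32),
            bd=np.zeros(c, dtype=np.float32),
            wh=rng.normal(0, s2, (c, cr)).astype(np.float32),
            bh=np.zeros(c, dtype=np.float32),
            ww=rng.normal(0, s2, (c, cr)).astype(np.float32),
            bw=np.zeros(c, dtype=np.float32),
        )


@dataclass
class SpatialAttentionParams:
    """Weights of an additive spatial attention gate.

    wx projects the skip features (C_x -> F_int), wg the gating signal
    (C_g -> F_int, with bias bg); psi (+ bias bpsi) collapses the fused map
    to a single attention-logit channel.
    """

    wx: object
    wg: object
    bg: object
    psi: object
    bpsi: object

    @classmethod
    def init(cls, cx: int, cg: int, f_int: int,
             rng: np.random.Generator) -> "SpatialAttentionParams":
        return cls(
            wx=rng.normal(0, np.sqrt(2.0 / cx), (f_int, cx)).astype(np.float32),
            wg=rng.normal(0, np.sqrt(2.0 / cg), (f_int, cg)).astype(np.float32),
            bg=np.zeros(f_int, dtype=np.float32),
            psi=rng.normal(0, np.sqrt(1.0 / f_int), (1, f_int)).astype(np.float32),
            bpsi=np.zeros(1, dtype=np.float32),
        )


# ---------------------------------------------------------------------------
# pooling primitives
# ---------------------------------------------------------------------------

def _check_feature_map(x) -> None:
    shape = ad.value_of(x).shape
    if len(shape) != 4:
        raise ValueError(f"feature map must be (C, D, H, W), got shape {shape}")
    if any(s == 0 for s in shape):
        raise ValueError("feature map has empty spatial extent")


def squeeze_pool(x):
    """Global average pool: per-channel mean over all spatial positions."""
    _check_feature_map(x)
    return ad.mean_axes(x, (1, 2, 3))


def directional_pool(x):
    """Three 1D global poolings of a (C, D, H, W) map.

    Returns (z_d, z_h, z_w) with shapes (C, D), (C, H), (C, W): for each
    position along one axis, the mean of the map over the other two axes.
    """
    _check_feature_map(x)
    z_d = ad.mean_axes(x, (2, 3))
    z_h = ad.mean_axes(x, (1, 3))
    z_w = ad.mean_axes(x, (1, 2))
    return z_d, z_h, z_w


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

def coordinate_attention(x, params: CoordinateAttentionParams, saturate: bool = False):
    """Apply a coordinate attention block; shape (C, D, H, W) is preserved.

    With ``saturate=True`` every gate is forced to 1 and the block is the
    identity — the ablation/diagnostic mode used to check equivalence with
    a plain (attention-free) network.
    """
    _check_feature_map(x)
    if saturate:
        return x
    c, d, h, w = ad.value_of(x).shape
    if ad.value_of(params.w1).shape[1] != c:
        raise ValueError(
            f"coordinate attention configured for {ad.value_of(params.w1).shape[1]} "
            f"channels, feature map has {c}"
        )
    z_d, z_h, z_w = directional_pool(x)
    cat = ad.concat([z_d, z_h, z_w], axis=1)  # (C, D+H+W)
    f = ad.relu(ad.channel_linear(cat, params.w1, params.b1))  # (C_r, D+H+W)
    f_d = f[:, :d]
    f_h = f[:, d : d + h]
    f_w = f[:, d + h :]
    g_d = ad.sigmoid(ad.channel_linear(f_d, params.wd, params.bd))  # (C, D)
    g_h = ad.sigmoid(ad.channel_linear(f_h, params.wh, params.bh))  # (C, H)
    g_w = ad.sigmoid(ad.channel_linear(f_w, params.ww, params.bw))  # (C, W)
    y = ad.mul(x, ad.reshape(g_d, (c, d, 1, 1)))
    y = ad.mul(y, ad.reshape(g_h, (c, 1, h, 1)))
    y = ad.mul(y, ad.reshape(g_w, (c, 1, 1, w)))
    return y


def _resample_gating(g, target_spatial):
    """Nearest-neighbour resample of a coarser gating signal onto the skip grid."""
    gd = ad.value_of(g)
    if gd.shape[1:] == tuple(target_spatial):
        return g
    if ad.is_tensor(g):
        # only exact x2 upsampling is supported inside training graphs
        up = g
        while ad.value_of(up).shape[1] < target_spatial[0]:
            up = ad.upsample2(up)
        if ad.value_of(up).shape[1:] != tuple(target_spatial):
            raise ValueError(
                f"cannot resample gating signal {gd.shape[1:]} to {target_spatial}"
            )
        return up
    if any(t % s for t, s in zip(target_spatial, gd.shape[1:])):
        raise ValueError(
            f"cannot resample gating signal {gd.shape[1:]} to {target_spatial}: "
            "spatial extents must divide evenly"
        )
    out = gd
    for axis, (t, s) in enumerate(zip(target_spatial, gd.shape[1:])):
        out = out.repeat(t // s, axis=axis + 1)
    return out


def spatial_attention_gate(x_l, g, params: SpatialAttentionParams,
                           saturate: bool = False):
    """Additive attention gate on a skip connection.

    Returns ``(alpha, gated)``: a single-channel coefficient grid with
    values in (0, 1) and the skip features scaled by it.  ``g`` may be at a
    coarser resolution; it is nearest-neighbour upsampled onto the grid of
    ``x_l`` first.  With ``saturate=True``, alpha is 1 everywhere.
    """
    _check_feature_map(x_l)
    _check_feature_map(g)
    spatial = ad.value_of(x_l).shape[1:]
    if saturate:
        one = np.ones((1,) + spatial, dtype=np.float32)
        return one, x_l
    g = _resample_gating(g, spatial)
    if ad.value_of(params.wx).shape[1] != ad.value_of(x_l).shape[0]:
        raise ValueError("spatial gate wx channel count does not match x_l")
    if ad.value_of(params.wg).shape[1] != ad.value_of(g).shape[0]:
        raise ValueError("spatial gate wg channel count does not match g")
    fused = ad.relu(
        ad.add(
            ad.channel_linear(x_l, params.wx, None),
            ad.channel_linear(g, params.wg, params.bg),
        )
    )
    q = ad.channel_linear(fused, params.psi, params.bpsi)  # (1, D, H, W)
    alpha = ad.sigmoid(q)
    gated = ad.mul(x_l, alpha)
    return alpha, gated
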