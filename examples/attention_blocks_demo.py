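"""Show what the two attention blocks do to a feature map.

Coordinate attention pools a (C, D, H, W) map along each spatial axis,
derives one sigmoid gate per axis, and rescales the map by the gate
product — so the output is always elementwise bounded by the input.  The
spatial gate fuses the map with a gating signal into per-voxel
coefficients alpha in (0, 1).
"""

import numpy as np

from attnmorph.attention import (
    CoordinateAttentionParams,
    SpatialAttentionParams,
    coordinate_attention,
    directional_pool,
    spatial_attention_gate,
    squeeze_pool,
)

rng = np.random.default_rng(0)
x = rng.normal(size=(8, 6, 6, 6)).astype(np.float32)

z = squeeze_pool(x)
zd, zh, zw = directional_pool(x)
print(f"squeeze descriptor (one mean per channel): shape {z.shape}")
print(f"directional descriptors: {zd.shape}, {zh.shape}, {zw.shape}")

ca = CoordinateAttentionParams.init(c=8, r=2, rng=np.random.default_rng(1))
y = coordinate_attention(x, ca)
print(f"\ncoordinate attention preserves shape: {y.shape == x.shape}")
print(f"elementwise |output| <= |input|: {bool(np.all(np.abs(y) <= np.abs(x) + 1e-7))}")
print(f"mean attenuation factor: {np.abs(y).sum() / np.abs(x).sum():.3f} "
      f"(three sigmoid gates multiply)")

g = rng.normal(size=(4, 6, 6, 6)).astype(np.float32)  # decoder gating signal
sa = SpatialAttentionParams.init(cx=8, cg=4, f_int=4,
                                 rng=np.random.default_rng(2))
alpha, gated = spatial_attention_gate(x, g, sa)
print(f"\nspatial gate coefficients: shape {alpha.shape}, "
      f"range ({alpha.min():.3f}, {alpha.max():.3f}) — strictly inside (0, 1)")
print("voxels with alpha < 0.5 are suppressed; alpha > 0.5 are emphasized")
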