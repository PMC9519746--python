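"""Dual-attention encoder–decoder predicting a dense displacement field.

The field predictor g_theta(f, m) = u follows the classic unsupervised
registration U-Net: the fixed and moving volumes are concatenated into a
2-channel 3D input, the encoder halves the grid with 3x3x3 stride-2
convolutions + LeakyReLU, and the decoder alternates nearest-neighbour x2
upsampling, skip concatenation and 3x3x3 convolutions, ending in a
3-channel head emitting u at full resolution.  Each skip connection is
passed through a coordinate-attention block followed by a gated spatial
attention block (gating signal = the upsampled decoder feature at the same
resolution) before concatenation; both blocks can be disabled per level,
which degenerates the model to the plain U-Net.

The head is initialized near zero so an untrained network predicts a
near-identity registration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .attention import (
    CoordinateAttentionParams,
    SpatialAttentionParams,
    coordinate_attention,
    reduced_channels,
    spatial_attention_gate,
)
from .volumes_io import DeformationField, ImageVolume

__all__ = [
    "NetworkConfig",
    "NetworkParams",
    "build_network",
    "forward_field",
    "predict_field",
    "save_checkpoint",
    "load_checkpoint",
]

HEAD_INIT_STD = 1e-5  # near-identity start


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    encoder_channels: output channels of the stride-2 encoder convolutions.
    decoder_channels: consumed as [bottleneck conv] + [one conv per skip
    level, deepest first] + [full-resolution convolutions after the input
    concat].  attention_enabled: one flag per skip level (deepest skip
    first) or a single bool applied to all levels.
    """

    encoder_channels: tuple = (16, 32, 32, 32)
    decoder_channels: tuple = (32, 32, 32, 32, 32, 16, 16)
    leaky_slope: float = 0.2
    attention_enabled: tuple | bool = True
    reduction_ratio: int = 8
    in_channels: int = 2

    @property
    def depth(self) -> int:
        return len(self.encoder_channels)

    def attention_flags(self) -> tuple:
        n_skips = self.depth - 1
        if isinstance(self.attention_enabled, bool):
            return (self.attention_enabled,) * n_skips
        flags = tuple(bool(b) for b in self.attention_enabled)
        if len(flags) != n_skips:
            raise ValueError(
                f"attention_enabled needs {n_skips} flags, got {len(flags)}"
            )
        return flags

    def validate(self):
        if self.depth < 2:
            raise ValueError("need at least 2 encoder levels")
        if len(self.decoder_channels) < self.depth:
            raise ValueError("decoder_channels shorter than encoder depth")
        if not (0.0 < self.leaky_slope < 1.0):
            raise ValueError("leaky_slope must be in (0, 1)")
        self.attention_flags()

    def to_dict(self) -> dict:
        return {
            "encoder_channels": list(self.encoder_channels),
            "decoder_channels": list(self.decoder_channels),
            "leaky_slope": self.leaky_slope,
            "attention_enabled": (
                self.attention_enabled
                if isinstance(self.attention_enabled, bool)
                else list(self.attention_enabled)
            ),
            "reduction_ratio": self.reduction_ratio,
            "in_channels": self.in_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("encoder_channels", "decoder_channels"):
            d[key] = tuple(d[key])
        if not isinstance(d["attention_enabled"], bool):
            d["attention_enabled"] = tuple(d["attention_enabled"])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class NetworkParams:
    """All learnable weights, addressable by layer name, in stable order."""

    config: NetworkConfig
    tensors: dict  # name -> ad.Tensor, insertion order is enumeration order
    step: int = 0

    def parameters(self):
        return list(self.tensors.values())

    def state_arrays(self) -> dict:
        return {name: t.data for name, t in self.tensors.items()}

    def attention_params(self, level: int):
        """(CoordinateAttentionParams, SpatialAttentionParams) views for a skip level."""
        t = self.tensors
        p = f"att{level}"
        ca = CoordinateAttentionParams(
            r=self.config.reduction_ratio,
            w1=t[f"{p}.ca.w1"], b1=t[f"{p}.ca.b1"],
            wd=t[f"{p}.ca.wd"], bd=t[f"{p}.ca.bd"],
            wh=t[f"{p}.ca.wh"], bh=t[f"{p}.ca.bh"],
            ww=t[f"{p}.ca.ww"], bw=t[f"{p}.ca.bw"],
        )
        sa = SpatialAttentionParams(
            wx=t[f"{p}.sa.wx"], wg=t[f"{p}.sa.wg"], bg=t[f"{p}.sa.bg"],
            psi=t[f"{p}.sa.psi"], bpsi=t[f"{p}.sa.bpsi"],
        )
        return ca, sa


def _conv_init(rng, cout, cin, std=None):
    if std is None:
        std = np.sqrt(2.0 / (cin * 27))
    w = rng.normal(0.0, std, (cout, cin, 3, 3, 3)).astype(np.float32)
    b = np.zeros(cout, dtype=np.float32)
    return w, b


def _decoder_plan(config: NetworkConfig):
    """Input/output channels of every decoder convolution.

    Returns (skip_convs, full_convs, head_in): skip_convs[i] handles the
    concatenation with skip level depth-2-i; full_convs run at full
    resolution after concatenating the raw 2-channel input.
    """
    enc = config.encoder_channels
    dec = config.decoder_channels
    depth = config.depth
    plan = []
    cur = enc[-1]
    plan.append(("dec0", cur, dec[0]))  # bottleneck conv
    cur = dec[0]
    for i in range(1, depth):
        skip_ch = enc[depth - 1 - i]
        plan.append((f"dec{i}", cur + skip_ch, dec[i]))
        cur = dec[i]
    full = []
    cin = cur + config.in_channels
    for j, ch in enumerate(dec[depth:]):
        full.append((f"dec{depth + j}", cin, ch))
        cin = ch
    return plan, full, cin


def build_network(config: NetworkConfig, seed: int) -> NetworkParams:
    """Initialize all parameters reproducibly from ``seed``.

    The final head uses a tiny-variance normal so the initial predicted
    field is near-identity.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    tensors: dict = {}

    def add(name, arr):
        tensors[name] = ad.Tensor(arr, requires_grad=True)

    cin = config.in_channels
    for i, cout in enumerate(config.encoder_channels):
        w, b = _conv_init(rng, cout, cin)
        add(f"enc{i}.w", w)
        add(f"enc{i}.b", b)
        cin = cout

    skip_convs, full_convs, head_in = _decoder_plan(config)
    for name, ci, co in skip_convs + full_convs:
        w, b = _conv_init(rng, co, ci)
        add(f"{name}.w", w)
        add(f"{name}.b", b)

    w, b = _conv_init(rng, 3, head_in, std=HEAD_INIT_STD)
    add("head.w", w)
    add("head.b", b)

    flags = config.attention_flags()
    gating_ch = {  # decoder channels feeding each skip level's gate
        lvl: config.decoder_channels[lvl - 1] for lvl in range(1, config.depth)
    }
    for i in range(1, config.depth):
        # skip level i consumes encoder feature depth-1-i
        if not flags[i - 1]:
            continue
        c = config.encoder_channels[config.depth - 1 - i]
        ca = CoordinateAttentionParams.init(c, config.reduction_ratio, rng)
        p = f"att{i}"
        add(f"{p}.ca.w1", ca.w1); add(f"{p}.ca.b1", ca.b1)
        add(f"{p}.ca.wd", ca.wd); add(f"{p}.ca.bd", ca.bd)
        add(f"{p}.ca.wh", ca.wh); add(f"{p}.ca.bh", ca.bh)
        add(f"{p}.ca.ww", ca.ww); add(f"{p}.ca.bw", ca.bw)
        f_int = max(c // 2, 4)
        sa = SpatialAttentionParams.init(c, gating_ch[i], f_int, rng)
        add(f"{p}.sa.wx", sa.wx); add(f"{p}.sa.wg", sa.wg); add(f"{p}.sa.bg", sa.bg)
        add(f"{p}.sa.psi", sa.psi); add(f"{p}.sa.bpsi", sa.bpsi)

    return NetworkParams(config=config, tensors=tensors)


def _check_divisible(shape, depth):
    for s in shape:
        if s % (2 ** depth) != 0:
            raise ValueError(
                f"input shape {tuple(shape)} not divisible by 2^{depth}"
            )


def forward_field(params: NetworkParams, f_arr, m_arr, saturate_attention: bool = False):
    """Forward pass on raw arrays; returns the (3, D, H, W) field.

    Returns an autodiff Tensor when parameters require gradients (always,
    for freshly built networks), suitable for loss backpropagation.  With
    ``saturate_attention=True`` every attention gate is forced fully open,
    which reproduces the plain U-Net computation exactly.
    """
    cfg = params.config
    f_arr = ad.value_of(f_arr)
    m_arr = ad.value_of(m_arr)
    if f_arr.shape != m_arr.shape:
        raise ValueError(f"fixed {f_arr.shape} and moving {m_arr.shape} differ")
    _check_divisible(f_arr.shape, cfg.depth)
    t = params.tensors
    slope = cfg.leaky_slope
    x = np.stack([f_arr, m_arr]).astype(np.float32)

    feats = []
    h = x
    for i in range(cfg.depth):
        h = ad.leaky_relu(
            ad.conv3d(h, t[f"enc{i}.w"], t[f"enc{i}.b"], stride=2), slope
        )
        feats.append(h)

    flags = cfg.attention_flags()
    d = ad.leaky_relu(ad.conv3d(feats[-1], t["dec0.w"], t["dec0.b"]), slope)
    for i in range(1, cfg.depth):
        d = ad.upsample2(d)
        skip = feats[cfg.depth - 1 - i]
        if flags[i - 1]:
            ca, sa = params.attention_params(i)
            skip = coordinate_attention(skip, ca, saturate=saturate_attention)
            _, skip = spatial_attention_gate(skip, d, sa, saturate=saturate_attention)
        d = ad.concat([d, skip], axis=0)
        d = ad.leaky_relu(ad.conv3d(d, t[f"dec{i}.w"], t[f"dec{i}.b"]), slope)
    d = ad.upsample2(d)
    d = ad.concat([d, x], axis=0)
    j = cfg.depth
    while f"dec{j}.w" in t:
        d = ad.leaky_relu(ad.conv3d(d, t[f"dec{j}.w"], t[f"dec{j}.b"]), slope)
        j += 1
    u = ad.conv3d(d, t["head.w"], t["head.b"])
    return u


def predict_field(params: NetworkParams, f: ImageVolume, m: ImageVolume) -> DeformationField:
    """Register ``m`` towards ``f``: one deterministic forward pass."""
    if f.shape != m.shape:
        raise ValueError(f"fixed {f.shape} and moving {m.shape} shapes differ")
    u = forward_field(params, f.data, m.data)
    return DeformationField(ad.value_of(u), spacing=f.spacing, origin=f.origin)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(params: NetworkParams, path) -> None:
    """Single-archive checkpoint: config, step counter and all arrays."""
    meta = json.dumps(
        {"config": params.config.to_dict(), "step": params.step,
         "hash": params.config.hash()}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **params.state_arrays())


def load_checkpoint(path) -> NetworkParams:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = NetworkConfig.from_dict(meta["config"])
        if config.hash() != meta["hash"]:
            raise ValueError("checkpoint config hash mismatch")
        tensors = {
            name: ad.Tensor(data[name], requires_grad=True)
            for name in data.files
            if name != "__meta__"
        }
    ref = build_network(config, seed=0)
    ordered = {name: tensors[name] for name in ref.tensors}
    if set(ordered) != set(tensors):
        raise ValueError("checkpoint parameter names do not match architecture")
    return NetworkParams(config=config, tensors=ordered, step=int(meta["step"]))
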