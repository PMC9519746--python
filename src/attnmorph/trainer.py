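"""Unsupervised optimization loop binding network, transform and losses.

Training minimizes -CC(f, m∘φ)/|Ω| + alpha·P(φ) with Adam at batch size 1,
cycling deterministically through the supplied (fixed, moving) pairs.  The
defaults mirror the full-scale regime (learning rate 1e-4, 50,000
iterations); ``TrainConfig.desk()`` is the scaled-down preset used for
synthetic single-pair problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from . import autodiff as ad
from .losses import LossConfig, total_loss
from .network import (
    NetworkConfig,
    NetworkParams,
    build_network,
    forward_field,
    predict_field,
    save_checkpoint,
)
from .transform import WarpSettings, warp
from .volumes_io import ImageVolume

__all__ = ["TrainConfig", "TrainingDiverged", "train", "register"]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries step diagnostics."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    iterations: int = 50_000
    batch_size: int = 1
    loss: LossConfig = dfield(default_factory=LossConfig)
    seed: int = 0
    log_every: int = 10
    checkpoint_every: int = 0  # 0 disables periodic checkpoints
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")

    @classmethod
    def desk(cls, iterations: int = 400, **kw) -> "TrainConfig":
        """Desk-scale preset for small synthetic problems: a few hundred
        steps at a proportionally larger learning rate than the 50k-step
        full-scale schedule."""
        return cls(learning_rate=1e-3, iterations=iterations, **kw)


def _image_array(x):
    return x.data if isinstance(x, ImageVolume) else np.asarray(x, dtype=np.float32)


def train(pairs, cfg: TrainConfig, net_cfg: NetworkConfig | None = None,
          params: NetworkParams | None = None, progress=None):
    """Optimize network parameters on (fixed, moving) pairs.

    Returns ``(params, history)`` where history is a list of dicts with
    keys step/total/similarity/smooth (similarity + smooth == total).
    Deterministic given the seed and pair order.
    """
    pairs = [( _image_array(f), _image_array(m)) for f, m in pairs]
    if not pairs:
        raise ValueError("need at least one training pair")
    shape = pairs[0][0].shape
    for f, m in pairs:
        if f.shape != shape or m.shape != shape:
            raise ValueError("all training pairs must share one shape")
    if params is None:
        net_cfg = net_cfg or NetworkConfig()
        params = build_network(net_cfg, seed=cfg.seed)
    opt = ad.Adam(params.parameters(), lr=cfg.learning_rate)
    history = []
    for it in range(cfg.iterations):
        f_arr, m_arr = pairs[it % len(pairs)]
        u = forward_field(params, f_arr, m_arr)
        total, sim, smooth = total_loss(f_arr, m_arr, u, cfg.loss)
        tval = float(ad.value_of(total))
        sval = float(ad.value_of(sim))
        pval = float(ad.value_of(smooth)) if ad.is_tensor(smooth) else float(smooth)
        if not np.isfinite(tval):
            raise TrainingDiverged(
                f"non-finite loss at step {it}: total={tval}, "
                f"similarity={sval}, smooth={pval}"
            )
        history.append(
            {"step": it, "total": tval, "similarity": sval, "smooth": pval}
        )
        opt.zero_grad()
        total.backward()
        opt.step()
        params.step += 1
        if progress is not None and (it % cfg.log_every == 0 or it == cfg.iterations - 1):
            progress(history[-1])
        if (
            cfg.checkpoint_every
            and cfg.checkpoint_path
            and (it + 1) % cfg.checkpoint_every == 0
        ):
            save_checkpoint(params, cfg.checkpoint_path)
    return params, history


def register(params: NetworkParams, fixed: ImageVolume, moving: ImageVolume):
    """One forward pass + warp; no parameter mutation.

    Returns ``(field, warped_moving)``.
    """
    field = predict_field(params, fixed, moving)
    warped = warp(moving, field, WarpSettings("trilinear", "border"))
    return field, warped
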