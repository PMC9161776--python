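"""Segmentation losses: soft Dice, binary cross-entropy and their weighted sum.

The soft Dice loss operates on predicted probabilities directly (no
thresholding) with an additive smoothing constant that keeps it defined for
empty masks; the BCE term is averaged over pixels and stabilises training when
the foreground/background balance makes the Dice term noisy for small nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossConfig", "dice_loss", "bce_loss", "combined_loss", "combined_loss_grad"]

_CLAMP = 1e-7  # probabilities are clamped away from {0,1} before taking logs


@dataclass
class LossConfig:
    w1: float = 1.0  # weight of the Dice term
    w2: float = 0.1  # weight of the BCE term
    epsilon: float = 1.0  # Dice smoothing

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _check(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {g.shape}")
    return p, g


def dice_loss(p: np.ndarray, g: np.ndarray, epsilon: float = 1.0) -> float:
    """Soft Dice loss ``1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps)``."""
    p, g = _check(p, g)
    num = 2.0 * float((p * g).sum()) + epsilon
    den = float(p.sum()) + float(g.sum()) + epsilon
    return 1.0 - num / den


def bce_loss(p: np.ndarray, g: np.ndarray) -> float:
    """Mean binary cross-entropy over all pixels, with probability clamping."""
    p, g = _check(p, g)
    pc = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    return float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())


def combined_loss(p: np.ndarray, g: np.ndarray, config: LossConfig | None = None) -> float:
    """Weighted sum ``w1 * dice + w2 * bce``."""
    cfg = config or LossConfig()
    return cfg.w1 * dice_loss(p, g, cfg.epsilon) + cfg.w2 * bce_loss(p, g)


def combined_loss_grad(
    p: np.ndarray, g: np.ndarray, config: LossConfig | None = None
) -> tuple[float, np.ndarray]:
    """Batch loss and its gradient w.r.t. the probabilities.

    ``p`` and ``g`` are (B, H, W, 1); the Dice term is evaluated per patch and
    averaged over the batch, matching the per-image definition of the loss.
    Returns ``(loss, dL/dp)`` with the gradient in float32.
    """
    cfg = config or LossConfig()
    p = np.asarray(p)
    g = np.asarray(g, dtype=p.dtype)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {g.shape}")
    b = p.shape[0]
    n = p[0].size

    axes = tuple(range(1, p.ndim))
    inter = (p * g).sum(axis=axes, dtype=np.float64)
    psum = p.sum(axis=axes, dtype=np.float64)
    gsum = g.sum(axis=axes, dtype=np.float64)
    num = 2.0 * inter + cfg.epsilon
    den = psum + gsum + cfg.epsilon
    dice = 1.0 - num / den

    pc = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    bce = -(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean(
        axis=axes, dtype=np.float64
    )

    loss = float(cfg.w1 * dice.mean() + cfg.w2 * bce.mean())

    shape = (b,) + (1,) * (p.ndim - 1)
    scale = (num / den ** 2).reshape(shape)
    ddice = scale - g * (2.0 / den).reshape(shape)
    dbce = (-(g / pc) + (1.0 - g) / (1.0 - pc)) / n
    grad = (cfg.w1 * ddice + cfg.w2 * dbce) / b
    return loss, grad.astype(np.float32)
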