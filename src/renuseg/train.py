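"""Mini-batch training of the U-Net with Adam.

The loop shuffles the patch pool each epoch, averages the combined
Dice+BCE gradient over mini-batches of four patches and applies Adam
updates.  Everything is driven by a single integer seed, so a run is
bit-reproducible on one machine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .losses import LossConfig, combined_loss_grad
from .model import UNet

__all__ = ["TrainConfig", "Adam", "train"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 4
    epochs: int = 30
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0
    validation_fraction: float = 0.0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


class Adam:
    """Adam with the customary moment decays (0.9 / 0.999) and bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def _epoch_loss(model: UNet, x: np.ndarray, y: np.ndarray, batch: int,
                loss_cfg: LossConfig) -> float:
    """Mean combined loss over a dataset in evaluation mode."""
    total, count = 0.0, 0
    for s in range(0, len(x), batch):
        p = model.forward(x[s : s + batch], train=False)
        loss, _ = combined_loss_grad(p, y[s : s + batch], loss_cfg)
        total += loss * len(x[s : s + batch])
        count += len(x[s : s + batch])
    return total / count


def train(model: UNet, patch_set, config: TrainConfig,
          optimizer: Adam | None = None) -> list[dict]:
    """Train ``model`` on a :class:`~renuseg.sample_prep.PatchSet`.

    Returns the per-epoch history as a list of dicts with ``train_loss`` (the
    running mean of mini-batch losses) and, when ``validation_fraction`` > 0,
    ``val_loss``.  Passing an existing ``optimizer`` continues its moment
    state (used by warm-start retraining); otherwise a fresh Adam is created.
    """
    if len(patch_set) == 0:
        raise ValueError("cannot train on an empty patch pool")
    polarities = set(patch_set.polarity.tolist())
    if polarities != {"positive", "negative"}:
        raise ValueError(
            "training pool must contain both positive and negative patches; "
            f"found polarities {sorted(polarities)}"
        )

    x = np.ascontiguousarray(patch_set.patches, dtype=np.float32)
    y = np.ascontiguousarray(
        patch_set.targets.astype(np.float32)[..., None]
    )

    rng = np.random.default_rng(config.seed)
    n = len(x)
    n_val = int(round(config.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("validation split leaves no training patches")
    xv, yv = x[val_idx], y[val_idx]
    xt, yt = x[tr_idx], y[tr_idx]

    if optimizer is None:
        optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(xt))
        running, seen = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            xb, yb = xt[idx], yt[idx]
            p = model.forward(xb, train=True, rng=rng)
            loss, grad = combined_loss_grad(p, yb, config.loss)
            model.backward(grad)
            optimizer.step(model.gradients())
            running += loss * len(idx)
            seen += len(idx)
        rec = {"epoch": epoch, "train_loss": running / seen}
        if n_val:
            rec["val_loss"] = _epoch_loss(model, xv, yv, config.batch_size, config.loss)
        history.append(rec)
        log.debug("epoch %d: %s", epoch, rec)
    return history
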