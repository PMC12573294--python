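"""Seeded training loop with cosine-annealed SGD.

The learning rate follows the half-cosine schedule
lr(t) = lr_min + (lr_max - lr_min) * (1 + cos(pi * t / T_max)) / 2,
decaying from lr_max at t = 0 to lr_min at t = T_max; a fixed-rate
schedule is available for comparison runs. The optimiser is momentum SGD
(momentum 0.9, weight decay 5e-4 by default) minimising softmax
cross-entropy. Training augments each minibatch image; validation runs
un-augmented in eval mode each epoch, and the best-validation state is
retained as the checkpoint. Given one seed and a single-threaded BLAS,
runs are bit-reproducible.
"""

from __future__ import annotations

import copy
import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .backbone import ResNet, save_checkpoint
from .datapipe import AugmentConfig, augment
from .nn import Tensor


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    lr_max: float = 0.02
    lr_min: float = 1e-5
    schedule: str = "cosine"  # or "fixed" (constant lr_max)
    momentum: float = 0.9
    weight_decay: float = 5e-4
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr_min < self.lr_max:
            raise ValueError("need lr_min < lr_max")
        if self.schedule not in ("cosine", "fixed"):
            raise ValueError("schedule must be 'cosine' or 'fixed'")


@dataclass
class TrainHistory:
    """One row per completed epoch."""

    rows: list[dict] = field(default_factory=list)

    def append(self, **kv) -> None:
        self.rows.append(kv)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list[float]:
        return [r[name] for r in self.rows]

    def to_csv(self, path: str | Path) -> None:
        cols = ["epoch", "lr", "train_loss", "train_acc", "val_loss", "val_acc"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            writer.writerows(self.rows)


def cosine_lr(t: float, t_max: float, lr_max: float, lr_min: float) -> float:
    """Half-cosine decay from lr_max (t=0) to lr_min (t=t_max)."""
    if not 0 <= t <= t_max:
        raise ValueError(f"epoch index {t} outside [0, {t_max}]")
    return lr_min + (lr_max - lr_min) * (1 + math.cos(math.pi * t / t_max)) / 2


def channel_stats(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std of an (N, H, W, 3) stack, for normalisation.
    Computed on the training split (no published constants exist for this
    domain)."""
    mean = images.mean(axis=(0, 1, 2), dtype=np.float64)
    std = images.std(axis=(0, 1, 2), dtype=np.float64) + 1e-6
    return mean.astype(np.float32), std.astype(np.float32)


def normalize(images: np.ndarray, stats: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """(N, H, W, 3) in [0,1] -> normalised channel-first (N, 3, H, W)."""
    mean, std = stats
    out = (images.astype(np.float32) - mean) / std
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def _eval_pass(model: ResNet, x: np.ndarray, labels: np.ndarray,
               batch_size: int) -> tuple[float, float]:
    model.eval()
    losses, correct = [], 0
    with nn.no_grad():
        for lo in range(0, len(x), batch_size):
            xb = x[lo:lo + batch_size]
            yb = labels[lo:lo + batch_size]
            logits = model(Tensor(xb)).data
            z = logits - logits.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            losses.append(-logp[np.arange(len(yb)), yb].sum())
            correct += int((logits.argmax(axis=1) == yb).sum())
    model.train()
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(model: ResNet,
          train_images: np.ndarray, train_labels: np.ndarray,
          val_images: np.ndarray, val_labels: np.ndarray,
          cfg: TrainConfig = TrainConfig(),
          augment_cfg: AugmentConfig | None = None,
          checkpoint_path: str | Path | None = None,
          stats: tuple[np.ndarray, np.ndarray] | None = None,
          ) -> tuple[TrainHistory, dict]:
    """Fit `model`; returns (history, best-state info).

    Images arrive as (N, H, W, 3) floats in [0, 1]; normalisation stats are
    computed on the training split unless supplied. The best-validation
    epoch's weights are restored into `model` at the end and optionally
    written to `checkpoint_path`.
    """
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and val splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    if stats is None:
        stats = channel_stats(train_images)
    val_x = normalize(val_images, stats)

    opt = nn.SGD(model.parameters(), lr=cfg.lr_max,
                 momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best = {"val_acc": -1.0, "epoch": -1, "state": None}
    n = len(train_images)
    model.train()
    for epoch in range(cfg.epochs):
        lr = cfg.lr_max if cfg.schedule == "fixed" else \
            cosine_lr(epoch, cfg.epochs, cfg.lr_max, cfg.lr_min)
        opt.lr = lr
        perm = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            sel = perm[lo:lo + cfg.batch_size]
            raw = train_images[sel]
            if augment_cfg is not None:
                raw = np.stack([augment(im, augment_cfg, rng) for im in raw])
            xb = normalize(raw, stats)
            yb = train_labels[sel]
            logits = model(Tensor(xb))
            loss = nn.cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{lo // cfg.batch_size} (lr={lr:.2e}); aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(sel)
            ep_correct += int((logits.data.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _eval_pass(model, val_x, val_labels, cfg.batch_size)
        history.append(epoch=epoch, lr=lr,
                       train_loss=ep_loss / n, train_acc=ep_correct / n,
                       val_loss=val_loss, val_acc=val_acc)
        if val_acc > best["val_acc"]:
            best.update(val_acc=val_acc, epoch=epoch,
                        state=copy.deepcopy(model.state_dict()))
    model.load_state_dict(best["state"])
    meta = {"best_epoch": best["epoch"], "best_val_acc": best["val_acc"],
            "norm_mean": stats[0].tolist(), "norm_std": stats[1].tolist()}
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, epoch=best["epoch"],
                        seed=cfg.seed, extra={"train_meta": meta})
    return history, meta
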