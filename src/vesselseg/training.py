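"""Seeded SGD training loop with a step learning-rate schedule.

The reference optimization recipe is stochastic gradient descent starting
at lr 0.001, multiplied by 0.1 every 20 epochs, batch size 20, 100 epochs.
All of that is configurable so the same loop runs desk-scale experiments
(smaller images, fewer epochs, a momentum term) in minutes; the schedule
itself is exact:  lr(e) = lr_init · decay^⌊e / every⌋.

The L2 term of the objective is applied inside the loss (λ·W added to each
parameter gradient, (λ/2)·ΣW² to the reported cost) rather than as
optimizer weight decay; for plain SGD the two are identical.  Training is
deterministic given the config seed: it fixes weight init, batch order and
nothing else (the data pairs carry their own seeds).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import preprocessing
from .io_datasets import SamplePair
from .losses import (
    LossParams, PixelBatch, combined_cost, combined_cost_grad,
    dice_loss, hard_dice_coefficient,
)
from .metrics import confusion, sen_spe_acc
from .network import NetworkSpec, SegmentationModel
from ._nn import SGD, DTYPE

__all__ = [
    "TrainConfig",
    "TrainLogRecord",
    "TrainingDivergedError",
    "lr_at_epoch",
    "pairs_to_arrays",
    "train",
    "compare_losses",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; message carries epoch, batch and lr."""


@dataclass(frozen=True)
class TrainConfig:
    lr_init: float = 0.001
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 20
    batch_size: int = 20
    epochs: int = 100
    seed: int = 0
    momentum: float = 0.0
    use_clahe: bool = True
    checkpoint_every: int = 0  # 0 disables periodic checkpoints
    loss: LossParams = field(default_factory=LossParams)
    network: NetworkSpec = field(default_factory=NetworkSpec)

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ValueError("lr_init must be > 0")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must be in (0, 1]")
        if self.batch_size < 1 or self.epochs < 1 or self.lr_decay_every < 1:
            raise ValueError("batch_size, epochs and lr_decay_every must be >= 1")


@dataclass
class TrainLogRecord:
    epoch: int
    lr: float
    train_loss: float
    val_dice: float = float("nan")
    val_sen: float = float("nan")
    val_spe: float = float("nan")
    wall_notes: str = ""


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step schedule: lr_init · decay^⌊epoch / every⌋ (0-based epochs)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr_init * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


def pairs_to_arrays(
    pairs: list[SamplePair], cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess SamplePairs into network tensors (x: N×1×H×W, y: N×1×H×W).

    Green channel, optional CLAHE, then scale to [0, 1].  All images in a
    batch array must share one size divisible by 2^depth.
    """
    xs, ys = [], []
    for p in pairs:
        g = preprocessing.green_channel(p.image)
        if cfg.use_clahe:
            g = preprocessing.clahe(g)
        xs.append(g.astype(np.float64) / 255.0)
        ys.append(np.asarray(p.truth, dtype=np.float64))
    x = np.stack(xs)[:, None].astype(DTYPE)
    y = np.stack(ys)[:, None].astype(DTYPE)
    div = 2**cfg.network.depth
    if x.shape[2] % div or x.shape[3] % div:
        raise ValueError(
            f"training images {x.shape[2]}×{x.shape[3]} must be divisible by 2^depth={div}")
    return x, y


def _validate(
    model: SegmentationModel, xv: np.ndarray, yv: np.ndarray, batch: int
) -> tuple[float, float, float]:
    dices, cms = [], None
    for s in range(0, len(xv), batch):
        prob = model.forward(xv[s : s + batch], training=False)
        for i in range(prob.shape[0]):
            pred = (prob[i, 0] >= 0.5).astype(np.uint8)
            truth = yv[s + i, 0].astype(np.uint8)
            y, p = yv[s + i : s + i + 1, 0], prob[i : i + 1, 0]
            b = PixelBatch(y.astype(np.float64), np.clip(p.astype(np.float64), 0, 1))
            dices.append(1.0 - dice_loss(b))
            c = confusion(pred, truth)
            cms = c if cms is None else cms + c
    sen, spe, _ = sen_spe_acc(cms)
    return float(np.mean(dices)), sen, spe


def train(
    cfg: TrainConfig,
    train_pairs: list[SamplePair],
    val_pairs: list[SamplePair] | None = None,
) -> tuple[SegmentationModel, list[TrainLogRecord]]:
    """SGD on the combined cost; returns the best-by-validation-Dice model.

    Deterministic given ``cfg.seed``.  Validation (soft Dice, sensitivity,
    specificity at threshold 0.5) runs once per epoch when ``val_pairs`` is
    given; without it the best-model tracking falls back to train loss.
    Raises :class:`TrainingDivergedError` on a non-finite loss.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    x, y = pairs_to_arrays(train_pairs, cfg)
    xv = yv = None
    if val_pairs:
        xv, yv = pairs_to_arrays(val_pairs, cfg)

    model = SegmentationModel(cfg.network, seed=cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr_init, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed + 1)
    logs: list[TrainLogRecord] = []
    best_score, best_state = -np.inf, None
    n = len(x)
    lam = cfg.loss.lambda_l2

    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(n)
        epoch_losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            prob = model.forward(xb, training=True)
            batch = PixelBatch(
                yb[:, 0].astype(np.float64),
                np.clip(prob[:, 0].astype(np.float64), 0.0, 1.0),
            )
            loss = combined_cost(batch, cfg.loss, model.weight_norm_sq())
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {s // cfg.batch_size}, "
                    f"lr {opt.lr:g}")
            grad = combined_cost_grad(batch, cfg.loss).reshape(prob[:, 0].shape)
            opt.zero_grad()
            model.backward(grad[:, None])
            if lam:
                for p in model.parameters():
                    p.grad += DTYPE(lam) * p.value
            opt.step()
            epoch_losses.append(loss)

        rec = TrainLogRecord(epoch=epoch, lr=opt.lr, train_loss=float(np.mean(epoch_losses)))
        if xv is not None:
            rec.val_dice, rec.val_sen, rec.val_spe = _validate(model, xv, yv, cfg.batch_size)
            score = rec.val_dice
        else:
            score = -rec.train_loss
        if score > best_score:
            best_score = score
            best_state = ([p.value.copy() for p in model.parameters()],
                          _bn_state(model))
            rec.wall_notes = "best"
        logs.append(rec)

    if best_state is not None:
        for p, v in zip(model.parameters(), best_state[0]):
            p.value[...] = v
        _restore_bn(model, best_state[1])
    return model, logs


def _bn_state(model: SegmentationModel):
    from ._nn import BatchNorm2D

    return [(l.running_mean.copy(), l.running_var.copy())
            for l in model._all_layers() if isinstance(l, BatchNorm2D)]


def _restore_bn(model: SegmentationModel, state) -> None:
    from ._nn import BatchNorm2D

    bns = [l for l in model._all_layers() if isinstance(l, BatchNorm2D)]
    for l, (m, v) in zip(bns, state):
        l.running_mean[...] = m
        l.running_var[...] = v


def compare_losses(
    cfg: TrainConfig,
    train_pairs: list[SamplePair],
    val_pairs: list[SamplePair],
    seeds: tuple[int, ...] = (0,),
) -> pd.DataFrame:
    """Twin-model comparison: plain cross-entropy vs the cost-sensitive combined loss.

    For each seed, two models differing *only* in the loss are trained with
    identical init, batch order and budget; held-out sensitivity,
    specificity and hard Dice at threshold 0.5 are reported (two rows per
    seed).  The cost-sensitive loss exists to keep the optimizer from
    collapsing onto the background class, so its sensitivity should not fall
    below the plain arm's on imbalanced data.
    """
    arms = {
        "plain_ce": replace(cfg.loss, alpha=0.0, vessel_penalty=0.0),
        "cost_sensitive": cfg.loss,
    }
    rows = []
    for seed in seeds:
        for arm, loss in arms.items():
            c = replace(cfg, seed=seed, loss=loss)
            model, _ = train(c, train_pairs, val_pairs)
            xv, yv = pairs_to_arrays(val_pairs, c)
            prob = np.concatenate(
                [model.forward(xv[s : s + c.batch_size], training=False)
                 for s in range(0, len(xv), c.batch_size)])
            pred = (prob[:, 0] >= 0.5).astype(np.uint8)
            truth = yv[:, 0].astype(np.uint8)
            cm = confusion(pred, truth)
            sen, spe, acc = sen_spe_acc(cm)
            rows.append({
                "seed": seed, "arm": arm, "sen": sen, "spe": spe, "acc": acc,
                "dice": hard_dice_coefficient(pred, truth),
            })
    return pd.DataFrame(rows)
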