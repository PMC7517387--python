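"""Cost-sensitive segmentation losses.

Retinal fundus images are heavily imbalanced: roughly one pixel in ten is
vessel, the rest background.  A network trained with a plain per-pixel loss
tends to collapse onto the background class.  The loss algebra implemented
here counters that with two ingredients:

* a soft Dice loss, ``1 - 2|A∩B| / (|A| + |B|)``, computed on probabilities
  so it is differentiable, and
* a cost-sensitive cross-entropy in which a vessel pixel predicted on the
  wrong side of a threshold incurs an extra penalty (weight ``1 + κ·I(p ≤ t)``
  with κ = 6 and t = 0.5 by default); background pixels are never
  penalty-weighted.

The two are blended by a coefficient ``alpha`` and an L2 term on the network
weights may be added on top:

    J = α·L_dice + (1-α)·L_ce + (λ/2)·Σ W²

Dice is computed per image and averaged over the batch; cross-entropy is a
per-pixel mean per image, averaged over the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossParams",
    "PixelBatch",
    "dice_loss",
    "dice_loss_grad",
    "hard_dice_coefficient",
    "cost_sensitive_ce",
    "cost_sensitive_ce_grad",
    "combined_cost",
    "combined_cost_grad",
    "gradient_check",
    "NonDifferentiablePointWarning",
]

_EPS = 1e-7  # clamp for logs; keeps losses finite at saturated predictions


class NonDifferentiablePointWarning(UserWarning):
    """Emitted when a gradient check straddles the indicator kink at p = threshold."""


@dataclass(frozen=True)
class LossParams:
    """Hyperparameters of the combined cost.

    alpha             Dice / cross-entropy blending coefficient in [0, 1].
    lambda_l2         L2 regularization coefficient (λ); the regularizer added
                      to the cost is (λ/2)·Σ W².
    vessel_penalty    extra penalty κ applied to a vessel pixel whose predicted
                      probability falls at or below ``penalty_threshold``.
    penalty_mode      "add" gives weight 1 + κ·I (the literal cost-matrix
                      product); "replace" gives weight κ when the indicator
                      fires and 1 otherwise.
    dice_smooth       smoothing constant added to numerator and denominator of
                      the soft Dice ratio.
    """

    alpha: float = 0.5
    lambda_l2: float = 1e-4
    vessel_penalty: float = 6.0
    penalty_threshold: float = 0.5
    penalty_mode: str = "add"
    dice_smooth: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lambda_l2 < 0:
            raise ValueError("lambda_l2 must be >= 0")
        if self.vessel_penalty < 0:
            raise ValueError("vessel_penalty must be >= 0")
        if self.dice_smooth < 0:
            raise ValueError("dice_smooth must be >= 0")
        if self.penalty_mode not in ("add", "replace"):
            raise ValueError("penalty_mode must be 'add' or 'replace'")


@dataclass
class PixelBatch:
    """A batch of per-pixel labels and predictions.

    ``y`` holds binary ground truth, ``p`` predicted vessel probabilities in
    [0, 1].  Both are shaped ``(m, ...)`` where the leading axis indexes the
    m samples (images) of the batch; per-image reductions run over the
    remaining axes.  1-D inputs are treated as a single sample.
    """

    y: np.ndarray
    p: np.ndarray
    m: int = field(init=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.y.shape != self.p.shape:
            raise ValueError(f"shape mismatch: y {self.y.shape} vs p {self.p.shape}")
        if self.y.size == 0:
            raise ValueError("empty batch: loss undefined on zero pixels")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("ground truth must be binary")
        if self.p.min() < 0.0 or self.p.max() > 1.0:
            raise ValueError("predictions must lie in [0, 1]")
        if self.y.ndim == 1:
            self.y = self.y[None, :]
            self.p = self.p[None, :]
        self.m = self.y.shape[0]

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        return self.y.reshape(self.m, -1), self.p.reshape(self.m, -1)


def dice_loss(batch: PixelBatch, params: LossParams = LossParams()) -> float:
    """Soft Dice loss, per image, averaged over the batch.

    |A∩B| = Σ p·y, |A| = Σ p, |B| = Σ y, both numerator and denominator
    smoothed by ``params.dice_smooth``.  0 for a perfect prediction, 1 for
    disjoint supports (up to the smoothing term).
    """
    y, p = batch.flat()
    s = params.dice_smooth
    inter = (p * y).sum(axis=1)
    d = 1.0 - (2.0 * inter + s) / (p.sum(axis=1) + y.sum(axis=1) + s)
    return float(d.mean())


def dice_loss_grad(batch: PixelBatch, params: LossParams = LossParams()) -> np.ndarray:
    """∂(dice_loss)/∂p, same shape as ``batch.p``."""
    y, p = batch.flat()
    s = params.dice_smooth
    inter = (p * y).sum(axis=1, keepdims=True)
    denom = p.sum(axis=1, keepdims=True) + y.sum(axis=1, keepdims=True) + s
    num = 2.0 * inter + s
    g = -(2.0 * y * denom - num) / denom**2
    return (g / batch.m).reshape(batch.p.shape)


def hard_dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Set-based Dice coefficient 2|A∩B|/(|A|+|B|) on binary masks.

    Evaluation-time counterpart of the soft loss; returns 1.0 when both
    masks are empty (perfect agreement on "nothing to segment").
    """
    a = np.asarray(pred).astype(bool)
    b = np.asarray(truth).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def _vessel_weight(y: np.ndarray, p: np.ndarray, params: LossParams) -> np.ndarray:
    ind = (p <= params.penalty_threshold).astype(np.float64)
    if params.penalty_mode == "add":
        w = 1.0 + params.vessel_penalty * ind
    else:  # replace: weight κ when the indicator fires, 1 otherwise
        w = np.where(ind > 0, max(params.vessel_penalty, 0.0), 1.0)
    return np.where(y > 0, w, 1.0)


def cost_sensitive_ce(batch: PixelBatch, params: LossParams = LossParams()) -> float:
    """Cost-sensitive binary cross-entropy, mean over pixels per image.

    Per pixel: -[w·y·log p + (1-y)·log(1-p)] where w = 1 + κ·I(p ≤ t) for
    vessel pixels and 1 for background.  The cost matrix rows are
    (1, κ·I; 0, 1): misclassified vessels are up-weighted, background is not.
    """
    y, p = batch.flat()
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    w = _vessel_weight(y, p, params)
    loss = -(w * y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    return float(loss.mean(axis=1).mean())


def cost_sensitive_ce_grad(batch: PixelBatch, params: LossParams = LossParams()) -> np.ndarray:
    """∂(cost_sensitive_ce)/∂p, treating the indicator as piecewise constant."""
    y, p = batch.flat()
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    w = _vessel_weight(y, p, params)
    g = -(w * y / pc) + (1.0 - y) / (1.0 - pc)
    g /= y.shape[1] * batch.m
    return g.reshape(batch.p.shape)


def combined_cost(
    batch: PixelBatch,
    params: LossParams = LossParams(),
    weight_norm_sq: float = 0.0,
) -> float:
    """α·dice + (1-α)·cost-sensitive CE + (λ/2)·Σ W²."""
    if weight_norm_sq < 0:
        raise ValueError("weight_norm_sq must be >= 0")
    a = params.alpha
    j = a * dice_loss(batch, params) + (1.0 - a) * cost_sensitive_ce(batch, params)
    return float(j + 0.5 * params.lambda_l2 * weight_norm_sq)


def combined_cost_grad(batch: PixelBatch, params: LossParams = LossParams()) -> np.ndarray:
    """∂(combined_cost)/∂p (the L2 term does not depend on p)."""
    a = params.alpha
    return a * dice_loss_grad(batch, params) + (1.0 - a) * cost_sensitive_ce_grad(batch, params)


def gradient_check(
    lossfn,
    gradfn,
    batch: PixelBatch,
    params: LossParams = LossParams(),
    eps: float = 1e-6,
) -> float:
    """Max relative error between ``gradfn`` and central finite differences.

    Warns (and still reports the error) when any probed point straddles the
    indicator kink at ``penalty_threshold``, where the loss is not
    differentiable.
    """
    p = batch.p.ravel()
    t = params.penalty_threshold
    if np.any((np.abs(p - t) < eps) | (p < eps) | (p > 1 - eps)):
        warnings.warn(
            "gradient check probes a non-differentiable or boundary point "
            f"(p near {t}, 0 or 1); finite differences are unreliable there",
            NonDifferentiablePointWarning,
            stacklevel=2,
        )
    analytic = gradfn(batch, params).ravel()
    numeric = np.empty_like(analytic)
    shape = batch.p.shape
    for i in range(p.size):
        pp = p.copy()
        pp[i] = p[i] + eps
        hi = lossfn(PixelBatch(batch.y, pp.reshape(shape)), params)
        pp[i] = p[i] - eps
        lo = lossfn(PixelBatch(batch.y, pp.reshape(shape)), params)
        numeric[i] = (hi - lo) / (2.0 * eps)
    scale = np.maximum(np.abs(analytic) + np.abs(numeric), 1e-8)
    return float(np.max(np.abs(analytic - numeric) / scale))
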