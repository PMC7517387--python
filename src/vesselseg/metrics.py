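"""Pixel-classification metrics for vessel segmentation.

Positive = vessel, negative = background.  Sensitivity is TP/(TP+FN),
specificity TN/(FP+TN), accuracy (TP+TN)/(TP+FN+TN+FP).  The ROC curve sweeps
a threshold over the predicted probability map, plotting TPR against FPR, and
the AUC is its trapezoidal area.  When a field-of-view (FOV) mask is supplied
only pixels inside it are counted — the black corners of a fundus photograph
carry no information and would inflate specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "UndefinedMetricWarning",
    "confusion",
    "sen_spe_acc",
    "roc_auc",
    "evaluate_dataset",
]


class UndefinedMetricWarning(UserWarning):
    """A metric's denominator is zero (or the FOV is empty); NaN is reported."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class RocCurve:
    """Threshold-swept (FPR, TPR) points, sorted by FPR, with trapezoidal AUC."""

    points: np.ndarray  # (n, 2) columns (fpr, tpr), endpoints (0,0) and (1,1)
    auc: float


def _binary(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1, False, True)).all():
        raise ValueError(f"{name} must be binary")
    return m.astype(bool)


def confusion(
    pred: np.ndarray, truth: np.ndarray, fov: np.ndarray | None = None
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN over the FOV (or the whole frame if no FOV given)."""
    p = _binary(pred, "pred")
    t = _binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if fov is not None:
        f = _binary(fov, "fov")
        if f.shape != t.shape:
            raise ValueError(f"shape mismatch: fov {f.shape} vs truth {t.shape}")
        if not f.any():
            warnings.warn("empty FOV: all confusion counts are zero",
                          UndefinedMetricWarning, stacklevel=2)
        p, t = p[f], t[f]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def sen_spe_acc(c: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity, accuracy; NaN (with a warning) on a zero denominator."""

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator",
                          UndefinedMetricWarning, stacklevel=3)
            return float("nan")
        return num / den

    sen = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spe = _ratio(c.tn, c.fp + c.tn, "specificity")
    acc = _ratio(c.tp + c.tn, c.total, "accuracy")
    return sen, spe, acc


def roc_auc(
    prob: np.ndarray,
    truth: np.ndarray,
    fov: np.ndarray | None = None,
    n_thresholds: int = 256,
) -> RocCurve:
    """ROC curve and trapezoidal AUC from a probability map.

    Thresholds sweep the unique predicted values (subsampled to at most
    ``n_thresholds``); the (0,0) and (1,1) endpoints are always included.
    Ties in the probability map are handled correctly because thresholds are
    drawn from the distinct values; when none are dropped (``n_thresholds`` at
    least the number of distinct values) the trapezoidal area equals the
    Mann–Whitney pair-counting statistic exactly.
    """
    p = np.asarray(prob, dtype=np.float64)
    t = _binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: prob {p.shape} vs truth {t.shape}")
    if fov is not None:
        f = _binary(fov, "fov")
        p, t = p[f], t[f]
    p, t = p.ravel(), t.ravel()
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class truth: AUC undefined",
                      UndefinedMetricWarning, stacklevel=2)
        return RocCurve(points=np.array([[0.0, 0.0], [1.0, 1.0]]), auc=float("nan"))

    thr = np.unique(p)
    if thr.size > n_thresholds:
        thr = thr[np.linspace(0, thr.size - 1, n_thresholds).round().astype(int)]
    # predict positive at prob >= threshold; sweep descending so FPR ascends
    order = np.argsort(p)
    t_sorted = t[order].astype(np.int64)
    # cum_pos[i] = positives with prob < p_sorted[i] boundary handled via searchsorted
    cum_pos = np.concatenate([[0], np.cumsum(t_sorted)])
    idx = np.searchsorted(p[order], thr, side="left")
    tp = n_pos - cum_pos[idx]
    fp = n_neg - (idx - cum_pos[idx])
    tpr = tp / n_pos
    fpr = fp / n_neg
    pts = np.column_stack([fpr, tpr])
    pts = np.vstack([[1.0, 1.0], pts, [0.0, 0.0]])
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RocCurve(points=pts, auc=auc)


def evaluate_dataset(
    predict_fn,
    pairs,
    threshold: float = 0.5,
    use_fov: bool = True,
    n_thresholds: int = 256,
) -> pd.DataFrame:
    """Per-image and micro-pooled metrics table.

    ``predict_fn(pair) -> probability map`` is called per sample (it wraps the
    model plus any preprocessing).  The returned frame has one row per image
    with columns (image_id, sen, spe, acc, auc) and a final ``pooled`` row
    whose sen/spe/acc come from the summed confusion counts and whose AUC is
    computed over the concatenated pixels.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty dataset")
    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    all_p, all_t = [], []
    for pair in pairs:
        try:
            prob = np.asarray(predict_fn(pair), dtype=np.float64)
            fov = pair.fov if use_fov else None
            pred = (prob >= threshold).astype(np.uint8)
            c = confusion(pred, pair.truth, fov)
            sen, spe, acc = sen_spe_acc(c)
            auc = roc_auc(prob, pair.truth, fov, n_thresholds).auc
        except Exception as exc:  # re-raise with the offending image attached
            raise RuntimeError(f"evaluation failed on image {pair.id!r}: {exc}") from exc
        pooled = pooled + c
        mask = np.asarray(fov, dtype=bool) if fov is not None else np.ones(prob.shape, bool)
        all_p.append(prob[mask])
        all_t.append(np.asarray(pair.truth)[mask])
        rows.append({"image_id": pair.id, "sen": sen, "spe": spe, "acc": acc, "auc": auc})
    sen, spe, acc = sen_spe_acc(pooled)
    auc = roc_auc(np.concatenate(all_p), np.concatenate(all_t), None, n_thresholds).auc
    rows.append({"image_id": "pooled", "sen": sen, "spe": spe, "acc": acc, "auc": auc})
    return pd.DataFrame(rows)
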