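"""Training objective (BCE + Dice) and the segmentation metric suite.

The training loss is the unweighted sum of mean pixelwise binary
cross-entropy and a soft Dice loss computed over all pixels of the batch.
Evaluation binarizes the probability map at 0.4 (chosen in the source
protocol from an ROC analysis) and reports the standard confusion-matrix
metrics; Dice and F1 coincide on binary masks by construction.

Ratios with zero denominators (e.g. sensitivity when the ground truth is
all background) are reported as ``None`` rather than silently coerced to
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "binarize",
    "soft_dice_loss",
    "bce_loss",
    "combined_loss",
    "combined_loss_grad",
    "metrics_from_counts",
    "compute_metrics",
]

DEFAULT_THRESHOLD = 0.4
DICE_SMOOTH = 1e-6
BCE_EPS = 1e-7


def binarize(prob_map: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold a probability map into a {0,1} mask; strictly greater-than."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    prob_map = np.asarray(prob_map)
    if prob_map.size and (prob_map.min() < 0 or prob_map.max() > 1):
        raise ValueError("probability map values must lie in [0,1]")
    return (prob_map > threshold).astype(np.uint8)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @classmethod
    def from_masks(cls, pred: np.ndarray, gt: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred).astype(bool)
        gt = np.asarray(gt).astype(bool)
        if pred.shape != gt.shape:
            raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
        return cls(
            tp=int(np.sum(pred & gt)),
            fp=int(np.sum(pred & ~gt)),
            tn=int(np.sum(~pred & ~gt)),
            fn=int(np.sum(~pred & gt)),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsRecord:
    """Confusion-matrix metrics plus the two loss values; None marks 0/0 cases."""

    accuracy: float | None = None
    precision: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None
    dice_coefficient: float | None = None
    loss: float | None = None
    dice_loss: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def metrics_from_counts(c: ConfusionCounts) -> MetricsRecord:
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision == 0.0 or recall == 0.0:
        f1 = 0.0
    return MetricsRecord(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        sensitivity=recall,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=f1,
        dice_coefficient=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def soft_dice_loss(prob_map: np.ndarray, gt_mask: np.ndarray, smooth: float = DICE_SMOOTH) -> float:
    """1 - (2*sum(p*g)+s) / (sum(p)+sum(g)+s), computed over all pixels given."""
    p = np.asarray(prob_map, dtype=np.float64)
    g = np.asarray(gt_mask, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    inter = float((p * g).sum())
    return 1.0 - (2.0 * inter + smooth) / (float(p.sum()) + float(g.sum()) + smooth)


def bce_loss(prob_map: np.ndarray, gt_mask: np.ndarray, eps: float = BCE_EPS) -> float:
    """Mean pixelwise binary cross-entropy with probability clipping."""
    p = np.clip(np.asarray(prob_map, dtype=np.float64), eps, 1.0 - eps)
    g = np.asarray(gt_mask, dtype=np.float64)
    return float(-(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).mean())


def combined_loss(
    prob_map: np.ndarray,
    gt_mask: np.ndarray,
    bce_weight: float = 1.0,
    dice_weight: float = 1.0,
) -> float:
    return bce_weight * bce_loss(prob_map, gt_mask) + dice_weight * soft_dice_loss(
        prob_map, gt_mask
    )


def combined_loss_grad(
    prob_map: np.ndarray,
    gt_mask: np.ndarray,
    bce_weight: float = 1.0,
    dice_weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the probability map.

    The closed-form gradient feeds the network's backward pass directly;
    the soft Dice term is differentiated through its global sums.
    """
    p = np.asarray(prob_map, dtype=np.float64)
    g = np.asarray(gt_mask, dtype=np.float64)
    pc = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    n = p.size
    bce = float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())
    grad_bce = (pc - g) / (pc * (1.0 - pc)) / n

    inter = float((p * g).sum())
    denom = float(p.sum()) + float(g.sum()) + DICE_SMOOTH
    dice_l = 1.0 - (2.0 * inter + DICE_SMOOTH) / denom
    # d/dp_i [-(2*inter+s)/denom] = -(2*g_i*denom - (2*inter+s)) / denom^2
    grad_dice = -(2.0 * g * denom - (2.0 * inter + DICE_SMOOTH)) / denom**2

    loss = bce_weight * bce + dice_weight * dice_l
    grad = (bce_weight * grad_bce + dice_weight * grad_dice).astype(np.float32)
    return loss, grad


def compute_metrics(
    prob_map: np.ndarray,
    gt_mask: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> MetricsRecord:
    """Binarize at ``threshold`` and report the full metric record."""
    pred = binarize(prob_map, threshold)
    rec = metrics_from_counts(ConfusionCounts.from_masks(pred, gt_mask))
    rec.loss = combined_loss(prob_map, gt_mask)
    rec.dice_loss = soft_dice_loss(prob_map, gt_mask)
    return rec
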