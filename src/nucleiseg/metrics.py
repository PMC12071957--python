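"""Training loss and evaluation statistics for binary nuclei segmentation.

The training objective is the hybrid loss ``alpha * BCE + (1 - alpha) *
DiceLoss`` with ``alpha = 0.5`` by default.  Evaluation covers pixel-level
overlap scores (Dice, Jaccard/IoU, accuracy, precision/recall/F1, figure of
merit) and object-level detection via greedy IoU matching of instances.

Two figure-of-merit entry points exist on purpose: the literal pixel-count
form TP/(TP+FP+FN) coincides with IoU on the same counts, while the
precision/recall-derived form PR/(P+R-PR) is a distinct statistic; reports
label which one was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: clamp for probabilities inside the BCE term
_EPS = 1e-7
#: smoothing term of the soft-Dice loss
DICE_SMOOTH = 1e-6


# ---------------------------------------------------------------------------
# loss

def soft_dice_loss(probs: np.ndarray, target: np.ndarray,
                   smooth: float = DICE_SMOOTH) -> float:
    """1 - soft Dice of a probability map against a binary target."""
    p = np.asarray(probs, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def binary_cross_entropy(probs: np.ndarray, target: np.ndarray) -> float:
    p = np.clip(np.asarray(probs, dtype=np.float64), _EPS, 1.0 - _EPS)
    t = np.asarray(target, dtype=np.float64)
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


def hybrid_loss(probs: np.ndarray, target: np.ndarray, alpha: float = 0.5,
                sample_weight: np.ndarray | None = None,
                return_grad: bool = False):
    """Weighted sum of BCE and soft-Dice loss.

    ``probs`` and ``target`` are broadcast-compatible arrays whose leading
    axis indexes samples when ``sample_weight`` is given.  With
    ``return_grad=True`` the gradient with respect to ``probs`` is returned
    alongside the scalar, for use by the training loop.
    """
    p = np.asarray(probs, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs target {t.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if sample_weight is None:
        w = np.ones(p.shape[0] if p.ndim else 1, dtype=np.float64)
    else:
        w = np.asarray(sample_weight, dtype=np.float64)
        if w.shape != (p.shape[0],):
            raise ValueError("sample_weight must have one entry per sample")
    wb = w.reshape((-1,) + (1,) * (p.ndim - 1))
    wmean = float(w.mean()) if w.size else 1.0

    pc = np.clip(p, _EPS, 1.0 - _EPS)
    per_pixel_bce = -(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc))
    bce = float((wb * per_pixel_bce).mean() / wmean)

    inter = float((wb * p * t).sum())
    psum = float((wb * p).sum())
    tsum = float((wb * t).sum())
    dice = (2.0 * inter + DICE_SMOOTH) / (psum + tsum + DICE_SMOOTH)
    loss = alpha * bce + (1.0 - alpha) * (1.0 - dice)
    if not return_grad:
        return loss

    n = p.size
    g_bce = wb * (pc - t) / (pc * (1.0 - pc)) / (n * wmean)
    denom = psum + tsum + DICE_SMOOTH
    g_dice = -(2.0 * wb * t * denom - (2.0 * inter + DICE_SMOOTH) * wb) / denom ** 2
    grad = alpha * g_bce + (1.0 - alpha) * g_dice
    return loss, grad


# ---------------------------------------------------------------------------
# pixel-level metrics

@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN pixel tallies of a binarized prediction vs ground truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_masks(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        p, g = _as_mask_pair(pred, truth)
        return cls(tp=int((p & g).sum()), tn=int((~p & ~g).sum()),
                   fp=int((p & ~g).sum()), fn=int((~p & g).sum()))


def _as_mask_pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred)
    g = np.asarray(truth)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    for name, a in (("pred", p), ("truth", g)):
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    return p.astype(bool), g.astype(bool)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """2|P∩G| / (|P|+|G|); empty vs empty scores 1.0 by convention."""
    p, g = _as_mask_pair(pred, truth)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def jaccard_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """|P∩G| / |P∪G|; empty vs empty scores 1.0.  Satisfies
    IoU = DSC / (2 - DSC) on any mask pair."""
    p, g = _as_mask_pair(pred, truth)
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


def pixel_accuracy(counts: ConfusionCounts) -> float:
    """(TP+TN) / total."""
    if counts.total == 0:
        raise ValueError("no pixels compared")
    return (counts.tp + counts.tn) / counts.total


def figure_of_merit(counts: ConfusionCounts) -> float:
    """Literal pixel-count figure of merit TP/(TP+FP+FN).

    On pixel counts this coincides with the Jaccard index; see
    :func:`figure_of_merit_pr` for the precision/recall-derived form.
    """
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0  # tn-only comparison: nothing to find, nothing found
    return counts.tp / denom


def figure_of_merit_pr(precision: float, recall: float) -> float:
    """Precision/recall-derived figure of merit PR/(P+R-PR)."""
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return precision * recall / (precision + recall - precision * recall)


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1; degenerate zero denominators yield 0."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


# ---------------------------------------------------------------------------
# object-level matching

def _check_disjoint(masks: list[np.ndarray], what: str) -> list[np.ndarray]:
    out = []
    cover = None
    for m in masks:
        b = np.asarray(m).astype(bool)
        if cover is None:
            cover = np.zeros_like(b)
        if (cover & b).any():
            raise ValueError(f"{what} instance masks overlap (no-overlap rule)")
        cover |= b
        out.append(b)
    return out


def pairwise_iou(pred_masks: list[np.ndarray],
                 gt_masks: list[np.ndarray]) -> np.ndarray:
    """IoU matrix (n_pred x n_gt) between two sets of instance masks."""
    iou = np.zeros((len(pred_masks), len(gt_masks)))
    for i, p in enumerate(pred_masks):
        for j, g in enumerate(gt_masks):
            union = int((p | g).sum())
            iou[i, j] = int((p & g).sum()) / union if union else 0.0
    return iou


def greedy_match(iou: np.ndarray, iou_threshold: float = 0.5) -> list[tuple[int, int]]:
    """One-to-one matching in descending pairwise-IoU order.

    Ties break deterministically on lower ground-truth index, then lower
    prediction index.  Only pairs with IoU strictly above the threshold
    participate.  Returns (pred_index, gt_index) pairs.
    """
    n_pred, n_gt = iou.shape
    candidates = [(-iou[i, j], j, i) for i in range(n_pred) for j in range(n_gt)
                  if iou[i, j] > iou_threshold]
    candidates.sort()
    used_p: set[int] = set()
    used_g: set[int] = set()
    matches = []
    for neg, j, i in candidates:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        matches.append((i, j))
    return matches


def match_objects(pred_masks: list[np.ndarray], gt_masks: list[np.ndarray],
                  iou_threshold: float = 0.5) -> tuple[list[tuple[int, int]], float]:
    """Greedy instance matching; a ground-truth nucleus counts as detected iff
    matched with IoU strictly above the threshold.  Returns the matching and
    the detection rate (detected / total ground truth)."""
    pred = _check_disjoint(list(pred_masks), "predicted")
    gt = _check_disjoint(list(gt_masks), "ground-truth")
    if not gt:
        return [], 1.0 if not pred else 0.0
    matches = greedy_match(pairwise_iou(pred, gt), iou_threshold)
    return matches, len(matches) / len(gt)


# ---------------------------------------------------------------------------
# reporting

@dataclass
class MetricReport:
    """Per-image and aggregate values of every evaluation statistic."""

    per_image: list[dict] = field(default_factory=list)
    fom_mode: str = "precision_recall"

    COLUMNS = ("accuracy", "precision", "recall", "f1", "dsc", "iou", "fom",
               "object_detection_rate")

    def add_image(self, image_id: str, pred_mask: np.ndarray, truth_mask: np.ndarray,
                  pred_instances: list[np.ndarray] | None = None,
                  gt_instances: list[np.ndarray] | None = None,
                  iou_threshold: float = 0.5) -> dict:
        counts = ConfusionCounts.from_masks(pred_mask, truth_mask)
        precision, recall, f1 = precision_recall_f1(counts)
        row = {
            "image_id": image_id,
            "accuracy": pixel_accuracy(counts),
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "dsc": dice_coefficient(pred_mask, truth_mask),
            "iou": jaccard_iou(pred_mask, truth_mask),
            "fom": (figure_of_merit_pr(precision, recall)
                    if self.fom_mode == "precision_recall"
                    else figure_of_merit(counts)),
            "degenerate": counts.tp + counts.fp + counts.fn == 0,
        }
        if pred_instances is not None and gt_instances is not None:
            _, rate = match_objects(pred_instances, gt_instances, iou_threshold)
            row["object_detection_rate"] = rate
        self.per_image.append(row)
        return row

    def aggregate(self) -> dict:
        agg = {}
        for col in self.COLUMNS:
            vals = [r[col] for r in self.per_image if col in r]
            if vals:
                agg[col] = float(np.mean(vals))
        agg["n_images"] = len(self.per_image)
        agg["fom_mode"] = self.fom_mode
        return agg

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.per_image)
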