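"""Detection/segmentation evaluation metrics and dataset splitting.

Axis-aligned box IoU, confusion-count precision/recall/F1, COCO-style
average precision (101-point interpolated PR curve, greedy
score-descending matching with one-to-one ground-truth assignment), mAP
over classes and over an IoU threshold grid (0.50:0.95 step 0.05), and a
deterministic train/validation/test split.

Boxes are (x, y, width, height) in pixels with continuous (float) area
arithmetic.  Predictions are (image_id, box, score) triples; ground
truths are (image_id, box) pairs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

#: default IoU threshold grid for mAP@[0.5:0.95]
DEFAULT_IOU_GRID = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes, in [0, 1]."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("box width and height must be positive")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(P, R, F1) with the defined-zero convention: an undefined ratio
    (zero denominator) is 0, and F1 = 0 whenever TP = 0.  The harmonic
    -mean and the 2TP/(2TP+FP+FN) forms of F1 agree identically."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if tp > 0 else 0.0
    return precision, recall, f1


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def _match_predictions(predictions, ground_truths, iou_threshold):
    """Greedy matching in descending score order; returns TP/FP flags in
    that order plus the number of ground truths."""
    preds = list(predictions)
    order = np.argsort([-float(p[2]) for p in preds], kind="stable")
    gts_by_image: dict = defaultdict(list)
    for img, box in ground_truths:
        gts_by_image[img].append([box, False])  # box, matched
    tp_flags = np.zeros(len(preds), dtype=bool)
    for rank, idx in enumerate(order):
        img, box, _ = preds[idx]
        best_iou, best = 0.0, None
        for gt in gts_by_image.get(img, ()):
            if gt[1]:
                continue
            v = iou(box, gt[0])
            if v >= iou_threshold and v > best_iou:
                best_iou, best = v, gt
        if best is not None:
            best[1] = True
            tp_flags[rank] = True
    return tp_flags, len(list(ground_truths))


def average_precision(predictions: Sequence, ground_truths: Sequence,
                      iou_threshold: float = 0.5) -> float:
    """COCO-style AP for one class.

    ``predictions``: (image_id, box, score) triples; ``ground_truths``:
    (image_id, box) pairs.  Each ground truth is matched at most once, in
    descending score order (ties keep input order).  AP is the mean of
    the interpolated precision over 101 equally spaced recall points.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must be in (0, 1]")
    ground_truths = list(ground_truths)
    n_gt = len(ground_truths)
    if n_gt == 0 or len(predictions) == 0:
        return 0.0
    tp_flags, _ = _match_predictions(predictions, ground_truths, iou_threshold)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    recall_grid = np.linspace(0.0, 1.0, 101)
    interpolated = np.zeros_like(recall_grid)
    for i, r in enumerate(recall_grid):
        mask = recall >= r
        interpolated[i] = precision[mask].max() if mask.any() else 0.0
    return float(interpolated.mean())


def mean_ap(per_class_ap: Mapping[object, float] | Sequence[float]) -> float:
    """Unweighted mean of per-class average precisions."""
    values = list(per_class_ap.values()) if isinstance(per_class_ap, Mapping) \
        else list(per_class_ap)
    if not values:
        raise ValueError("at least one class is required")
    return float(np.mean(values))


def map_range(predictions_by_class: Mapping[object, Sequence],
              ground_truths_by_class: Mapping[object, Sequence],
              grid: Sequence[float] = DEFAULT_IOU_GRID) -> float:
    """mAP averaged over an IoU threshold grid (default 0.50:0.95)."""
    grid = list(grid)
    if not grid or list(grid) != sorted(grid):
        raise ValueError("grid must be a non-empty ascending sequence")
    classes = sorted(set(predictions_by_class) | set(ground_truths_by_class),
                     key=str)
    if not classes:
        raise ValueError("at least one class is required")
    values = []
    for thr in grid:
        aps = [average_precision(predictions_by_class.get(cls, []),
                                 ground_truths_by_class.get(cls, []), thr)
               for cls in classes]
        values.append(mean_ap(aps))
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

def split_dataset(n_items: int, ratios: Sequence[float] = (0.7, 0.2, 0.1),
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic disjoint train/validation/test partition of
    ``range(n_items)``.

    Subset sizes are ``floor(n * r)`` with the remainder assigned one
    item at a time in decreasing-ratio order (train first, then
    validation).  The shuffle derives from ``seed`` alone.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be three non-negative numbers")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if n_items < 3:
        raise ValueError("n_items must be >= 3")
    sizes = [int(np.floor(n_items * r)) for r in ratios]
    remainder = n_items - sum(sizes)
    order = sorted(range(3), key=lambda i: (-ratios[i], i))
    for i in range(remainder):
        sizes[order[i % 3]] += 1
    perm = np.random.default_rng(seed).permutation(n_items)
    train = perm[: sizes[0]]
    val = perm[sizes[0]: sizes[0] + sizes[1]]
    test = perm[sizes[0] + sizes[1]:]
    return train, val, test
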