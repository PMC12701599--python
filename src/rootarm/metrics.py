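"""Mask-level detection/segmentation evaluation: IoU, PR curves, AP, mAP@0.5.

Matching is done per image and per class, greedily in descending prediction
confidence: each prediction is assigned the unmatched ground-truth mask of
highest IoU, and counts as a true positive when that IoU is at least the
threshold (inclusive, default 0.5).  Average precision is the area under
the precision-recall curve with the monotone precision envelope and
all-points interpolation; mAP@0.5 is the arithmetic mean of per-class AP.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .maskgeom import BinaryMask

logger = logging.getLogger(__name__)

__all__ = [
    "InstancePrediction",
    "GroundTruthInstance",
    "PRCurve",
    "APResult",
    "mask_iou",
    "match_instances",
    "precision_recall",
    "average_precision",
    "map_at_50",
    "evaluate",
]

CLASSES = ("seed", "root")


@dataclass(frozen=True)
class InstancePrediction:
    image_id: str
    class_label: str
    confidence: float
    mask: BinaryMask
    instance_id: str = ""

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if not math.isfinite(self.confidence):
            raise ValueError("confidence must be finite")
        if self.mask.area == 0:
            raise ValueError("prediction mask must be non-empty")

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(x_min, y_min, x_max, y_max) of the mask's foreground."""
        ys, xs = np.nonzero(self.mask.grid)
        return int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())


@dataclass(frozen=True)
class GroundTruthInstance:
    image_id: str
    class_label: str
    mask: BinaryMask

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.mask.area == 0:
            raise ValueError("ground-truth mask must be non-empty")


def mask_iou(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection over union of two equal-sized binary masks."""
    if a.grid.shape != b.grid.shape:
        raise ValueError(
            f"mask dimensions differ: {a.grid.shape} vs {b.grid.shape}"
        )
    inter = np.logical_and(a.grid, b.grid).sum()
    union = np.logical_or(a.grid, b.grid).sum()
    return float(inter) / float(union) if union else 0.0


def match_instances(
    preds: Sequence[InstancePrediction],
    gts: Sequence[GroundTruthInstance],
    iou_threshold: float = 0.5,
) -> tuple[list[bool], int]:
    """Greedy one-to-one matching of one image's, one class's instances.

    Predictions are processed in descending confidence; each one matches the
    still-unmatched ground truth of highest IoU provided that IoU >=
    ``iou_threshold`` (inclusive).  Returns per-prediction TP flags in the
    sorted order, and the count of unmatched ground truths (false negatives).
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    matched = [False] * len(gts)
    flags: list[bool] = []
    for i in order:
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if matched[j]:
                continue
            iou = mask_iou(preds[i].mask, gt.mask)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    fn = matched.count(False)
    return flags, fn


@dataclass
class PRCurve:
    """Cumulative precision/recall over the descending-confidence sweep."""

    precision: np.ndarray
    recall: np.ndarray
    n_gt: int

    def __post_init__(self) -> None:
        if len(self.precision) != len(self.recall):
            raise ValueError("precision and recall must have equal length")


def precision_recall(flags: Sequence[bool], n_gt: int) -> PRCurve:
    """Cumulative P/R arrays from confidence-ordered TP/FP flags.

    ``Precision = TP / (TP + FP)`` and ``Recall = TP / n_gt`` at each prefix
    of the sweep.  With no ground truths every prediction is a false
    positive and the resulting AP is zero.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    tp = np.cumsum(np.asarray(flags, dtype=float))
    fp = np.cumsum(1.0 - np.asarray(flags, dtype=float))
    denom = tp + fp
    precision = np.divide(tp, denom, out=np.zeros_like(tp), where=denom > 0)
    recall = tp / n_gt if n_gt > 0 else np.zeros_like(tp)
    return PRCurve(precision=precision, recall=recall, n_gt=n_gt)


def average_precision(curve: PRCurve) -> float:
    """Area under P(R) with monotone envelope, all-points interpolation."""
    if len(curve.precision) == 0 or curve.n_gt == 0:
        return 0.0
    # prepend R=0 and apply the running-max envelope from the right
    r = np.concatenate([[0.0], curve.recall])
    p = np.concatenate([[1.0], curve.precision])
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


@dataclass
class APResult:
    per_class: dict[str, float]
    map50: float
    skipped_classes: list[str] = field(default_factory=list)


def map_at_50(per_class_ap: dict[str, float | None]) -> APResult:
    """Arithmetic mean of per-class AP; classes with no ground truth
    anywhere in the set (AP is None) are excluded from the mean and logged."""
    present = {k: v for k, v in per_class_ap.items() if v is not None}
    skipped = sorted(k for k, v in per_class_ap.items() if v is None)
    if not present:
        raise ValueError("no class has ground-truth instances")
    for k in skipped:
        logger.warning("class %r has no ground truth; excluded from mAP", k)
    return APResult(
        per_class=dict(present),
        map50=float(np.mean(list(present.values()))),
        skipped_classes=skipped,
    )


def evaluate(
    preds: Iterable[InstancePrediction],
    gts: Iterable[GroundTruthInstance],
    iou_threshold: float = 0.5,
    classes: Sequence[str] = CLASSES,
) -> APResult:
    """Full dataset evaluation: per-class AP over all images, then mAP.

    Flags from per-image matching are pooled per class, re-sorted globally
    by confidence, and integrated into one PR curve per class.
    """
    preds = list(preds)
    gts = list(gts)
    per_class_ap: dict[str, float | None] = {}
    for cls in classes:
        cls_preds = [p for p in preds if p.class_label == cls]
        cls_gts = [g for g in gts if g.class_label == cls]
        if not cls_gts:
            per_class_ap[cls] = None
            continue
        image_ids = sorted(
            {p.image_id for p in cls_preds} | {g.image_id for g in cls_gts}
        )
        scored: list[tuple[float, bool]] = []
        n_gt = 0
        for img in image_ids:
            ip = [p for p in cls_preds if p.image_id == img]
            ig = [g for g in cls_gts if g.image_id == img]
            n_gt += len(ig)
            flags, _ = match_instances(ip, ig, iou_threshold)
            confs = sorted((p.confidence for p in ip), reverse=True)
            scored.extend(zip(confs, flags))
        scored.sort(key=lambda t: -t[0])
        curve = precision_recall([f for _, f in scored], n_gt)
        per_class_ap[cls] = average_precision(curve)
    return map_at_50(per_class_ap)
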