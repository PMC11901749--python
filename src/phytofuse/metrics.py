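"""Detection and classification evaluation.

Precision / recall / accuracy from a confusion matrix, IoU, per-class
average precision by precision-recall integration, and mAP at a fixed IoU
threshold (default 0.75).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

Box = Tuple[float, float, float, float]  # (x0, y0, x1, y1), half-open


@dataclass(frozen=True)
class Detection:
    image_id: str
    class_id: int
    box: Box
    score: float

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"malformed box {self.box}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class EvalReport:
    """Per-class and macro metrics plus the confusion matrix behind them."""
    per_class: Dict[int, Dict[str, float]]
    macro: Dict[str, float]
    confusion: np.ndarray
    matches: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "macro": self.macro,
            "confusion": self.confusion.astype(int).tolist(),
        }


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two half-open boxes; disjoint -> 0."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def classification_metrics(confusion: np.ndarray) -> Tuple[Dict[int, Dict[str, float]], Dict[str, float]]:
    """One-vs-rest precision/recall per class plus macro averages and accuracy.

    0/0 ratios are reported as 0 (logged), never NaN.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be nonnegative")
    n_classes = cm.shape[0]
    total = cm.sum()
    per_class: Dict[int, Dict[str, float]] = {}
    for c in range(n_classes):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        if tp + fp == 0:
            logger.info("class %d has no predictions; precision set to 0", c)
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        if tp + fn == 0:
            logger.info("class %d has no ground truth; recall set to 0", c)
            rec = 0.0
        else:
            rec = tp / (tp + fn)
        per_class[c] = {"precision": float(prec), "recall": float(rec)}
    acc = float(np.trace(cm) / total) if total > 0 else 0.0
    macro = {
        "precision": float(np.mean([v["precision"] for v in per_class.values()])),
        "recall": float(np.mean([v["recall"] for v in per_class.values()])),
        "accuracy": acc,
    }
    return per_class, macro


def _match_detections(dets: Sequence[Detection],
                      gts: Mapping[str, Sequence[Box]],
                      iou_thresh: float) -> Tuple[List[bool], int]:
    """Greedy matching: detections in descending score (ties: image_id asc);
    each ground truth matched at most once; a detection takes the unmatched
    GT of highest IoU >= threshold in its image."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, dets[i].image_id))
    used: Dict[str, List[bool]] = {img: [False] * len(boxes) for img, boxes in gts.items()}
    n_gt = sum(len(b) for b in gts.values())
    hits: List[bool] = []
    for i in order:
        d = dets[i]
        best_j, best_iou = -1, -1.0
        for j, g in enumerate(gts.get(d.image_id, ())):
            if used[d.image_id][j]:
                continue
            v = iou(d.box, g)
            if v >= iou_thresh and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            used[d.image_id][best_j] = True
            hits.append(True)
        else:
            hits.append(False)
    return hits, n_gt


def _ap_from_hits(hits: Sequence[bool], n_gt: int,
                  interpolation: str = "all") -> float:
    """Area under the precision envelope over recall.

    `interpolation`: "all" (exact all-point), "11point", or "101point".
    """
    if n_gt == 0:
        raise ValueError("AP undefined with zero ground truths")
    if not hits:
        return 0.0
    tp = np.cumsum(np.asarray(hits, dtype=float))
    fp = np.cumsum(~np.asarray(hits, dtype=bool))
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope: max precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "all":
        ap = 0.0
        prev_r = 0.0
        for r, p, h in zip(recall, env, hits):
            if h:
                ap += (r - prev_r) * p
                prev_r = r
        return float(ap)
    if interpolation == "11point":
        pts = np.linspace(0, 1, 11)
    elif interpolation == "101point":
        pts = np.linspace(0, 1, 101)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    vals = [env[recall >= r].max() if (recall >= r).any() else 0.0 for r in pts]
    return float(np.mean(vals))


def average_precision(dets: Sequence[Detection],
                      gts: Mapping[str, Sequence[Box]],
                      iou_thresh: float,
                      interpolation: str = "all") -> float:
    """AP for a single class at a fixed IoU threshold."""
    hits, n_gt = _match_detections(dets, gts, iou_thresh)
    return _ap_from_hits(hits, n_gt, interpolation)


def map_at(dets: Sequence[Detection],
           gts: Mapping[Tuple[str, int], Sequence[Box]] | Mapping[str, Mapping[int, Sequence[Box]]],
           iou_thresh: float = 0.75,
           n_classes: int = 5,
           interpolation: str = "all") -> Tuple[float, Dict[int, float]]:
    """Unweighted mean of per-class APs; classes without ground truth are
    excluded (with a log note) rather than scored zero.

    `gts` maps image_id -> {class_id -> [boxes]}.
    """
    per_class_ap: Dict[int, float] = {}
    for c in range(n_classes):
        class_dets = [d for d in dets if d.class_id == c]
        class_gts = {img: list(bycls.get(c, [])) for img, bycls in gts.items()}
        class_gts = {img: boxes for img, boxes in class_gts.items() if boxes}
        if not class_gts:
            logger.warning("class %d has no ground truths; excluded from mAP", c)
            continue
        per_class_ap[c] = average_precision(class_dets, class_gts, iou_thresh,
                                            interpolation)
    if not per_class_ap:
        return 0.0, {}
    return float(np.mean(list(per_class_ap.values()))), per_class_ap
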