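"""Detection and classification metrics: mAP, accuracy, confusion matrices.

Detection quality uses the PASCAL-style protocol: detections are matched
greedily (descending score) to same-class ground-truth boxes at a fixed
IoU threshold, each ground truth matching at most once; average
precision integrates the precision envelope over all recall points
(all-point interpolation, not the older 11-point variant) and mAP is the
mean over the head and upper-body classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boxes import POSE_CLASSES, iou_matrix

logger = logging.getLogger(__name__)


@dataclass
class MatchResult:
    """Per-detection true/false-positive flags plus ground-truth coverage."""

    det_is_tp: np.ndarray
    det_scores: np.ndarray
    det_classes: list[str]
    gt_matched: np.ndarray
    iou_threshold: float


def match_detections(detections, ground_truth, iou_threshold: float
                     ) -> MatchResult:
    """Greedy score-descending matching within classes.

    ``detections`` carry ``box``/``region_class``/``region_score``;
    ``ground_truth`` carry ``box``/``region_class``.  Each detection
    matches the highest-IoU not-yet-matched ground truth of its class if
    that IoU reaches the threshold.
    """
    order = np.argsort([-d.region_score for d in detections], kind="stable")
    dets = [detections[i] for i in order]
    gt_boxes = np.array([g.box for g in ground_truth], dtype=float).reshape(
        -1, 4)
    gt_classes = [g.region_class for g in ground_truth]
    gt_matched = np.zeros(len(ground_truth), dtype=bool)
    is_tp = np.zeros(len(dets), dtype=bool)
    for i, det in enumerate(dets):
        best_j, best_iou = -1, 0.0
        for j, (gbox, gcls) in enumerate(zip(gt_boxes, gt_classes)):
            if gcls != det.region_class or gt_matched[j]:
                continue
            ov = float(iou_matrix(np.asarray(det.box), gbox)[0, 0])
            if ov > best_iou:
                best_iou, best_j = ov, j
        if best_j >= 0 and best_iou >= iou_threshold:
            is_tp[i] = True
            gt_matched[best_j] = True
    return MatchResult(is_tp, np.array([d.region_score for d in dets]),
                       [d.region_class for d in dets], gt_matched,
                       iou_threshold)


def average_precision(tp_flags: np.ndarray, scores: np.ndarray,
                      n_ground_truth: int) -> float:
    """All-point interpolated AP from flat TP flags and scores."""
    if n_ground_truth == 0:
        raise ValueError("average precision undefined without ground truth")
    if len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores), kind="stable")
    tp = np.asarray(tp_flags, dtype=float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1 - tp)
    recall = cum_tp / n_ground_truth
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope (running max from the right), then rectangle sum
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_average_precision(image_detections, image_ground_truths,
                           iou_threshold: float = 0.5,
                           classes=("head", "upper_body")) -> dict:
    """Per-class AP and their mean over a set of images.

    ``image_detections`` / ``image_ground_truths`` are parallel
    sequences, one entry per image.  A class with no ground truth
    anywhere is excluded from the mean (logged).
    """
    per_class: dict[str, float] = {}
    for cls in classes:
        flags, scores, n_gt = [], [], 0
        for dets, gts in zip(image_detections, image_ground_truths,
                             strict=True):
            match = match_detections(dets, gts, iou_threshold)
            for f, s, c in zip(match.det_is_tp, match.det_scores,
                               match.det_classes):
                if c == cls:
                    flags.append(f)
                    scores.append(s)
            n_gt += sum(1 for g in gts if g.region_class == cls)
        if n_gt == 0:
            logger.warning("class %s has no ground truth; excluded from mAP",
                           cls)
            continue
        per_class[cls] = average_precision(np.array(flags), np.array(scores),
                                           n_gt)
    if not per_class:
        raise ValueError("no class had ground truth")
    result = {f"AP_{c}": v for c, v in per_class.items()}
    result["mAP"] = float(np.mean(list(per_class.values())))
    return result


def classification_accuracy(true_labels, predicted_labels) -> float:
    """Percentage of exact label agreements (0-100)."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    if not true_labels:
        raise ValueError("cannot compute accuracy of an empty label set")
    correct = sum(t == p for t, p in zip(true_labels, predicted_labels))
    return 100.0 * correct / len(true_labels)


@dataclass
class ConfusionMatrix:
    """Pose-class confusion counts; rows = truth, columns = prediction."""

    counts: np.ndarray
    classes: tuple[str, ...] = POSE_CLASSES

    def normalized(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(row_sums > 0, self.counts / row_sums, 0.0)
        return out

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return 100.0 * np.trace(self.counts) / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion_matrix(true_labels, predicted_labels,
                     classes=POSE_CLASSES) -> ConfusionMatrix:
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(list(true_labels), list(predicted_labels), strict=True):
        if t not in idx or p not in idx:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))
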