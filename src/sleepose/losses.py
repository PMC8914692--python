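"""Multi-task losses for joint detection and pose classification.

The total training objective is a weighted sum of four terms: region
classification (head / upper-body / background, categorical
cross-entropy), head-pose and upper-body-pose classification (categorical
cross-entropy, each masked to regions of the matching class), and
bounding-box regression (smooth L1 over the four parameterized
coordinates of foreground regions):

    L = lambda_class * L_class + lambda_head * L_head
        + lambda_body * L_body + lambda_box * L_box

All functions here consume probabilities / plain arrays and return
scalars, so they double as the independent reference used when checking
the network's internally computed gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .boxes import REGION_CLASSES

logger = logging.getLogger(__name__)

HEAD = REGION_CLASSES.index("head")
UPPER_BODY = REGION_CLASSES.index("upper_body")

_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class LossWeights:
    """Weights balancing the four task losses; all must be nonnegative."""

    lambda_class: float = 1.0
    lambda_head: float = 1.0
    lambda_body: float = 1.0
    lambda_box: float = 1.0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class LossBreakdown:
    L_class: float
    L_head: float
    L_body: float
    L_box: float
    L_total: float


def _cross_entropy_rows(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Per-row -log score of the true class; labels are class indices."""
    labels = np.asarray(labels, dtype=int)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    p = scores[np.arange(len(labels)), labels]
    if np.any(p <= 0):
        logger.warning("zero predicted score for a true class; clamping to "
                       "machine epsilon")
        p = np.clip(p, _EPS, None)
    return -np.log(p)


def loss_detection_class(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mean categorical cross-entropy over region classes.

    ``labels`` are region-class indices over (head, upper_body,
    background); ``scores`` are softmax outputs, one row per sampled
    region.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return 0.0
    return float(_cross_entropy_rows(labels, scores).mean())


def _masked_pose_loss(region_labels, pose_labels, pose_scores,
                      target_region: int) -> float:
    region_labels = np.asarray(region_labels, dtype=int)
    mask = region_labels == target_region
    if not mask.any():
        return 0.0
    pose_labels = np.asarray(pose_labels, dtype=int)[mask]
    pose_scores = np.atleast_2d(np.asarray(pose_scores, dtype=float))[mask]
    return float(_cross_entropy_rows(pose_labels, pose_scores).mean())


def loss_head_pose(region_labels, pose_labels, pose_scores) -> float:
    """Pose cross-entropy averaged over regions labelled as heads only."""
    return _masked_pose_loss(region_labels, pose_labels, pose_scores, HEAD)


def loss_body_pose(region_labels, pose_labels, pose_scores) -> float:
    """Pose cross-entropy averaged over upper-body regions only."""
    return _masked_pose_loss(region_labels, pose_labels, pose_scores,
                             UPPER_BODY)


def smooth_l1(d: np.ndarray) -> np.ndarray:
    """Elementwise smooth L1: 0.5 d^2 for |d| < 1, |d| - 0.5 otherwise."""
    d = np.asarray(d, dtype=float)
    a = np.abs(d)
    return np.where(a < 1, 0.5 * d * d, a - 0.5)


def smooth_l1_grad(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    return np.clip(d, -1.0, 1.0)


def loss_box_regression(pred_deltas: np.ndarray,
                        target_deltas: np.ndarray) -> float:
    """Smooth-L1 box loss, summed over (tx, ty, tw, th) and averaged over
    the foreground regions supplied (callers pass matched rows only)."""
    pred = np.atleast_2d(np.asarray(pred_deltas, dtype=float))
    target = np.atleast_2d(np.asarray(target_deltas, dtype=float))
    if pred.size == 0:
        return 0.0
    return float(smooth_l1(pred - target).sum(axis=1).mean())


def total_loss(L_class: float, L_head: float, L_body: float, L_box: float,
               weights: LossWeights) -> LossBreakdown:
    """Combine the four components into the weighted-sum objective."""
    total = (weights.lambda_class * L_class + weights.lambda_head * L_head
             + weights.lambda_body * L_body + weights.lambda_box * L_box)
    return LossBreakdown(float(L_class), float(L_head), float(L_body),
                         float(L_box), float(total))
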