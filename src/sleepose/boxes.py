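"""Box geometry for the two-stage detector.

All boxes are ``(x_min, y_min, x_max, y_max)`` in 0-based, half-open pixel
coordinates: a box covers columns ``x_min <= x < x_max`` and rows
``y_min <= y < y_max``, so its area is ``(x_max - x_min) * (y_max - y_min)``.

Class orderings are fixed package-wide:

* region classes: ``head``, ``upper_body``, ``background``
* pose classes: ``supine``, ``prone``, ``left``, ``right``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

REGION_CLASSES = ("head", "upper_body", "background")
POSE_CLASSES = ("supine", "prone", "left", "right")
BACKGROUND = REGION_CLASSES.index("background")


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor layout: three areas x three aspect ratios = nine per location.

    ``scales`` are the side lengths of the square (1:1) anchors, i.e. an
    entry ``s`` denotes an anchor of area ``s**2``.  ``aspect_ratios`` are
    width:height ratios; non-square anchors preserve the area of their scale.
    ``stride`` is the pixel spacing between feature-map locations.
    """

    scales: tuple[float, ...] = (128.0, 256.0, 512.0)
    aspect_ratios: tuple[float, ...] = (1.0, 0.5, 2.0)
    stride: int = 16

    @property
    def anchors_per_location(self) -> int:
        return len(self.scales) * len(self.aspect_ratios)


def generate_anchors(feature_map_height: int, feature_map_width: int,
                     cfg: AnchorConfig) -> np.ndarray:
    """Tile the nine reference boxes over every feature-map location.

    Returns an ``(H * W * A, 4)`` float array ordered location-major
    (row, column, anchor).  Anchor centers sit at
    ``((j + 0.5) * stride, (i + 0.5) * stride)`` in image coordinates.
    """
    if feature_map_height <= 0 or feature_map_width <= 0:
        raise ValueError("feature map dimensions must be positive")
    shapes = []
    for s in cfg.scales:
        for r in cfg.aspect_ratios:
            w = s * np.sqrt(r)
            h = s / np.sqrt(r)
            shapes.append((w, h))
    shapes = np.asarray(shapes, dtype=float)  # (A, 2)

    ys = (np.arange(feature_map_height) + 0.5) * cfg.stride
    xs = (np.arange(feature_map_width) + 0.5) * cfg.stride
    cy, cx = np.meshgrid(ys, xs, indexing="ij")
    centers = np.stack([cx.ravel(), cy.ravel()], axis=1)  # (H*W, 2)

    cxs = centers[:, None, 0]
    cys = centers[:, None, 1]
    ws = shapes[None, :, 0]
    hs = shapes[None, :, 1]
    anchors = np.stack(
        [cxs - ws / 2, cys - hs / 2, cxs + ws / 2, cys + hs / 2], axis=2)
    return anchors.reshape(-1, 4)


def box_areas(boxes: np.ndarray) -> np.ndarray:
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    return (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union, shape ``(len(a), len(b))``."""
    a = np.atleast_2d(np.asarray(boxes_a, dtype=float))
    b = np.atleast_2d(np.asarray(boxes_b, dtype=float))
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    union = box_areas(a)[:, None] + box_areas(b)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def iou(box_a, box_b) -> float:
    """IoU of two boxes under the half-open pixel convention."""
    return float(iou_matrix(box_a, box_b)[0, 0])


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list[int]:
    """Greedy non-maximum suppression.

    Boxes are visited in descending score order (ties broken by input
    order); a box is kept if its IoU with every already-kept box is below
    ``iou_threshold``.  Returns the kept indices in visit order.
    """
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    scores = np.asarray(scores, dtype=float)
    if len(boxes) != len(scores):
        raise ValueError("boxes and scores must have equal length")
    if len(boxes) == 0:
        return []
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for idx in order:
        if suppressed[idx]:
            continue
        keep.append(int(idx))
        ious = iou_matrix(boxes[idx], boxes)[0]
        suppressed |= ious >= iou_threshold
    return keep


def encode_box_deltas(boxes: np.ndarray, reference_boxes: np.ndarray) -> np.ndarray:
    """Parameterize ``boxes`` against ``reference_boxes``.

    Center offsets are normalized by the reference size and sizes are
    log-ratios: ``t = ((cx-cx_r)/w_r, (cy-cy_r)/h_r, ln(w/w_r), ln(h/h_r))``.
    """
    b = np.atleast_2d(np.asarray(boxes, dtype=float))
    r = np.atleast_2d(np.asarray(reference_boxes, dtype=float))
    rw = r[:, 2] - r[:, 0]
    rh = r[:, 3] - r[:, 1]
    if np.any(rw <= 0) or np.any(rh <= 0):
        raise ValueError("reference boxes must have positive width and height")
    bw = b[:, 2] - b[:, 0]
    bh = b[:, 3] - b[:, 1]
    tx = ((b[:, 0] + b[:, 2]) / 2 - (r[:, 0] + r[:, 2]) / 2) / rw
    ty = ((b[:, 1] + b[:, 3]) / 2 - (r[:, 1] + r[:, 3]) / 2) / rh
    tw = np.log(bw / rw)
    th = np.log(bh / rh)
    out = np.stack([tx, ty, tw, th], axis=1)
    return out[0] if np.asarray(boxes).ndim == 1 else out


def decode_box_deltas(deltas: np.ndarray, reference_boxes: np.ndarray) -> np.ndarray:
    """Invert :func:`encode_box_deltas`."""
    t = np.atleast_2d(np.asarray(deltas, dtype=float))
    r = np.atleast_2d(np.asarray(reference_boxes, dtype=float))
    rw = r[:, 2] - r[:, 0]
    rh = r[:, 3] - r[:, 1]
    if np.any(rw <= 0) or np.any(rh <= 0):
        raise ValueError("reference boxes must have positive width and height")
    cx = (r[:, 0] + r[:, 2]) / 2 + t[:, 0] * rw
    cy = (r[:, 1] + r[:, 3]) / 2 + t[:, 1] * rh
    w = rw * np.exp(t[:, 2])
    h = rh * np.exp(t[:, 3])
    out = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)
    return out[0] if np.asarray(deltas).ndim == 1 else out


def clip_boxes(boxes: np.ndarray, height: int, width: int) -> np.ndarray:
    b = np.atleast_2d(np.asarray(boxes, dtype=float)).copy()
    b[:, 0::2] = np.clip(b[:, 0::2], 0, width)
    b[:, 1::2] = np.clip(b[:, 1::2], 0, height)
    return b


@dataclass
class TargetAssignment:
    """Per-box training targets produced by :func:`assign_targets`.

    ``labels``: region-class index (0 head, 1 upper_body, 2 background) or
    -1 for ignored boxes.  ``pose_labels`` carry the matched ground-truth
    pose index for foreground boxes, -1 otherwise.  ``deltas`` encode the
    matched box against each foreground box; rows for non-foreground boxes
    are zero.  ``matched_gt`` is the index of the claimed ground-truth box
    (-1 if none).
    """

    labels: np.ndarray
    pose_labels: np.ndarray
    deltas: np.ndarray
    matched_gt: np.ndarray
    max_ious: np.ndarray = field(default=None)


def assign_targets(boxes: np.ndarray,
                   gt_boxes: np.ndarray,
                   gt_region_labels: np.ndarray,
                   gt_pose_labels: np.ndarray,
                   iou_positive: float,
                   iou_negative: float) -> TargetAssignment:
    """Match candidate boxes to ground truth for training.

    A box with best IoU >= ``iou_positive`` takes the region class, pose
    label and encoded delta of its best ground-truth box; best IoU <=
    ``iou_negative`` makes it background; anything between is ignored
    (-1).  Additionally every ground-truth box claims its single best-IoU
    candidate even when that IoU is below the positive threshold, so no
    object goes unrepresented.
    """
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    n = len(boxes)
    labels = np.full(n, -1, dtype=int)
    pose_labels = np.full(n, -1, dtype=int)
    deltas = np.zeros((n, 4), dtype=float)
    matched = np.full(n, -1, dtype=int)
    gt_boxes = np.atleast_2d(np.asarray(gt_boxes, dtype=float))
    if gt_boxes.size == 0:
        labels[:] = BACKGROUND
        return TargetAssignment(labels, pose_labels, deltas, matched,
                                np.zeros(n))
    gt_region_labels = np.asarray(gt_region_labels, dtype=int)
    gt_pose_labels = np.asarray(gt_pose_labels, dtype=int)

    ious = iou_matrix(boxes, gt_boxes)
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(n), best_gt]

    labels[best_iou <= iou_negative] = BACKGROUND
    fg = best_iou >= iou_positive
    # every gt claims its best candidate, even below threshold
    for g in range(len(gt_boxes)):
        col = ious[:, g]
        top = col.max()
        if top > 0:
            claim = np.flatnonzero(col == top)
            fg[claim] = True
            best_gt[claim] = g
    labels[fg] = gt_region_labels[best_gt[fg]]
    pose_labels[fg] = gt_pose_labels[best_gt[fg]]
    matched[fg] = best_gt[fg]
    if fg.any():
        deltas[fg] = encode_box_deltas(gt_boxes[best_gt[fg]], boxes[fg])
    return TargetAssignment(labels, pose_labels, deltas, matched, best_iou)


def resize_for_network(image: np.ndarray,
                       shortest_side: int = 600,
                       longest_side_cap: int = 1000,
                       enforce: bool = True) -> tuple[np.ndarray, float]:
    """Rescale an image to the detector's input-size rule.

    The shortest side is brought to ``shortest_side`` preserving aspect
    ratio unless that would push the longest side past
    ``longest_side_cap``, in which case the longest side is pinned to the
    cap.  With ``enforce=False`` (test mode for small synthetic scenes)
    the image passes through untouched with scale 1.0.
    """
    image = np.asarray(image)
    if image.ndim < 2 or image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("image must be non-empty and 2-D")
    if not enforce:
        return image, 1.0
    h, w = image.shape[:2]
    scale = shortest_side / min(h, w)
    if max(h, w) * scale > longest_side_cap:
        scale = longest_side_cap / max(h, w)
    out_shape = (int(round(h * scale)), int(round(w * scale)))
    resized = _sk_resize(image.astype(float), out_shape, order=1,
                         anti_aliasing=scale < 1.0, preserve_range=True)
    return resized, scale
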