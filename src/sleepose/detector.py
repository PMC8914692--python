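"""Two-stage multi-task detector for in-sleep head / upper-body pose.

The network follows the classic two-stage recipe: a shared convolutional
backbone produces a stride-16 feature map; a region proposal network
(RPN) scores nine anchors per location (three areas x three aspect
ratios) and regresses box offsets; proposals are pooled to a fixed grid
(RoI max pooling), refined through a residual block and average pooling,
and fed to three sibling heads:

* region classification (head / upper-body / background) + per-class
  box regression,
* head-pose classification (supine / prone / left / right),
* upper-body-pose classification (same four classes).

Training optimizes the weighted multi-task objective (region CE, two
masked pose CEs, smooth-L1 box loss) jointly with the RPN's own
objectness/regression losses, end to end with Adam and validation-based
early stopping.  Everything runs in numpy with hand-written gradients;
see :mod:`sleepose.nn`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import losses as L
from .backbones import STRIDE, get_backbone
from .boxes import (POSE_CLASSES, REGION_CLASSES, AnchorConfig,
                    TargetAssignment, assign_targets, clip_boxes,
                    decode_box_deltas, encode_box_deltas, generate_anchors,
                    nms, resize_for_network)
from .losses import LossWeights
from .nn import (Adam, Conv2d, GlobalAvgPool, Linear, ReLU, ResidualBlock,
                 softmax)

logger = logging.getLogger(__name__)

N_REGION = 3
N_POSE = 4
N_FG = 2  # head, upper_body


@dataclass(frozen=True)
class Detection:
    """One localized region with class and pose scores."""

    box: tuple[float, float, float, float]
    region_class: str
    region_score: float
    pose_class: str | None
    pose_score: float | None


@dataclass(frozen=True)
class DetectorConfig:
    backbone: str = "paper_resnet50"
    anchor: AnchorConfig = field(default_factory=AnchorConfig)
    rpn_channels: int = 512
    rpn_positive_iou: float = 0.7
    rpn_negative_iou: float = 0.3
    rpn_nms_threshold: float = 0.7
    rpn_pre_nms_top_n: int = 2000
    rpn_post_nms_top_n: int = 64
    rpn_batch: int = 64
    roi_output_size: int = 14
    roi_channels: int = 64
    fg_iou: float = 0.5
    rois_per_image: int = 64
    fg_fraction: float = 0.5
    detection_nms_threshold: float = 0.3
    score_threshold: float = 0.5
    resize_shortest: int = 600
    resize_longest: int = 1000
    resize_enforce: bool = True


def tiny_detector_config(**overrides) -> DetectorConfig:
    """Desk-scale configuration matched to the 96-px synthetic scenes."""
    base = dict(
        backbone="tiny_test",
        anchor=AnchorConfig(scales=(20.0, 32.0, 44.0),
                            aspect_ratios=(1.0, 0.5, 2.0), stride=STRIDE),
        rpn_channels=128,
        rpn_pre_nms_top_n=128,
        rpn_post_nms_top_n=12,
        rpn_batch=64,
        roi_output_size=6,
        roi_channels=32,
        rois_per_image=20,
        detection_nms_threshold=0.15,
        resize_enforce=False,
    )
    base.update(overrides)
    return DetectorConfig(**base)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    patience: int = 5
    max_epochs: int = 50
    batch_size: int = 1
    seed: int = 0
    backbone: str = "paper_resnet50"
    augment: bool = False
    lr_step_epoch: int | None = None  # halve-style step decay, optional
    lr_step_factor: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0 or self.max_epochs <= 0 \
                or self.patience <= 0 or self.batch_size <= 0:
            raise ValueError("training hyperparameters must be positive")


def tiny_train_config(seed: int = 0, **overrides) -> TrainConfig:
    base = dict(learning_rate=2e-3, patience=3, max_epochs=12, seed=seed,
                backbone="tiny_test", lr_step_epoch=7, lr_step_factor=0.3)
    base.update(overrides)
    return TrainConfig(**base)


# ---------------------------------------------------------------------------
# RoI max pooling (standalone, oracle-testable)

def roi_max_pool(feature_map: np.ndarray, boxes, stride: int,
                 output_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Max-pool each box's projected feature window to a fixed grid.

    ``feature_map`` is ``(C, Hf, Wf)``; boxes are image-coordinate
    ``(x0, y0, x1, y1)``.  Each output cell takes the max over the
    feature cells its fractional sub-window overlaps.  Boxes projecting
    to less than one cell fall back to the nearest cell.  Returns
    ``(pooled (R, C, S, S), argmax flat indices into Hf*Wf)`` — the
    indices drive the backward pass.
    """
    c, fh, fw = feature_map.shape
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    S = output_size
    pooled = np.empty((len(boxes), c, S, S))
    argflat = np.empty((len(boxes), c, S, S), dtype=np.int64)
    degenerate = False
    for b, (x0, y0, x1, y1) in enumerate(boxes):
        gx0 = np.clip(x0 / stride, 0, fw)
        gx1 = np.clip(x1 / stride, 0, fw)
        gy0 = np.clip(y0 / stride, 0, fh)
        gy1 = np.clip(y1 / stride, 0, fh)
        if gx1 - gx0 < 1e-9 or gy1 - gy0 < 1e-9:
            degenerate = True
            gx0 = min(gx0, fw - 1e-3)
            gy0 = min(gy0, fh - 1e-3)
            gx1 = gx0 + 1e-3
            gy1 = gy0 + 1e-3
        col_edges = np.linspace(gx0, gx1, S + 1)
        row_edges = np.linspace(gy0, gy1, S + 1)
        r0s = np.clip(np.floor(row_edges[:-1]).astype(int), 0, fh - 1)
        r1s = np.clip(np.ceil(row_edges[1:]).astype(int), 1, fh)
        r1s = np.maximum(r1s, r0s + 1)
        c0s = np.clip(np.floor(col_edges[:-1]).astype(int), 0, fw - 1)
        c1s = np.clip(np.ceil(col_edges[1:]).astype(int), 1, fw)
        c1s = np.maximum(c1s, c0s + 1)
        for i in range(S):
            r0, r1 = r0s[i], r1s[i]
            for j in range(S):
                c0, c1 = c0s[j], c1s[j]
                win = feature_map[:, r0:r1, c0:c1].reshape(c, -1)
                a = win.argmax(axis=1)
                pooled[b, :, i, j] = win[np.arange(c), a]
                rows = r0 + a // (c1 - c0)
                cols = c0 + a % (c1 - c0)
                argflat[b, :, i, j] = rows * fw + cols
    if degenerate:
        logger.warning("degenerate RoI projected to <1 feature cell; "
                       "nearest-cell fallback used")
    return pooled, argflat


class _RoIPool:
    """Stateful wrapper around :func:`roi_max_pool` for backprop."""

    def __init__(self, stride: int, output_size: int):
        self.stride = stride
        self.output_size = output_size

    def forward(self, feature_map: np.ndarray, boxes) -> np.ndarray:
        self._shape = feature_map.shape
        pooled, self._argflat = roi_max_pool(feature_map, boxes, self.stride,
                                             self.output_size)
        return pooled

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, fh, fw = self._shape
        dflat = np.zeros((c, fh * fw))
        ch = np.broadcast_to(np.arange(c)[None, :, None, None],
                             dout.shape).ravel()
        np.add.at(dflat, (ch, self._argflat.ravel()), dout.ravel())
        return dflat.reshape(self._shape)


# ---------------------------------------------------------------------------


class MultiTaskDetector:
    """The shared-backbone detector with its three sibling heads."""

    def __init__(self, cfg: DetectorConfig | None = None,
                 seed: int = 0):
        self.cfg = cfg or DetectorConfig()
        rng = np.random.default_rng(seed)
        self.backbone = get_backbone(self.cfg.backbone, rng)
        cch = self.backbone.out_channels
        A = self.cfg.anchor.anchors_per_location
        self.rpn_conv = Conv2d(cch, self.cfg.rpn_channels, 3, rng)
        self.rpn_relu = ReLU()
        self.rpn_cls = Conv2d(self.cfg.rpn_channels, 2 * A, 1, rng)
        self.rpn_reg = Conv2d(self.cfg.rpn_channels, 4 * A, 1, rng)
        rch = self.cfg.roi_channels
        self.roi_reduce = Conv2d(cch, rch, 1, rng)
        self.roi_relu = ReLU()
        self.roi_block = ResidualBlock(rch, rng)
        self.gap = GlobalAvgPool()
        self.roi_pool = _RoIPool(self.cfg.anchor.stride,
                                 self.cfg.roi_output_size)
        self.fc_det = Linear(rch, N_REGION, rng)
        self.fc_reg = Linear(rch, N_FG * 4, rng)
        self.fc_head_pose = Linear(rch, N_POSE, rng)
        self.fc_body_pose = Linear(rch, N_POSE, rng)
        self._head_modules = (self.rpn_conv, self.rpn_cls, self.rpn_reg,
                              self.roi_reduce, self.roi_block, self.fc_det,
                              self.fc_reg, self.fc_head_pose,
                              self.fc_body_pose)

    # -- parameters --------------------------------------------------------
    def params(self):
        out = list(self.backbone.params())
        for m in self._head_modules:
            out.extend(m.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w

    # -- forward pieces ----------------------------------------------------
    def extract_features(self, image: np.ndarray) -> np.ndarray:
        """Stride-16 convolutional feature map for a grayscale image."""
        image = np.asarray(image, dtype=float)
        if image.ndim == 3:
            image = image @ np.array([0.299, 0.587, 0.114])
        h, w = image.shape
        if min(h, w) < self.cfg.anchor.stride:
            raise ValueError("image smaller than the feature stride")
        x = image[None, None] / 255.0 - 0.25
        return self.backbone(x)

    def _rpn_maps(self, feat: np.ndarray):
        mid = self.rpn_relu(self.rpn_conv(feat))
        cls_map = self.rpn_cls(mid)
        reg_map = self.rpn_reg(mid)
        A = self.cfg.anchor.anchors_per_location
        _, _, fh, fw = cls_map.shape
        cls_logits = cls_map[0].transpose(1, 2, 0).reshape(fh * fw * A, 2)
        reg = reg_map[0].transpose(1, 2, 0).reshape(fh * fw * A, 4)
        return cls_logits, reg, (fh, fw)

    def rpn_propose(self, feat: np.ndarray, image_shape,
                    max_proposals: int | None = None):
        """Scored, clipped, NMS-pruned proposals sorted by objectness.

        Returns ``(proposals (P, 4), scores (P,), rpn_internals)`` where
        the internals carry the raw per-anchor logits for training.
        """
        cls_logits, reg, (fh, fw) = self._rpn_maps(feat)
        anchors = generate_anchors(fh, fw, self.cfg.anchor)
        obj = softmax(cls_logits, axis=1)[:, 1]
        decoded = decode_box_deltas(reg, anchors)
        decoded = clip_boxes(decoded, image_shape[0], image_shape[1])
        # drop proposals collapsing below one pixel after clipping
        valid = ((decoded[:, 2] - decoded[:, 0] >= 1.0) &
                 (decoded[:, 3] - decoded[:, 1] >= 1.0))
        obj = np.where(valid, obj, -np.inf)
        order = np.argsort(-obj, kind="stable")[:self.cfg.rpn_pre_nms_top_n]
        order = order[np.isfinite(obj[order])]
        keep = nms(decoded[order], obj[order], self.cfg.rpn_nms_threshold)
        top = max_proposals or self.cfg.rpn_post_nms_top_n
        keep = np.asarray(keep[:top], dtype=int)
        sel = order[keep] if len(keep) else keep
        internals = {"cls_logits": cls_logits, "reg": reg,
                     "anchors": anchors, "shape": (fh, fw)}
        return decoded[sel], obj[sel], internals

    def roi_extract(self, feat: np.ndarray, boxes) -> np.ndarray:
        """Pooled, residual-refined, average-pooled per-region features."""
        pooled = self.roi_pool.forward(feat[0], boxes)
        z = self.roi_relu(self.roi_reduce(pooled))
        z = self.roi_block(z)
        return self.gap(z)

    def _roi_backward(self, dvec: np.ndarray) -> np.ndarray:
        d = self.gap.backward(dvec)
        d = self.roi_block.backward(d)
        d = self.roi_reduce.backward(self.roi_relu.backward(d))
        return self.roi_pool.backward(d)[None]

    def detect(self, roi_feats: np.ndarray):
        """Region-class softmax scores (R, 3) and per-class deltas (R, 2, 4)."""
        logits = self.fc_det(roi_feats)
        reg = self.fc_reg(roi_feats).reshape(-1, N_FG, 4)
        return softmax(logits, axis=1), reg, logits

    def classify_poses(self, roi_feats: np.ndarray):
        """Two independent four-way softmax score vectors per region."""
        hl = self.fc_head_pose(roi_feats)
        bl = self.fc_body_pose(roi_feats)
        return softmax(hl, axis=1), softmax(bl, axis=1), hl, bl

    # -- inference ---------------------------------------------------------
    def predict_frame(self, image: np.ndarray,
                      score_threshold: float | None = None,
                      nms_threshold: float | None = None,
                      max_proposals: int = 32) -> list[Detection]:
        """Full forward pass to a pruned list of detections.

        Background regions are discarded, surviving boxes are refined by
        the class-specific regression and pruned per class by NMS; the
        pose label of a detection is read from the pose head matching
        its region class.
        """
        cfg = self.cfg
        score_threshold = cfg.score_threshold if score_threshold is None \
            else score_threshold
        nms_threshold = cfg.detection_nms_threshold if nms_threshold is None \
            else nms_threshold
        image = np.asarray(image, dtype=float)
        resized, scale = resize_for_network(
            image, cfg.resize_shortest, cfg.resize_longest,
            enforce=cfg.resize_enforce)
        feat = self.extract_features(resized)
        proposals, _, _ = self.rpn_propose(feat, resized.shape,
                                           max_proposals=max_proposals)
        if len(proposals) == 0:
            return []
        roi_feats = self.roi_extract(feat, proposals)
        det_scores, reg, _ = self.detect(roi_feats)
        head_scores, body_scores, _, _ = self.classify_poses(roi_feats)

        detections: list[Detection] = []
        for k in range(N_FG):
            cls_scores = det_scores[:, k]
            mask = (det_scores.argmax(axis=1) == k) & \
                (cls_scores >= score_threshold)
            if not mask.any():
                continue
            idx = np.flatnonzero(mask)
            refined = decode_box_deltas(reg[idx, k], proposals[idx])
            refined = clip_boxes(refined, resized.shape[0], resized.shape[1])
            keep = nms(refined, cls_scores[idx], nms_threshold)
            pose_scores = head_scores if k == 0 else body_scores
            for j in keep:
                i = idx[j]
                pose_idx = int(pose_scores[i].argmax())
                detections.append(Detection(
                    box=tuple(refined[j] / scale),
                    region_class=REGION_CLASSES[k],
                    region_score=float(cls_scores[i]),
                    pose_class=POSE_CLASSES[pose_idx],
                    pose_score=float(pose_scores[i, pose_idx])))
        detections.sort(key=lambda d: -d.region_score)
        return detections

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Self-describing checkpoint: config + class order + parameters."""
        meta = {
            "config": _config_to_dict(self.cfg),
            "region_classes": list(REGION_CLASSES),
            "pose_classes": list(POSE_CLASSES),
        }
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "MultiTaskDetector":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            cfg = _config_from_dict(meta["config"])
            model = cls(cfg, seed=0)
            params = model.params()
            for i, p in enumerate(params):
                p.value[...] = data[f"param_{i}"]
        return model


def _config_to_dict(cfg: DetectorConfig) -> dict:
    d = asdict(cfg)
    d["anchor"] = asdict(cfg.anchor)
    return d


def _config_from_dict(d: dict) -> DetectorConfig:
    d = dict(d)
    a = d.pop("anchor")
    anchor = AnchorConfig(scales=tuple(a["scales"]),
                          aspect_ratios=tuple(a["aspect_ratios"]),
                          stride=a["stride"])
    return DetectorConfig(anchor=anchor, **d)


# ---------------------------------------------------------------------------
# training


def sample_to_targets(sample):
    """Ground-truth arrays (boxes, region idx, pose idx) from a SceneSample
    or any object with a compatible ``annotations`` list."""
    boxes, regions, poses = [], [], []
    for ann in sample.annotations:
        boxes.append(ann.box)
        regions.append(REGION_CLASSES.index(ann.region_class))
        poses.append(POSE_CLASSES.index(ann.pose_class))
    return (np.asarray(boxes, dtype=float), np.asarray(regions),
            np.asarray(poses))


def _sample_rois(assign: TargetAssignment, n_rois: int, fg_fraction: float,
                 rng: np.random.Generator | None) -> np.ndarray:
    fg = np.flatnonzero(assign.labels < N_FG)
    bg = np.flatnonzero(assign.labels == N_FG)
    if rng is None:
        return np.concatenate([fg, bg])[:n_rois]
    n_fg = min(len(fg), int(round(n_rois * fg_fraction)))
    n_bg = min(len(bg), n_rois - n_fg)
    sel_fg = rng.choice(fg, size=n_fg, replace=False) if n_fg else fg[:0]
    sel_bg = rng.choice(bg, size=n_bg, replace=False) if n_bg else bg[:0]
    return np.concatenate([sel_fg, sel_bg])


def _sample_rpn_anchors(labels: np.ndarray, batch: int,
                        rng: np.random.Generator | None) -> np.ndarray:
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if rng is None:
        return np.concatenate([pos, neg])
    n_pos = min(len(pos), batch // 2)
    n_neg = min(len(neg), batch - n_pos)
    sel_p = rng.choice(pos, size=n_pos, replace=False) if n_pos else pos[:0]
    sel_n = rng.choice(neg, size=n_neg, replace=False) if n_neg else neg[:0]
    return np.concatenate([sel_p, sel_n])


class _StepResult:
    __slots__ = ("breakdown", "rpn_cls", "rpn_box", "total")

    def __init__(self, breakdown, rpn_cls, rpn_box):
        self.breakdown = breakdown
        self.rpn_cls = rpn_cls
        self.rpn_box = rpn_box
        self.total = breakdown.L_total + rpn_cls + rpn_box


def _forward_loss(model: MultiTaskDetector, image, gt_boxes, gt_regions,
                  gt_poses, weights: LossWeights,
                  rng: np.random.Generator | None,
                  compute_grads: bool,
                  rois_override: np.ndarray | None = None) -> _StepResult:
    """One image's losses; with ``compute_grads`` the parameter gradients
    are accumulated (caller zeroes them).

    Box coordinates of proposals are treated as constants (approximate
    joint training): gradients flow into the RPN through its own losses,
    not through the pooled windows.  ``rois_override`` replaces the
    proposal+ground-truth RoI set (used by gradient-check tests, where
    the RoIs must not move under weight perturbation).
    """
    cfg = model.cfg
    feat = model.extract_features(image)
    image_shape = np.asarray(image).shape[:2]
    proposals, _, internals = model.rpn_propose(feat, image_shape)
    anchors = internals["anchors"]

    # RPN targets: binary objectness on anchors
    a_assign = assign_targets(anchors, gt_boxes, gt_regions, gt_poses,
                              cfg.rpn_positive_iou, cfg.rpn_negative_iou)
    rpn_labels = np.where(a_assign.labels < 0, -1,
                          (a_assign.labels < N_FG).astype(int))
    rpn_sel = _sample_rpn_anchors(rpn_labels, cfg.rpn_batch, rng)
    cls_logits = internals["cls_logits"]
    rpn_probs = softmax(cls_logits[rpn_sel], axis=1)
    rpn_cls_loss = float(-np.log(np.clip(
        rpn_probs[np.arange(len(rpn_sel)), rpn_labels[rpn_sel]],
        L._EPS, None)).mean()) if len(rpn_sel) else 0.0
    pos_sel = rpn_sel[rpn_labels[rpn_sel] == 1]
    if len(pos_sel):
        rpn_diff = internals["reg"][pos_sel] - a_assign.deltas[pos_sel]
        rpn_box_loss = float(L.smooth_l1(rpn_diff).sum(axis=1).mean())
    else:
        rpn_box_loss = 0.0

    # second stage on proposals + ground truth (plus, while training,
    # jittered ground-truth boxes: mild jitters give well-overlapping
    # foreground for regression, strong jitters land as hard negatives)
    if rois_override is not None:
        rois = np.asarray(rois_override, dtype=float)
    elif len(gt_boxes):
        extra = [proposals, gt_boxes]
        if rng is not None:
            for magnitude in (0.1, 0.25, 0.5):
                g = gt_boxes.copy()
                sizes = np.stack([g[:, 2] - g[:, 0], g[:, 3] - g[:, 1],
                                  g[:, 2] - g[:, 0], g[:, 3] - g[:, 1]],
                                 axis=1)
                g = g + rng.uniform(-magnitude, magnitude,
                                    size=g.shape) * sizes
                extra.append(clip_boxes(g, image_shape[0], image_shape[1]))
        rois = np.vstack(extra)
        rois = rois[(rois[:, 2] - rois[:, 0] >= 1) &
                    (rois[:, 3] - rois[:, 1] >= 1)]
    else:
        rois = proposals
    r_assign = assign_targets(rois, gt_boxes, gt_regions, gt_poses,
                              cfg.fg_iou, cfg.fg_iou)
    sel = _sample_rois(r_assign, cfg.rois_per_image, cfg.fg_fraction, rng)
    rois = rois[sel]
    labels = r_assign.labels[sel]
    pose_labels = r_assign.pose_labels[sel]
    delta_targets = r_assign.deltas[sel]
    R = len(rois)

    roi_feats = model.roi_extract(feat, rois)
    det_scores, reg, det_logits = model.detect(roi_feats)
    head_scores, body_scores, head_logits, body_logits = \
        model.classify_poses(roi_feats)

    L_class = L.loss_detection_class(labels, det_scores)
    L_head = L.loss_head_pose(labels, pose_labels, head_scores)
    L_body = L.loss_body_pose(labels, pose_labels, body_scores)
    fg_rows = np.flatnonzero(labels < N_FG)
    if len(fg_rows):
        pred_fg = reg[fg_rows, labels[fg_rows]]
        L_box = L.loss_box_regression(pred_fg, delta_targets[fg_rows])
    else:
        L_box = 0.0
    breakdown = L.total_loss(L_class, L_head, L_body, L_box, weights)
    result = _StepResult(breakdown, rpn_cls_loss, rpn_box_loss)
    if not compute_grads:
        return result

    # ---- gradients -------------------------------------------------------
    onehot = np.eye(N_REGION)[labels]
    d_det_logits = (det_scores - onehot) / R * weights.lambda_class

    d_reg = np.zeros_like(reg)
    if len(fg_rows) and weights.lambda_box > 0:
        diff = reg[fg_rows, labels[fg_rows]] - delta_targets[fg_rows]
        d_reg[fg_rows, labels[fg_rows]] = \
            L.smooth_l1_grad(diff) / len(fg_rows) * weights.lambda_box

    def pose_grad(logits, scores, region_idx, lam):
        d = np.zeros_like(logits)
        rows = np.flatnonzero(labels == region_idx)
        if len(rows) and lam > 0:
            oh = np.eye(N_POSE)[pose_labels[rows]]
            d[rows] = (scores[rows] - oh) / len(rows) * lam
        return d

    d_head = pose_grad(head_logits, head_scores, 0, weights.lambda_head)
    d_body = pose_grad(body_logits, body_scores, 1, weights.lambda_body)

    dvec = model.fc_det.backward(d_det_logits)
    dvec = dvec + model.fc_reg.backward(d_reg.reshape(R, -1))
    dvec = dvec + model.fc_head_pose.backward(d_head)
    dvec = dvec + model.fc_body_pose.backward(d_body)
    dfeat = model._roi_backward(dvec)

    # RPN gradients
    d_cls = np.zeros_like(cls_logits)
    if len(rpn_sel):
        oh = np.eye(2)[rpn_labels[rpn_sel]]
        d_cls[rpn_sel] = (rpn_probs - oh) / len(rpn_sel)
    d_reg_map = np.zeros_like(internals["reg"])
    if len(pos_sel):
        d_reg_map[pos_sel] = L.smooth_l1_grad(rpn_diff) / len(pos_sel)
    fh, fw = internals["shape"]
    A = cfg.anchor.anchors_per_location
    d_cls_map = d_cls.reshape(fh, fw, 2 * A).transpose(2, 0, 1)[None]
    d_reg_map = d_reg_map.reshape(fh, fw, 4 * A).transpose(2, 0, 1)[None]
    dmid = model.rpn_cls.backward(d_cls_map) + \
        model.rpn_reg.backward(d_reg_map)
    dfeat = dfeat + model.rpn_conv.backward(model.rpn_relu.backward(dmid))

    model.backbone.backward(dfeat)
    return result


def train(train_set, val_set, cfg: TrainConfig | None = None,
          det_cfg: DetectorConfig | None = None,
          weights: LossWeights | None = None,
          augmenter=None) -> tuple[MultiTaskDetector, pd.DataFrame]:
    """End-to-end joint training with validation-based early stopping.

    Parameters
    ----------
    train_set, val_set
        Sequences of annotated samples (``SceneSample`` or compatible).
    cfg
        Optimizer / schedule settings.  Training stops once the
        validation total loss has not improved for ``cfg.patience``
        epochs; the best-validation parameters are restored.
    det_cfg
        Network architecture; defaults to the tiny desk-scale preset
        when ``cfg.backbone`` is ``tiny_test``.
    weights
        The four task-loss weights (default all 1).

    Returns the fitted model and a per-epoch loss history.
    """
    cfg = cfg or TrainConfig()
    if det_cfg is None:
        det_cfg = tiny_detector_config() if cfg.backbone == "tiny_test" \
            else DetectorConfig()
    if det_cfg.backbone != cfg.backbone:
        det_cfg = replace(det_cfg, backbone=cfg.backbone)
    weights = weights or LossWeights()
    if not len(train_set) or not len(val_set):
        raise ValueError("training and validation sets must be nonempty")
    if augmenter is None and cfg.augment:
        from .augment import AugmentationRejected, augment_sample

        def augmenter(sample, rng):
            try:
                return augment_sample(sample, rng)
            except AugmentationRejected:
                return sample  # keep the unaugmented sample

    rng = np.random.default_rng(cfg.seed)
    model = MultiTaskDetector(det_cfg, seed=cfg.seed)
    optimizer = Adam(model.params(), lr=cfg.learning_rate)

    targets = [sample_to_targets(s) for s in train_set]
    val_targets = [sample_to_targets(s) for s in val_set]

    history = []
    best_val = np.inf
    best_weights = model.get_weights()
    wait = 0
    for epoch in range(cfg.max_epochs):
        if cfg.lr_step_epoch is not None and epoch == cfg.lr_step_epoch:
            optimizer.lr *= cfg.lr_step_factor
        order = rng.permutation(len(train_set))
        tr_totals, tr_parts = [], np.zeros(4)
        for i in order:
            sample = train_set[i]
            image, (gt_boxes, gt_regions, gt_poses) = sample.image, targets[i]
            if augmenter is not None:
                sample_aug = augmenter(sample, rng)
                image = sample_aug.image
                gt_boxes, gt_regions, gt_poses = sample_to_targets(sample_aug)
            optimizer.zero_grad()
            res = _forward_loss(model, image, gt_boxes, gt_regions, gt_poses,
                                weights, rng, compute_grads=True)
            if not np.isfinite(res.total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={res.total}")
            optimizer.step()
            tr_totals.append(res.total)
            tr_parts += (res.breakdown.L_class, res.breakdown.L_head,
                         res.breakdown.L_body, res.breakdown.L_box)
        val_totals = []
        for s, (gb, gr, gp) in zip(val_set, val_targets):
            res = _forward_loss(model, s.image, gb, gr, gp, weights,
                                rng=None, compute_grads=False)
            val_totals.append(res.total)
        val_loss = float(np.mean(val_totals))
        parts = tr_parts / len(train_set)
        history.append({
            "epoch": epoch, "train_total": float(np.mean(tr_totals)),
            "val_total": val_loss, "L_class": parts[0], "L_head": parts[1],
            "L_body": parts[2], "L_box": parts[3]})
        logger.info("epoch %d train %.4f val %.4f", epoch,
                    history[-1]["train_total"], val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = model.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    model.set_weights(best_weights)
    return model, pd.DataFrame(history)
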