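"""Brute-force reference implementations used as independent oracles.

Everything here is written with explicit loops and set arithmetic,
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


# -- boxes ------------------------------------------------------------------

def iou_pixels(box_a, box_b) -> float:
    """IoU of integer boxes by rasterizing and counting pixels."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    cells_a = {(x, y) for x in range(ax0, ax1) for y in range(ay0, ay1)}
    cells_b = {(x, y) for x in range(bx0, bx1) for y in range(by0, by1)}
    union = cells_a | cells_b
    if not union:
        return 0.0
    return len(cells_a & cells_b) / len(union)


def iou_float(box_a, box_b) -> float:
    ix = min(box_a[2], box_b[2]) - max(box_a[0], box_b[0])
    iy = min(box_a[3], box_b[3]) - max(box_a[1], box_b[1])
    inter = max(ix, 0.0) * max(iy, 0.0)
    area_a = (box_a[2] - box_a[0]) * (box_a[3] - box_a[1])
    area_b = (box_b[2] - box_b[0]) * (box_b[3] - box_b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def nms_oracle(boxes, scores, threshold) -> list[int]:
    """Greedy suppression with explicit loops; ties broken by index."""
    order = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept = []
    for i in order:
        ok = True
        for j in kept:
            if iou_float(boxes[i], boxes[j]) >= threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept


def assign_oracle(boxes, gt_boxes, gt_labels, iou_pos, iou_neg,
                  background_label):
    """Exhaustive IoU-table target assignment (labels only)."""
    n, g = len(boxes), len(gt_boxes)
    table = [[iou_float(boxes[i], gt_boxes[j]) for j in range(g)]
             for i in range(n)]
    labels = [None] * n
    for i in range(n):
        best = max(range(g), key=lambda j: table[i][j])
        if table[i][best] >= iou_pos:
            labels[i] = gt_labels[best]
        elif table[i][best] <= iou_neg:
            labels[i] = background_label
    # each gt claims its best box (any nonzero overlap)
    for j in range(g):
        col = [table[i][j] for i in range(n)]
        top = max(col)
        if top > 0:
            for i in range(n):
                if col[i] == top:
                    labels[i] = gt_labels[j]
    return labels


# -- ViBe pixel classification ----------------------------------------------

def vibe_classify_oracle(frame, samples, radius, min_matches):
    """Per-pixel loop over the sample sets; 1 = foreground."""
    h, w = frame.shape
    out = np.zeros((h, w), dtype=np.uint8)
    n = samples.shape[0]
    for y in range(h):
        for x in range(w):
            count = 0
            for k in range(n):
                if abs(float(frame[y, x]) - float(samples[k, y, x])) < radius:
                    count += 1
            out[y, x] = 0 if count >= min_matches else 1
    return out


# -- morphology -------------------------------------------------------------

def _shifted_all(mask, k):
    """Erosion: pixel survives iff the whole k x k window is foreground
    (outside the image counts as background)."""
    h, w = mask.shape
    r = k // 2
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy in range(-r, k - r):
                for dx in range(-r, k - r):
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < h and 0 <= xx < w and mask[yy, xx]):
                        ok = False
                        break
                if not ok:
                    break
            out[y, x] = ok
    return out


def _shifted_any(mask, k):
    h, w = mask.shape
    r = k // 2
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            hit = False
            for dy in range(-r, k - r):
                for dx in range(-r, k - r):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                        hit = True
                        break
                if hit:
                    break
            out[y, x] = hit
    return out


def _components8(mask):
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                stack = [(y, x)]
                seen[y, x] = True
                comp = []
                while stack:
                    cy, cx = stack.pop()
                    comp.append((cy, cx))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = cy + dy, cx + dx
                            if 0 <= yy < h and 0 <= xx < w and \
                                    mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(comp)
    return comps


def _fill_holes(mask):
    """Background connected (4-conn) to the border stays; the rest fills."""
    h, w = mask.shape
    outside = np.zeros_like(mask, dtype=bool)
    stack = [(y, x) for y in range(h) for x in range(w)
             if (y in (0, h - 1) or x in (0, w - 1)) and not mask[y, x]]
    for y, x in stack:
        outside[y, x] = True
    while stack:
        cy, cx = stack.pop()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = cy + dy, cx + dx
            if 0 <= yy < h and 0 <= xx < w and not mask[yy, xx] \
                    and not outside[yy, xx]:
                outside[yy, xx] = True
                stack.append((yy, xx))
    return mask | ~outside


def clean_mask_oracle(mask, kernel_size, min_area):
    m = mask.astype(bool)
    m = _shifted_all(m, kernel_size)
    m = _shifted_any(m, kernel_size)
    for comp in _components8(m):
        if len(comp) < min_area:
            for y, x in comp:
                m[y, x] = False
    m = _fill_holes(m)
    return m.astype(np.uint8)


# -- RoI pooling ------------------------------------------------------------

def roi_pool_oracle(feature_map, box, stride, out_size):
    """Fractional-window max pooling with explicit loops."""
    c, fh, fw = feature_map.shape
    x0 = min(max(box[0] / stride, 0), fw)
    x1 = min(max(box[2] / stride, 0), fw)
    y0 = min(max(box[1] / stride, 0), fh)
    y1 = min(max(box[3] / stride, 0), fh)
    out = np.zeros((c, out_size, out_size))
    for i in range(out_size):
        r0 = int(np.floor(y0 + (y1 - y0) * i / out_size))
        r1 = int(np.ceil(y0 + (y1 - y0) * (i + 1) / out_size))
        r0 = min(max(r0, 0), fh - 1)
        r1 = min(max(r1, r0 + 1), fh)
        for j in range(out_size):
            c0 = int(np.floor(x0 + (x1 - x0) * j / out_size))
            c1 = int(np.ceil(x0 + (x1 - x0) * (j + 1) / out_size))
            c0 = min(max(c0, 0), fw - 1)
            c1 = min(max(c1, c0 + 1), fw)
            for ch in range(c):
                best = -np.inf
                for r in range(r0, r1):
                    for cc in range(c0, c1):
                        best = max(best, feature_map[ch, r, cc])
                out[ch, i, j] = best
    return out


# -- detection matching and AP ----------------------------------------------

def match_oracle(det_boxes, det_scores, det_classes, gt_boxes, gt_classes,
                 threshold):
    """Greedy matching with explicit loops; returns TP flags in the order
    of detections sorted by descending score (ties by input order)."""
    order = sorted(range(len(det_boxes)),
                   key=lambda i: (-det_scores[i], i))
    used = [False] * len(gt_boxes)
    flags = []
    for i in order:
        best_j, best_iou = -1, 0.0
        for j in range(len(gt_boxes)):
            if used[j] or gt_classes[j] != det_classes[i]:
                continue
            ov = iou_float(det_boxes[i], gt_boxes[j])
            if ov > best_iou:
                best_iou, best_j = ov, j
        if best_j >= 0 and best_iou >= threshold:
            flags.append(True)
            used[best_j] = True
        else:
            flags.append(False)
    return flags


def ap_oracle(tp_flags, scores, n_gt):
    """All-point AP: for every achieved recall level, the precision is
    the maximum over all operating points with at least that recall."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    flags = [bool(tp_flags[i]) for i in order]
    points = []  # (recall, precision) at every prefix
    tp = fp = 0
    for f in flags:
        tp += int(f)
        fp += int(not f)
        points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for r, _ in points:
        if r <= prev_r:
            continue
        best_p = max(p for rr, p in points if rr >= r)
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap
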