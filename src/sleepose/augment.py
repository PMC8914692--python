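"""Training-time augmentation: small rotations plus photometric jitter.

Images are rotated by a uniform random angle in [0, 15] degrees;
bounding boxes are replaced by the axis-aligned bounding box of their
rotated corners, clipped to the frame.  Contrast and brightness are
jittered within configurable ranges.  Labels never change.
"""

from __future__ import annotations

import logging
from dataclasses import replace as _replace

import numpy as np
from skimage.transform import rotate as _sk_rotate

logger = logging.getLogger(__name__)


class AugmentationRejected(ValueError):
    """Raised when a box rotates fully out of the frame."""


def rotate_box(box, angle_deg: float, center) -> np.ndarray:
    """Axis-aligned bounding box of a box's corners after rotation.

    The rotation is counterclockwise in image (x right, y down)
    coordinates about ``center``; this matches the image rotation
    applied by :func:`augment_sample`.
    """
    x0, y0, x1, y1 = box
    cx, cy = center
    th = np.deg2rad(angle_deg)
    # y grows downward, so a CCW rotation of content uses this matrix
    rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]], dtype=float)
    rotated = (corners - (cx, cy)) @ rot.T + (cx, cy)
    return np.array([rotated[:, 0].min(), rotated[:, 1].min(),
                     rotated[:, 0].max(), rotated[:, 1].max()])


def augment_sample(sample, seed_or_rng=0, max_angle: float = 15.0,
                   contrast_range: tuple[float, float] = (0.9, 1.1),
                   brightness_range: float = 10.0):
    """Return an augmented copy of an annotated sample.

    Raises :class:`AugmentationRejected` when a rotated box leaves the
    frame entirely (logged); callers should then draw a fresh sample.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    image = np.asarray(sample.image, dtype=float)
    h, w = image.shape[:2]
    angle = float(rng.uniform(0.0, max_angle))
    alpha = float(rng.uniform(*contrast_range))
    beta = float(rng.uniform(-brightness_range, brightness_range))

    if angle != 0.0:
        out = _sk_rotate(image, angle, center=((w - 1) / 2, (h - 1) / 2),
                         preserve_range=True, mode="edge")
    else:
        out = image.copy()
    out = np.clip(alpha * (out - 128.0) + 128.0 + beta, 0, 255)

    center = ((w - 1) / 2, (h - 1) / 2)
    new_annotations = []
    for ann in sample.annotations:
        rb = rotate_box(ann.box, angle, center)
        clipped = np.array([max(rb[0], 0), max(rb[1], 0),
                            min(rb[2], w), min(rb[3], h)])
        if clipped[2] - clipped[0] < 1 or clipped[3] - clipped[1] < 1:
            logger.warning("augmentation rotated a box out of frame; "
                           "sample rejected")
            raise AugmentationRejected("box left the frame under rotation")
        new_annotations.append(_replace(ann, box=tuple(clipped)))
    out_sample = type(sample)(image=out.astype(sample.image.dtype)
                              if np.issubdtype(np.asarray(sample.image).dtype,
                                               np.integer)
                              else out,
                              annotations=new_annotations)
    return out_sample
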