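"""Seeded synthetic bed scenes, motion videos and posture timelines.

Real overnight footage cannot ship with the package, so every stage is
exercised on generated data with exact ground truth.  A scene is a
grayscale bed image containing one rectangular upper-body blob and one
adjacent elliptical head blob.  Pose (supine / prone / left / right) is
encoded as the placement of a bright internal marker on the matching
side of each blob (top / bottom / left / right) — an unambiguous,
learnable stand-in for real body orientation.  A translucent
uniform-intensity rectangle over the lower body emulates blanket
coverage, and global brightness jitter emulates illumination changes.

All generators are pure functions of (spec, seed): the same spec and
seed reproduce bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .analysis import PostureEpisode, PostureTimeline
from .boxes import POSE_CLASSES

logger = logging.getLogger(__name__)

BODY_LEVEL = 140.0
HEAD_LEVEL = 175.0
BODY_MARKER_LEVEL = 215.0
HEAD_MARKER_LEVEL = 245.0
BLANKET_LEVEL = 105.0
BLANKET_ALPHA = 0.45  # blend weight of the blanket overlay

# pose -> which side of the blob carries the bright marker
_POSE_SIDE = {"supine": "top", "prone": "bottom", "left": "left",
              "right": "right"}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic bed scene."""

    image_height: int = 256
    image_width: int = 256
    background_level: float = 60.0
    noise_sd: float = 4.0
    head_size_range: tuple[int, int] = (28, 40)
    body_size_range: tuple[int, int] = (96, 140)
    occlusion_fraction: float = 0.3
    brightness_jitter: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        for lo, hi in (self.head_size_range, self.body_size_range):
            if lo <= 0 or hi < lo:
                raise ValueError("size ranges must be positive and ordered")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.brightness_jitter < 0:
            raise ValueError("noise_sd and brightness_jitter must be >= 0")


def desk_spec(seed: int = 0, **overrides) -> SceneSpec:
    """96x96 scene preset used for CPU desk-scale training runs."""
    base = dict(image_height=96, image_width=96, head_size_range=(18, 24),
                body_size_range=(40, 54), seed=seed)
    base.update(overrides)
    return SceneSpec(**base)


@dataclass(frozen=True)
class Annotation:
    box: tuple[int, int, int, int]  # x_min, y_min, x_max, y_max; half-open
    region_class: str
    pose_class: str


@dataclass
class SceneSample:
    image: np.ndarray  # (H, W) uint8
    annotations: list[Annotation]

    def annotation_for(self, region_class: str) -> Annotation:
        return next(a for a in self.annotations
                    if a.region_class == region_class)


def _side_mask(h: int, w: int, side: str, fraction: float = 0.38) -> np.ndarray:
    mask = np.zeros((h, w), dtype=bool)
    if side == "top":
        mask[: max(1, int(round(h * fraction))), :] = True
    elif side == "bottom":
        mask[h - max(1, int(round(h * fraction))):, :] = True
    elif side == "left":
        mask[:, : max(1, int(round(w * fraction)))] = True
    else:
        mask[:, w - max(1, int(round(w * fraction))):] = True
    return mask


def _ellipse_mask(h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = h / 2.0, w / 2.0
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


@dataclass(frozen=True)
class _Geometry:
    head_box: tuple[int, int, int, int]
    body_box: tuple[int, int, int, int]


def _sample_geometry(spec: SceneSpec, rng: np.random.Generator) -> _Geometry:
    hs = int(rng.integers(spec.head_size_range[0],
                          spec.head_size_range[1] + 1))
    bh = int(rng.integers(spec.body_size_range[0],
                          spec.body_size_range[1] + 1))
    bw = max(4, int(round(bh * 0.62)))
    gap = 2
    total_h = hs + gap + bh
    margin = 3
    if total_h > spec.image_height - 2 * margin or \
            max(hs, bw) > spec.image_width - 2 * margin:
        raise ValueError(
            f"sampled blob sizes (head {hs}, body {bw}x{bh}) exceed the "
            f"{spec.image_height}x{spec.image_width} image bounds")
    y0 = int(rng.integers(margin, spec.image_height - total_h - margin + 1))
    x_body = int(rng.integers(margin, spec.image_width - bw - margin + 1))
    cx = x_body + bw // 2
    x_head = int(np.clip(cx - hs // 2, margin,
                         spec.image_width - hs - margin))
    head_box = (x_head, y0, x_head + hs, y0 + hs)
    body_box = (x_body, y0 + hs + gap, x_body + bw, y0 + hs + gap + bh)
    return _Geometry(head_box, body_box)


def _render(spec: SceneSpec, geometry: _Geometry, pose_head: str,
            pose_body: str, rng: np.random.Generator) -> SceneSample:
    for pose in (pose_head, pose_body):
        if pose not in POSE_CLASSES:
            raise ValueError(f"unknown pose class {pose!r}")
    h, w = spec.image_height, spec.image_width
    img = np.full((h, w), float(spec.background_level))

    bx0, by0, bx1, by1 = geometry.body_box
    img[by0:by1, bx0:bx1] = BODY_LEVEL
    bmark = _side_mask(by1 - by0, bx1 - bx0, _POSE_SIDE[pose_body])
    img[by0:by1, bx0:bx1][bmark] = BODY_MARKER_LEVEL

    hx0, hy0, hx1, hy1 = geometry.head_box
    ell = _ellipse_mask(hy1 - hy0, hx1 - hx0)
    patch = img[hy0:hy1, hx0:hx1]
    patch[ell] = HEAD_LEVEL
    hmark = ell & _side_mask(hy1 - hy0, hx1 - hx0, _POSE_SIDE[pose_head])
    patch[hmark] = HEAD_MARKER_LEVEL

    if spec.occlusion_fraction > 0:
        cover = int(round((by1 - by0) * spec.occlusion_fraction))
        if cover > 0:
            sl = (slice(by1 - cover, by1), slice(bx0, bx1))
            img[sl] = (1 - BLANKET_ALPHA) * img[sl] \
                + BLANKET_ALPHA * BLANKET_LEVEL

    if spec.brightness_jitter > 0:
        img += rng.uniform(-spec.brightness_jitter, spec.brightness_jitter)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    annotations = [
        Annotation(geometry.head_box, "head", pose_head),
        Annotation(geometry.body_box, "upper_body", pose_body),
    ]
    return SceneSample(img, annotations)


def generate_scene(spec: SceneSpec, pose_head: str, pose_body: str,
                   rng: np.random.Generator | None = None) -> SceneSample:
    """Render one annotated scene.

    The blob bounding boxes in the returned annotations match the
    rendered geometry exactly.  Without an explicit ``rng`` the output
    is a pure function of ``spec`` (including ``spec.seed``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return _render(spec, _sample_geometry(spec, rng), pose_head, pose_body,
                   rng)


@dataclass
class DatasetSplits:
    train: list[SceneSample]
    val: list[SceneSample]
    test: list[SceneSample]

    def __iter__(self):
        return iter((self.train, self.val, self.test))


def _split_sizes(n: int, fractions) -> list[int]:
    fractions = [float(f) for f in fractions]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    sizes = [int(np.floor(f * n)) for f in fractions]
    remainders = [f * n - s for f, s in zip(fractions, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1
    return sizes


def generate_dataset(spec: SceneSpec, n: int,
                     split_fractions=(0.8, 0.1, 0.1)) -> DatasetSplits:
    """Generate ``n`` scenes with cycled pose classes and stratified splits.

    Pose classes are cycled sample-by-sample (head and body share the
    sample's pose, as they usually do in real sleep), so every class
    appears ``n/4`` times up to rounding and contiguous slices of the
    cycled order stay class-balanced; the three splits are such slices
    and are therefore disjoint, exhaustive and stratified.
    """
    if n < len(POSE_CLASSES):
        raise ValueError(
            f"need at least {len(POSE_CLASSES)} samples, got {n}")
    rng = np.random.default_rng(spec.seed)
    samples = []
    for i in range(n):
        pose = POSE_CLASSES[i % len(POSE_CLASSES)]
        samples.append(generate_scene(spec, pose, pose, rng=rng))
    sizes = _split_sizes(n, split_fractions)
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplits(samples[:a], samples[a:b], samples[b:])


def generate_motion_video(spec: SceneSpec, n_frames: int, object_path
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Static noisy background plus a bright square moving along a path.

    ``object_path`` is a list of (x, y) top-left positions: empty for no
    object, a single position for a static object, otherwise one
    position per frame.  Positions that would push the object outside
    the frame are clipped (with a logged warning).  Returns
    ``(frames, masks)`` where ``masks`` are per-frame boolean ground
    truth of the object's support.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    path = list(object_path)
    if len(path) == 1:
        path = path * n_frames
    if path and len(path) != n_frames:
        raise ValueError("object_path length must equal n_frames")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    side = max(8, spec.head_size_range[0])
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    masks = np.zeros((n_frames, h, w), dtype=bool)
    clipped = False
    for t in range(n_frames):
        img = np.full((h, w), float(spec.background_level))
        if path:
            x, y = path[t]
            xc = int(np.clip(x, 0, w - side))
            yc = int(np.clip(y, 0, h - side))
            clipped |= (xc != x or yc != y)
            img[yc:yc + side, xc:xc + side] = 200.0
            masks[t, yc:yc + side, xc:xc + side] = True
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[t] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if clipped:
        logger.warning("object path left the frame and was clipped")
    return frames, masks


@dataclass(frozen=True)
class TimelineEpisodeSpec:
    head_pose: str
    body_pose: str
    duration_min: float
    wake_flag: bool = False


@dataclass(frozen=True)
class TimelineSpec:
    total_duration_min: float
    episodes: tuple[TimelineEpisodeSpec, ...]
    frame_interval_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.episodes:
            raise ValueError("timeline needs at least one episode")
        for e in self.episodes:
            if e.duration_min <= 0:
                raise ValueError("episode durations must be positive")
        if abs(sum(e.duration_min for e in self.episodes)
               - self.total_duration_min) > 1e-9:
            raise ValueError("episode durations must sum to total_duration")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass
class TimelineSample:
    """Ground-truth timeline plus its per-frame label sampling."""

    timeline: PostureTimeline
    frame_times: np.ndarray
    head_poses: list[str]
    body_poses: list[str]
    wake_flags: list[bool]


def generate_posture_timeline(spec: TimelineSpec) -> TimelineSample:
    """Expand an episode list into per-frame labels at frame_interval
    resolution, together with the exact ground-truth timeline."""
    episodes = []
    t = 0.0
    for e in spec.episodes:
        end = t + e.duration_min * 60.0
        episodes.append(PostureEpisode(t, end, e.head_pose, e.body_pose,
                                       e.wake_flag))
        t = end
    # merge accidental identical neighbours so the timeline is canonical
    merged: list[PostureEpisode] = []
    for ep in episodes:
        if merged and (merged[-1].head_pose, merged[-1].body_pose,
                       merged[-1].wake_flag) == (ep.head_pose, ep.body_pose,
                                                 ep.wake_flag):
            merged[-1] = PostureEpisode(merged[-1].start, ep.end, ep.head_pose,
                                        ep.body_pose, ep.wake_flag)
        else:
            merged.append(ep)
    timeline = PostureTimeline(merged)

    n_frames = int(spec.total_duration_min * 60.0 / spec.frame_interval_s)
    times = np.arange(n_frames) * spec.frame_interval_s
    bounds = np.array([e.end for e in merged])
    idx = np.searchsorted(bounds, times, side="right")
    idx = np.clip(idx, 0, len(merged) - 1)
    heads = [merged[i].head_pose for i in idx]
    bodies = [merged[i].body_pose for i in idx]
    wakes = [merged[i].wake_flag for i in idx]
    return TimelineSample(timeline, times, heads, bodies, wakes)


def generate_sleep_video(scene_spec: SceneSpec, timeline_spec: TimelineSpec,
                         fps: float = 1.0, transition_s: float = 8.0
                         ) -> tuple[np.ndarray, TimelineSample]:
    """Render a whole night as video frames following a posture timeline.

    Within an episode the subject's geometry is fixed (only sensor noise
    varies frame to frame).  Around each episode boundary the blobs
    slide from the old position to the new one over ``transition_s``
    seconds, producing genuine motion for the background-subtraction
    stage; the pose label switches at the boundary.
    """
    sample = generate_posture_timeline(timeline_spec)
    rng = np.random.default_rng(timeline_spec.seed)
    episodes = sample.timeline.episodes
    geos = []
    for _ in episodes:
        geos.append(_sample_geometry(scene_spec, rng))
    n_frames = int(round(sample.timeline.span_s * fps))
    frames = np.empty((n_frames, scene_spec.image_height,
                       scene_spec.image_width), dtype=np.uint8)
    bounds = np.array([e.end for e in episodes])
    for t in range(n_frames):
        time_s = t / fps
        i = int(np.clip(np.searchsorted(bounds, time_s, side="right"), 0,
                        len(episodes) - 1))
        geo = geos[i]
        if i + 1 < len(episodes):
            to_boundary = episodes[i].end - time_s
            if to_boundary < transition_s:
                frac = 1.0 - to_boundary / transition_s
                g0, g1 = geos[i], geos[i + 1]
                interp = tuple(
                    tuple(int(round((1 - frac) * a + frac * b))
                          for a, b in zip(b0, b1))
                    for b0, b1 in ((g0.head_box, g1.head_box),
                                   (g0.body_box, g1.body_box)))
                geo = _Geometry(*interp)
        frames[t] = _render(scene_spec, geo, episodes[i].head_pose,
                            episodes[i].body_pose, rng).image
    return frames, sample
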