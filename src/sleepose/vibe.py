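"""ViBe background subtraction and motion-event triggering.

ViBe keeps, for every pixel x, a set of N past intensity values
M(x) = {v1..vN}.  A pixel of the current frame is background when at
least ``min_matches`` stored samples lie within intensity distance R of
its current value; otherwise it is foreground (moving).  Background
pixels update their own sample set with probability 1/phi (the paper's
"1 chance in 16"), replacing a uniformly random sample, and - with the
classic spatial-diffusion rule enabled - also replace a random sample of
a random 8-neighbor.  Random replacement gives the model a long memory
so slow movers are still detected.

Cleaned foreground fractions above a trigger threshold define motion
events, which gate the (expensive) detector downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ViBeParams:
    """N samples per pixel, match radius R, #min matches, subsampling phi."""

    n_samples: int = 20
    match_radius: float = 20.0
    min_matches: int = 2
    update_subsampling: int = 16
    neighbor_update: bool = True

    def __post_init__(self):
        if not self.n_samples >= self.min_matches >= 1:
            raise ValueError("require n_samples >= min_matches >= 1")
        if self.match_radius <= 0:
            raise ValueError("match_radius must be positive")
        if self.update_subsampling < 1:
            raise ValueError("update_subsampling must be >= 1")


@dataclass
class BackgroundModel:
    """Per-pixel sample sets, stored as an (N, H, W) array."""

    samples: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self):
        if self.samples.shape[1:] != self.shape:
            raise ValueError("sample array does not match frame shape")


@dataclass(frozen=True)
class MotionEvent:
    start_frame: int
    end_frame: int  # inclusive
    peak_foreground_fraction: float

    def __post_init__(self):
        if self.end_frame < self.start_frame:
            raise ValueError("event must have start <= end")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def to_luminance(frame: np.ndarray) -> np.ndarray:
    """Collapse an RGB frame to ITU-R 601 luminance; pass grayscale through."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        return frame @ np.array([0.299, 0.587, 0.114])
    return frame


def equalize_histogram(frame: np.ndarray) -> np.ndarray:
    """Classic integer histogram equalization onto [0, 255].

    Adjusts image intensities so the output cumulative histogram is
    approximately uniform across varying bedroom lighting.  A frame with
    a single occupied bin is returned unchanged.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    lum = np.clip(np.round(to_luminance(frame)), 0, 255).astype(np.uint8)
    hist = np.bincount(lum.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    nonzero = np.flatnonzero(hist)
    cdf_min = cdf[nonzero[0]]
    total = lum.size
    if total == cdf_min:  # degenerate: one occupied bin
        return lum
    lut = np.round((cdf - cdf_min) / (total - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[lum]


_NEIGHBOR_OFFSETS = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
                              (1, -1), (1, 0), (1, 1)])


def init_background_model(first_frame: np.ndarray, params: ViBeParams,
                          seed: int | np.random.Generator = 0
                          ) -> BackgroundModel:
    """Fill each pixel's sample set from its 8-neighborhood in frame 0.

    Border pixels use clamped (edge-replicated) neighborhoods.
    """
    frame = to_luminance(first_frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    h, w = frame.shape
    padded = np.pad(frame, 1, mode="edge")
    shifted = np.stack([padded[1 + dy:1 + dy + h, 1 + dx:1 + dx + w]
                        for dy, dx in _NEIGHBOR_OFFSETS])  # (8, H, W)
    choice = rng.integers(0, 8, size=(params.n_samples, h, w))
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    samples = shifted[choice, rows[None], cols[None]].astype(float)
    return BackgroundModel(samples, (h, w))


def classify_frame(frame: np.ndarray, model: BackgroundModel,
                   params: ViBeParams) -> np.ndarray:
    """Per-pixel foreground/background decision.

    A pixel is background iff at least ``min_matches`` of its stored
    samples lie strictly within ``match_radius`` of its current value.
    Returns a uint8 mask with 1 = foreground (moving).
    """
    frame = to_luminance(frame)
    if frame.shape != model.shape:
        raise ValueError("frame shape does not match model")
    matches = (np.abs(model.samples - frame[None]) <
               params.match_radius).sum(axis=0)
    return (matches < params.min_matches).astype(np.uint8)


def update_background_model(frame: np.ndarray, mask: np.ndarray,
                            model: BackgroundModel, params: ViBeParams,
                            seed: int | np.random.Generator = 0
                            ) -> BackgroundModel:
    """Stochastic in-place model update; returns the (same) model.

    Each background-classified pixel is selected with probability
    1/``update_subsampling``; a selected pixel overwrites one uniformly
    random sample of its own set with its current value and, when
    ``neighbor_update`` is on, also one random sample of a uniformly
    random 8-neighbor (clamped at borders).  Colliding neighbor writes
    resolve arbitrarily (last write wins), which is unbiased on average.
    """
    frame = to_luminance(frame)
    mask = np.asarray(mask)
    if frame.shape != model.shape or mask.shape != model.shape:
        raise ValueError("shapes do not match model")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    h, w = model.shape
    background = mask == 0
    selected = background & (rng.random((h, w)) <
                             1.0 / params.update_subsampling)
    if not selected.any():
        return model
    rows, cols = np.nonzero(selected)
    vals = frame[rows, cols]
    sidx = rng.integers(0, params.n_samples, size=len(rows))
    model.samples[sidx, rows, cols] = vals
    if params.neighbor_update:
        off = _NEIGHBOR_OFFSETS[rng.integers(0, 8, size=len(rows))]
        nr = np.clip(rows + off[:, 0], 0, h - 1)
        nc = np.clip(cols + off[:, 1], 0, w - 1)
        sidx2 = rng.integers(0, params.n_samples, size=len(rows))
        model.samples[sidx2, nr, nc] = vals
    return model


def clean_mask(mask: np.ndarray, kernel_size: int = 3,
               min_area: float | None = None) -> np.ndarray:
    """Morphological cleanup of a binary motion mask.

    Erosion then dilation with a ``kernel_size`` square structuring
    element (outside-of-image treated as background), removal of
    connected components (8-connectivity) smaller than ``min_area``
    pixels, then interior hole filling.  ``min_area`` defaults to 0.1%
    of the frame area.
    """
    mask = np.asarray(mask)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must be binary (values 0/1)")
    if min_area is None:
        min_area = 0.001 * mask.size
    footprint = np.ones((kernel_size, kernel_size), dtype=bool)
    m = mask.astype(bool)
    m = ndimage.binary_erosion(m, structure=footprint)
    m = ndimage.binary_dilation(m, structure=footprint)
    labels, n = ndimage.label(m, structure=np.ones((3, 3)))
    if n:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area)
        small = small[small > 0]
        if len(small):
            m[np.isin(labels, small)] = False
    m = ndimage.binary_fill_holes(m)
    return m.astype(np.uint8)


def foreground_fraction(mask: np.ndarray) -> float:
    return float(np.asarray(mask, dtype=bool).mean())


def detect_motion_events(frames, params: ViBeParams | None = None,
                         trigger_fraction: float = 0.02,
                         min_event_frames: int = 3,
                         seed: int = 0,
                         equalize: bool = False,
                         kernel_size: int = 3,
                         min_area: float | None = None
                         ) -> list[MotionEvent]:
    """Run the full ViBe chain over a frame sequence and emit events.

    Per frame: (optional histogram equalization,) classification against
    the model, morphological cleanup, model update.  Frames whose
    cleaned foreground fraction reaches ``trigger_fraction`` form
    events; events shorter than ``min_event_frames`` are dropped.
    """
    fracs = motion_fractions(frames, params=params, seed=seed,
                             equalize=equalize, kernel_size=kernel_size,
                             min_area=min_area)
    return events_from_fractions(fracs, trigger_fraction, min_event_frames)


def motion_fractions(frames, params: ViBeParams | None = None, seed: int = 0,
                     equalize: bool = False, kernel_size: int = 3,
                     min_area: float | None = None,
                     mask_callback=None) -> np.ndarray:
    """Cleaned foreground fraction per frame (the event detector's core)."""
    if params is None:
        params = ViBeParams()
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(seed)
    fracs = np.zeros(len(frames))
    model = None
    for t, raw in enumerate(frames):
        f = to_luminance(raw)
        if equalize:
            f = equalize_histogram(f).astype(float)
        if model is None:
            model = init_background_model(f, params, rng)
        mask = classify_frame(f, model, params)
        cleaned = clean_mask(mask, kernel_size=kernel_size, min_area=min_area)
        fracs[t] = foreground_fraction(cleaned)
        if mask_callback is not None:
            mask_callback(t, cleaned)
        update_background_model(f, mask, model, params, rng)
    return fracs


def events_from_fractions(fracs: np.ndarray, trigger_fraction: float,
                          min_event_frames: int) -> list[MotionEvent]:
    active = np.asarray(fracs) >= trigger_fraction
    events: list[MotionEvent] = []
    start = None
    for t, flag in enumerate(active):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            events.append(MotionEvent(start, t - 1,
                                      float(np.max(fracs[start:t]))))
            start = None
    if start is not None:
        events.append(MotionEvent(start, len(active) - 1,
                                  float(np.max(fracs[start:]))))
    return [e for e in events if e.n_frames >= min_event_frames]
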