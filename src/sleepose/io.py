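"""File formats: frame sources, JSONL annotations/detections, CSV events."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detector import Detection
from .synthetic import Annotation, SceneSample
from .vibe import MotionEvent


def load_frames(path) -> np.ndarray:
    """Load a frame stack ``(T, H, W)`` from a directory of images, a
    ``.npy``/``.npz`` array, or any imageio-readable video/image file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff",
                                               ".jpg", ".jpeg"))
        if not files:
            raise FileNotFoundError(f"no image frames in {path}")
        frames = [np.asarray(iio.imread(f)) for f in files]
        return np.stack([f if f.ndim == 2 else
                         f @ np.array([0.299, 0.587, 0.114]) for f in frames])
    if path.suffix == ".npy":
        return np.load(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return data[list(data.keys())[0]]
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        return arr[None]
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # single RGB image
        return (arr[..., :3] @ np.array([0.299, 0.587, 0.114]))[None]
    return arr


def save_frames(frames: np.ndarray, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(frames):
        iio.imwrite(directory / f"frame_{t:06d}.png",
                    np.asarray(frame, dtype=np.uint8))


def save_dataset(samples, directory) -> None:
    """Images as PNG plus one JSONL annotation line per image."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    with open(directory / "annotations.jsonl", "w") as fh:
        for i, s in enumerate(samples):
            name = f"sample_{i:05d}.png"
            iio.imwrite(directory / "images" / name, s.image)
            fh.write(json.dumps({
                "image": name,
                "boxes": [list(map(float, a.box)) for a in s.annotations],
                "region_class": [a.region_class for a in s.annotations],
                "pose_class": [a.pose_class for a in s.annotations],
            }) + "\n")


def load_dataset(directory) -> list[SceneSample]:
    directory = Path(directory)
    ann_path = directory / "annotations.jsonl"
    if not ann_path.exists():
        raise FileNotFoundError(f"no annotations.jsonl under {directory}")
    samples = []
    with open(ann_path) as fh:
        for line in fh:
            rec = json.loads(line)
            img = np.asarray(iio.imread(directory / "images" / rec["image"]))
            anns = [Annotation(tuple(b), rc, pc) for b, rc, pc in
                    zip(rec["boxes"], rec["region_class"], rec["pose_class"])]
            samples.append(SceneSample(img, anns))
    if not samples:
        raise ValueError(f"dataset under {directory} is empty")
    return samples


def write_detections_jsonl(per_frame: dict[int, list[Detection]],
                           path) -> None:
    """``frame, region_class, pose_class, box, region_score, pose_score``
    JSON lines, one per detection."""
    with open(path, "w") as fh:
        for frame in sorted(per_frame):
            for d in per_frame[frame]:
                fh.write(json.dumps({
                    "frame": frame,
                    "region_class": d.region_class,
                    "pose_class": d.pose_class,
                    "box": [float(v) for v in d.box],
                    "region_score": float(d.region_score),
                    "pose_score": None if d.pose_score is None
                    else float(d.pose_score),
                }) + "\n")


def write_events_csv(events: list[MotionEvent], path) -> None:
    pd.DataFrame([{
        "start_frame": e.start_frame,
        "end_frame": e.end_frame,
        "peak_fraction": e.peak_foreground_fraction,
    } for e in events]).to_csv(path, index=False)
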