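"""End-to-end orchestration: video in, indicators and synopsis out.

The monitoring loop runs background subtraction over every frame,
invokes the (comparatively expensive) detector on every ``event_stride``-th
frame inside motion events and at a fixed sampling rate (default one
frame per second) during quiescence, then assembles the posture
timeline, indicator report, and the circular night synopsis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .analysis import (build_timeline, compute_indicators, render_synopsis,
                       timeline_to_csv)
from .detector import (DetectorConfig, MultiTaskDetector, TrainConfig,
                       sample_to_targets, tiny_detector_config,
                       tiny_train_config, train)
from .evaluation import (classification_accuracy, confusion_matrix,
                         mean_average_precision)
from .synthetic import SceneSpec, generate_dataset
from .vibe import ViBeParams, events_from_fractions, motion_fractions

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input: str | None = None
    checkpoint: str | None = None
    output_dir: str = "sleepose_out"
    fps: float = 1.0
    vibe: ViBeParams = field(default_factory=ViBeParams)
    trigger_fraction: float = 0.02
    min_event_frames: int = 3
    equalize: bool = False
    sample_interval_s: float = 1.0
    event_stride: int = 1
    score_threshold: float = 0.5
    nms_threshold: float | None = None  # None: use checkpoint setting
    smoothing_window: int = 5
    wake_min_event_s: float = 300.0
    min_motion_event_s: float = 10.0
    long_posture_min: float = 15.0
    dial_hours: float = 12.0
    seed: int = 0
    log_level: str = "INFO"
    # training / evaluation inputs
    dataset_dir: str | None = None
    eval_dir: str | None = None
    n_synthetic: int = 0
    scene: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    tiny: bool = True

    def __post_init__(self):
        if self.fps <= 0 or self.sample_interval_s <= 0 \
                or self.event_stride < 1:
            raise ValueError("rates must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "vibe" in raw:
            raw["vibe"] = ViBeParams(**raw["vibe"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _setup_run_logger(output_dir: Path, level: str) -> logging.Logger:
    run_logger = logging.getLogger(f"sleepose.run.{output_dir}")
    run_logger.setLevel(level.upper())
    run_logger.handlers.clear()
    handler = logging.FileHandler(output_dir / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    run_logger.addHandler(handler)
    run_logger.propagate = False
    return run_logger


def run_monitoring(config: PipelineConfig, frames: np.ndarray | None = None,
                   model: MultiTaskDetector | None = None) -> dict:
    """Process a night of video into detections, timeline, indicators and
    synopsis.  ``frames``/``model`` may be passed in memory; otherwise
    they are loaded from ``config.input`` / ``config.checkpoint``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_logger = _setup_run_logger(out, config.log_level)
    t0 = time.time()

    if frames is None:
        if config.input is None:
            raise ValueError("no input configured")
        frames = sio.load_frames(config.input)
    if model is None:
        if config.checkpoint is None or not Path(config.checkpoint).exists():
            raise FileNotFoundError(
                f"checkpoint not found: {config.checkpoint}")
        model = MultiTaskDetector.load(config.checkpoint)
    n_frames = len(frames)
    if n_frames == 0:
        raise ValueError("input video has no frames")
    run_logger.info("loaded %d frames, seed=%d", n_frames, config.seed)

    # motion pass over every frame
    if n_frames >= 2:
        fracs = motion_fractions(frames, params=config.vibe,
                                 seed=config.seed, equalize=config.equalize)
        events = events_from_fractions(fracs, config.trigger_fraction,
                                       config.min_event_frames)
    else:
        fracs = np.zeros(n_frames)
        events = []
    run_logger.info("motion pass done: %d events", len(events))

    in_event = np.zeros(n_frames, dtype=bool)
    for e in events:
        in_event[e.start_frame:e.end_frame + 1] = True

    sample_every = max(1, int(round(config.sample_interval_s * config.fps)))
    detect_flags = np.zeros(n_frames, dtype=bool)
    reason = np.empty(n_frames, dtype=object)
    last_in_event = False
    count_since = sample_every  # sample the very first frame
    for t in range(n_frames):
        if in_event[t]:
            if not last_in_event:
                offset = t
            if (t - offset) % config.event_stride == 0:
                detect_flags[t] = True
                reason[t] = "event"
            else:
                reason[t] = "skipped"
            count_since = sample_every
        else:
            if count_since >= sample_every:
                detect_flags[t] = True
                reason[t] = "sampled"
                count_since = 1
            else:
                reason[t] = "skipped"
                count_since += 1
        last_in_event = in_event[t]

    per_frame_dets = {}
    poses = []
    times = []
    for t in np.flatnonzero(detect_flags):
        dets = model.predict_frame(frames[t],
                                   score_threshold=config.score_threshold,
                                   nms_threshold=config.nms_threshold)
        per_frame_dets[int(t)] = dets
        head = next((d for d in dets if d.region_class == "head"), None)
        body = next((d for d in dets if d.region_class == "upper_body"), None)
        if head is None and body is None:
            poses.append(None)
        else:
            hp = head.pose_class if head else (body.pose_class if body else None)
            bp = body.pose_class if body else (head.pose_class if head else None)
            poses.append((hp, bp))
        times.append(t / config.fps)
    run_logger.info("detector ran on %d frames (%d in events, %d sampled, "
                    "%d skipped)", int(detect_flags.sum()),
                    int((reason == "event").sum()),
                    int((reason == "sampled").sum()),
                    int((reason == "skipped").sum()))

    event_spans = [(e.start_frame / config.fps,
                    (e.end_frame + 1) / config.fps) for e in events]
    video_end = n_frames / config.fps
    no_subject = all(p is None for p in poses) or not poses
    if no_subject:
        run_logger.warning("no subject detected in any processed frame; "
                           "timeline and indicators omitted")
        timeline, indicators = None, None
    else:
        timeline = build_timeline(poses, motion_events=event_spans,
                                  times=np.asarray(times),
                                  smoothing_window=config.smoothing_window,
                                  wake_min_event_s=config.wake_min_event_s,
                                  end_time=video_end)
        indicators = compute_indicators(
            timeline, event_spans, min_duration_min=config.long_posture_min,
            min_event_s=config.min_motion_event_s)

    # artifacts
    sio.write_detections_jsonl(per_frame_dets, out / "detections.jsonl")
    sio.write_events_csv(events, out / "events.csv")
    sel = np.flatnonzero(detect_flags)
    timeline_to_csv(np.asarray(times),
                    [p[0] if p else "" for p in poses],
                    [p[1] if p else "" for p in poses],
                    [bool(in_event[t]) for t in sel],
                    out / "timeline.csv")
    report = {
        "seed": config.seed,
        "n_frames": n_frames,
        "n_events": len(events),
        "frames_detector": int(detect_flags.sum()),
        "frames_in_events": int((reason == "event").sum()),
        "frames_sampled": int((reason == "sampled").sum()),
        "frames_skipped": int((reason == "skipped").sum()),
        "no_subject_detected": no_subject,
        "indicators": None if no_subject else indicators.to_dict(),
        "elapsed_s": time.time() - t0,
    }
    if not no_subject:
        with open(out / "indicators.json", "w") as fh:
            json.dump({"seed": config.seed, **indicators.to_dict()}, fh,
                      indent=2)
        pd.DataFrame([indicators.to_dict()]).to_csv(out / "indicators.csv",
                                                    index=False)
        dial = max(config.dial_hours, timeline.span_s / 3600.0)
        render_synopsis(timeline, out / "synopsis.png", dial_hours=dial)
    run_logger.info("report: %s", json.dumps(report))
    report["timeline"] = timeline
    report["events"] = events
    return report


def _scene_spec(config: PipelineConfig) -> SceneSpec:
    from .synthetic import desk_spec
    if config.tiny:
        return desk_spec(seed=config.seed, **config.scene)
    return SceneSpec(seed=config.seed, **config.scene)


def run_train(config: PipelineConfig) -> Path:
    """Train a detector and write checkpoint + loss history."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.dataset_dir:
        samples = sio.load_dataset(config.dataset_dir)
        n_val = max(1, len(samples) // 10)
        train_set, val_set = samples[:-n_val], samples[-n_val:]
    elif config.n_synthetic:
        splits = generate_dataset(_scene_spec(config), config.n_synthetic)
        train_set, val_set = splits.train, splits.val
    else:
        raise ValueError("no dataset_dir or n_synthetic configured")
    if not train_set:
        raise ValueError("training set is empty")
    overrides = dict(config.train)
    cfg = tiny_train_config(seed=config.seed, **overrides) if config.tiny \
        else TrainConfig(seed=config.seed, **overrides)
    det_cfg = tiny_detector_config() if config.tiny else DetectorConfig()
    model, history = train(train_set, val_set, cfg, det_cfg)
    ckpt = out / "checkpoint.npz"
    model.save(ckpt)
    history.to_csv(out / "loss_history.csv", index=False)
    return ckpt


def run_eval(config: PipelineConfig, model: MultiTaskDetector | None = None,
             samples=None) -> dict:
    """Evaluate a checkpoint on an annotated set; write metrics JSON/CSVs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if model is None:
        if config.checkpoint is None or not Path(config.checkpoint).exists():
            raise FileNotFoundError(
                f"checkpoint not found: {config.checkpoint}")
        model = MultiTaskDetector.load(config.checkpoint)
    if samples is None:
        samples = sio.load_dataset(config.eval_dir or config.dataset_dir)
    metrics = evaluate_model(model, samples,
                             score_threshold=config.score_threshold)
    with open(out / "metrics.json", "w") as fh:
        json.dump({k: v for k, v in metrics.items()
                   if not k.startswith("confusion")}, fh, indent=2)
    metrics["confusion_head"].to_frame().to_csv(out / "confusion_head.csv")
    metrics["confusion_body"].to_frame().to_csv(out / "confusion_body.csv")
    return metrics


def evaluate_model(model: MultiTaskDetector, samples,
                   iou_threshold: float = 0.5,
                   score_threshold: float = 0.5) -> dict:
    """mAP plus pose accuracies/confusions of matched detections."""
    all_dets, all_gts = [], []
    head_true, head_pred, body_true, body_pred = [], [], [], []
    for s in samples:
        dets = model.predict_frame(s.image, score_threshold=score_threshold)
        all_dets.append(dets)
        all_gts.append(s.annotations)
        for region, t_list, p_list in (("head", head_true, head_pred),
                                       ("upper_body", body_true, body_pred)):
            gt = next(a for a in s.annotations if a.region_class == region)
            best = None
            for d in dets:
                if d.region_class == region and \
                        (best is None or d.region_score > best.region_score):
                    best = d
            if best is not None:
                t_list.append(gt.pose_class)
                p_list.append(best.pose_class)
    metrics = mean_average_precision(all_dets, all_gts, iou_threshold)
    n = len(list(samples))
    metrics["head_pose_accuracy"] = (
        classification_accuracy(head_true, head_pred) * len(head_true) / n
        if head_true else 0.0)
    metrics["body_pose_accuracy"] = (
        classification_accuracy(body_true, body_pred) * len(body_true) / n
        if body_true else 0.0)
    metrics["n_images"] = n
    metrics["confusion_head"] = confusion_matrix(head_true, head_pred) \
        if head_true else confusion_matrix([], [])
    metrics["confusion_body"] = confusion_matrix(body_true, body_pred) \
        if body_true else confusion_matrix([], [])
    return metrics
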