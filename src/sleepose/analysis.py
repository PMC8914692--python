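"""Posture timelines and posture-based sleep-quality indicators.

A night is summarized as an ordered list of contiguous episodes, each
holding a head pose, an upper-body pose and a wake flag.  From the
timeline four indicators are computed:

* shifts in sleep posture per hour (count of body-pose changes / hours),
* postures lasting longer than 15 minutes per hour (strict inequality),
* average duration in a posture (minutes),
* sleep efficiency: percentage of the span not spent turning, where
  "turning" is the union of detected motion intervals.

Healthy sleepers typically shift posture 10-30 times per night; the
indicators quantify restlessness without interpreting it clinically.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxes import POSE_CLASSES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PostureEpisode:
    """One maximal run of constant (head pose, body pose, wake) state.

    ``start``/``end`` are seconds from the beginning of monitoring.
    """

    start: float
    end: float
    head_pose: str
    body_pose: str
    wake_flag: bool = False

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("episode must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end - self.start

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


@dataclass
class PostureTimeline:
    episodes: list[PostureEpisode] = field(default_factory=list)

    def __post_init__(self):
        for a, b in zip(self.episodes, self.episodes[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise ValueError("episodes must be contiguous")
            if (a.head_pose, a.body_pose, a.wake_flag) == (
                    b.head_pose, b.body_pose, b.wake_flag):
                raise ValueError("consecutive episodes must differ")

    @property
    def start(self) -> float:
        return self.episodes[0].start

    @property
    def end(self) -> float:
        return self.episodes[-1].end

    @property
    def span_s(self) -> float:
        return self.end - self.start

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "start_s": e.start, "end_s": e.end, "head_pose": e.head_pose,
            "body_pose": e.body_pose, "wake_flag": e.wake_flag}
            for e in self.episodes])


@dataclass(frozen=True)
class SleepIndicators:
    shifts_per_hour: float
    long_postures_per_hour: float
    average_duration_min: float
    sleep_efficiency_pct: float

    def to_dict(self) -> dict[str, float]:
        return {
            "shifts_per_hour": self.shifts_per_hour,
            "long_postures_per_hour": self.long_postures_per_hour,
            "average_duration_min": self.average_duration_min,
            "sleep_efficiency_pct": self.sleep_efficiency_pct,
        }


def _majority_smooth(labels: list, window: int) -> list:
    """Centered majority vote; ties keep the previously smoothed label."""
    if window <= 1:
        return list(labels)
    half = window // 2
    out = []
    prev = labels[0]
    for i in range(len(labels)):
        lo, hi = max(0, i - half), min(len(labels), i + half + 1)
        counts = Counter(labels[lo:hi])
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1] and prev in counts \
                and counts[prev] == top[0][1]:
            choice = prev
        else:
            choice = top[0][0]
        out.append(choice)
        prev = choice
    return out


def episodes_from_frames(times: np.ndarray, head_poses: list, body_poses: list,
                         wake_flags: list, end_time: float | None = None
                         ) -> PostureTimeline:
    """Merge per-frame labels into maximal constant episodes.

    Frame ``i`` is taken to hold from ``times[i]`` to ``times[i+1]`` (the
    last frame extends to ``end_time``, default one median frame step).
    """
    times = np.asarray(times, dtype=float)
    n = len(times)
    if end_time is None:
        step = float(np.median(np.diff(times))) if n > 1 else 1.0
        end_time = times[-1] + step
    bounds = np.append(times, end_time)
    episodes = []
    run_start = 0
    state = (head_poses[0], body_poses[0], wake_flags[0])
    for i in range(1, n + 1):
        cur = None if i == n else (head_poses[i], body_poses[i], wake_flags[i])
        if cur != state:
            episodes.append(PostureEpisode(
                float(bounds[run_start]), float(bounds[i]),
                state[0], state[1], bool(state[2])))
            run_start = i
            state = cur
    return PostureTimeline(episodes)


def build_timeline(per_frame_poses,
                   motion_events=(),
                   frame_interval: float = 1.0,
                   smoothing_window: int = 5,
                   times=None,
                   wake_min_event_s: float = 300.0,
                   end_time: float | None = None) -> PostureTimeline:
    """Assemble a posture timeline from per-frame pose labels.

    Parameters
    ----------
    per_frame_poses
        Sequence over frames of ``(head_pose, body_pose)`` tuples or
        ``None`` when no detection is available for that frame (the
        previous labels are then carried forward).
    motion_events
        Iterable of ``(start_s, end_s)`` motion intervals.  Frames inside
        events longer than ``wake_min_event_s`` are flagged as wake.
    frame_interval
        Seconds between frames when ``times`` is not given explicitly.
    smoothing_window
        Width of the centered majority filter applied to both pose label
        streams before episodes are merged.
    """
    per_frame_poses = list(per_frame_poses)
    if times is None:
        times = np.arange(len(per_frame_poses)) * float(frame_interval)
    times = np.asarray(times, dtype=float)
    if len(times) != len(per_frame_poses):
        raise ValueError("times and per_frame_poses length mismatch")
    if all(p is None for p in per_frame_poses):
        raise ValueError("timeline has zero detected frames")

    heads, bodies = [], []
    prev = None
    n_missing = 0
    for p in per_frame_poses:
        if p is None:
            n_missing += 1
            p = prev
        if p is None:  # leading gap: backfill later
            heads.append(None)
            bodies.append(None)
        else:
            heads.append(p[0])
            bodies.append(p[1])
        prev = p
    if n_missing:
        logger.info("%d frames without detection inherited previous labels",
                    n_missing)
    first = next(i for i, h in enumerate(heads) if h is not None)
    for i in range(first):
        heads[i], bodies[i] = heads[first], bodies[first]

    heads = _majority_smooth(heads, smoothing_window)
    bodies = _majority_smooth(bodies, smoothing_window)

    wake = np.zeros(len(times), dtype=bool)
    for ev in motion_events:
        s, e = float(ev[0]), float(ev[1])
        if e - s > wake_min_event_s:
            wake |= (times >= s) & (times < e)

    return episodes_from_frames(times, heads, bodies, list(wake),
                                end_time=end_time)


def compute_shifts_per_hour(timeline: PostureTimeline) -> float:
    """Body-pose transitions per hour of monitored span."""
    if not timeline.episodes:
        raise ValueError("timeline is empty")
    span_h = timeline.span_s / 3600.0
    if span_h <= 0:
        raise ValueError("timeline span must be positive")
    shifts = sum(1 for a, b in zip(timeline.episodes, timeline.episodes[1:])
                 if a.body_pose != b.body_pose)
    return shifts / span_h


def compute_long_posture_rate(timeline: PostureTimeline,
                              min_duration_min: float = 15.0) -> float:
    """Episodes strictly longer than ``min_duration_min`` per hour."""
    if not timeline.episodes:
        raise ValueError("timeline is empty")
    span_h = timeline.span_s / 3600.0
    count = sum(1 for e in timeline.episodes
                if e.duration_min > min_duration_min)
    return count / span_h


def compute_average_duration(timeline: PostureTimeline) -> float:
    """Arithmetic mean episode duration, in minutes."""
    if not timeline.episodes:
        raise ValueError("timeline is empty")
    return float(np.mean([e.duration_min for e in timeline.episodes]))


def _union_duration(spans, lo: float, hi: float) -> float:
    spans = sorted((max(lo, float(s)), min(hi, float(e))) for s, e in spans)
    total, cur_s, cur_e = 0.0, None, None
    for s, e in spans:
        if e <= s:
            continue
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def compute_sleep_efficiency(timeline: PostureTimeline,
                             motion_events=(),
                             min_event_s: float = 10.0) -> float:
    """Percentage of the span without turning.

    Turning time is the union of motion intervals at least
    ``min_event_s`` long, clipped to the timeline span.
    """
    if not timeline.episodes:
        raise ValueError("timeline is empty")
    span = timeline.span_s
    events = [(float(s), float(e)) for s, e in motion_events]
    for s, e in events:
        if e < s:
            raise ValueError("motion event with negative duration")
    events = [ev for ev in events if ev[1] - ev[0] >= min_event_s]
    raw_union = _union_duration(events, -np.inf, np.inf)
    if raw_union > span * (1 + 1e-9):
        raise ValueError("motion time exceeds timeline span")
    turning = _union_duration(events, timeline.start, timeline.end)
    return 100.0 * (span - turning) / span


def compute_indicators(timeline: PostureTimeline, motion_events=(),
                       min_duration_min: float = 15.0,
                       min_event_s: float = 10.0) -> SleepIndicators:
    """All four indicators bundled."""
    return SleepIndicators(
        shifts_per_hour=compute_shifts_per_hour(timeline),
        long_postures_per_hour=compute_long_posture_rate(
            timeline, min_duration_min),
        average_duration_min=compute_average_duration(timeline),
        sleep_efficiency_pct=compute_sleep_efficiency(
            timeline, motion_events, min_event_s),
    )


_POSE_COLORS = {
    "supine": "#4c72b0",
    "prone": "#dd8452",
    "left": "#55a868",
    "right": "#c44e52",
}
_WAKE_COLOR = "#9e9e9e"


def synopsis_arcs(timeline: PostureTimeline, dial_hours: float = 12.0
                  ) -> list[tuple[float, float, str]]:
    """Arc geometry of the night dial: ``(theta_start, width, color)`` in
    radians per episode, clockwise from the top; grey marks wake."""
    if timeline.span_s > dial_hours * 3600.0 + 1e-6:
        raise ValueError("timeline span exceeds the dial span")
    full = dial_hours * 3600.0
    arcs = []
    for e in timeline.episodes:
        theta0 = 2 * np.pi * (e.start - timeline.start) / full
        width = 2 * np.pi * e.duration_s / full
        color = _WAKE_COLOR if e.wake_flag else _POSE_COLORS[e.body_pose]
        arcs.append((theta0, width, color))
    return arcs


def render_synopsis(timeline: PostureTimeline, output_path,
                    dial_hours: float = 12.0) -> None:
    """Draw the circular night synopsis and write it to ``output_path``.

    The dial represents ``dial_hours`` (12 by default, starting at the
    top, running clockwise); each episode is an arc colored by its body
    pose and wake episodes are drawn grey.  The angular extent of each
    arc is proportional to the episode duration.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    arcs = synopsis_arcs(timeline, dial_hours)
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    for theta0, width, color in arcs:
        ax.bar(theta0 + width / 2, height=0.35, width=width, bottom=0.65,
               color=color, edgecolor="white", linewidth=0.5)
    ax.set_yticks([])
    hours = np.arange(0, dial_hours, max(1, int(dial_hours // 12)))
    ax.set_xticks(2 * np.pi * hours / dial_hours)
    ax.set_xticklabels([f"{int(h)}h" for h in hours], fontsize=8)
    handles = [Patch(color=c, label=p) for p, c in _POSE_COLORS.items()]
    handles.append(Patch(color=_WAKE_COLOR, label="wake"))
    ax.legend(handles=handles, loc="center", fontsize=8, frameon=False)
    fig.savefig(output_path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def timeline_to_csv(times, head_poses, body_poses, wake_flags, path) -> None:
    """Write a per-frame timeline as ``timestamp_s, head_pose, body_pose,
    wake_flag`` CSV."""
    pd.DataFrame({
        "timestamp_s": np.asarray(times, dtype=float),
        "head_pose": head_poses,
        "body_pose": body_poses,
        "wake_flag": np.asarray(wake_flags, dtype=bool),
    }).to_csv(path, index=False)


def timeline_from_csv(path) -> PostureTimeline:
    df = pd.read_csv(path)
    for pose_col in ("head_pose", "body_pose"):
        bad = set(df[pose_col]) - set(POSE_CLASSES)
        if bad:
            raise ValueError(f"unknown pose labels in {pose_col}: {bad}")
    return episodes_from_frames(
        df["timestamp_s"].to_numpy(), list(df["head_pose"]),
        list(df["body_pose"]), list(df["wake_flag"].astype(bool)))
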