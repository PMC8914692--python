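"""Posture timelines and the four sleep-quality indicators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepose.analysis import (PostureEpisode, PostureTimeline,
                               build_timeline, compute_average_duration,
                               compute_indicators, compute_long_posture_rate,
                               compute_shifts_per_hour,
                               compute_sleep_efficiency, render_synopsis,
                               synopsis_arcs, timeline_from_csv,
                               timeline_to_csv)
from sleepose.synthetic import (TimelineEpisodeSpec, TimelineSpec,
                                generate_posture_timeline)


def _timeline(durations_min, body_poses, head_poses=None, wake=None,
              start=0.0):
    head_poses = head_poses or body_poses
    wake = wake or [False] * len(durations_min)
    eps = []
    t = start
    for d, bp, hp, w in zip(durations_min, body_poses, head_poses, wake):
        eps.append(PostureEpisode(t, t + d * 60, hp, bp, w))
        t += d * 60
    return PostureTimeline(eps)


EIGHT_HOURS = _timeline([120, 240, 120], ["supine", "left", "right"])


class TestTimelineStructure:
    def test_episodes_must_be_contiguous(self):
        with pytest.raises(ValueError):
            PostureTimeline([PostureEpisode(0, 60, "left", "left"),
                             PostureEpisode(120, 180, "right", "right")])

    def test_consecutive_identical_episodes_rejected(self):
        with pytest.raises(ValueError):
            PostureTimeline([PostureEpisode(0, 60, "left", "left"),
                             PostureEpisode(60, 120, "left", "left")])

    def test_durations_sum_to_span(self):
        total = sum(e.duration_s for e in EIGHT_HOURS.episodes)
        assert total == pytest.approx(EIGHT_HOURS.span_s)


class TestBuildTimeline:
    def test_constant_labels_give_single_episode(self):
        tl = build_timeline([("supine", "supine")] * 20, frame_interval=30)
        assert len(tl.episodes) == 1
        assert tl.span_s == pytest.approx(20 * 30)

    def test_single_frame_flicker_smoothed_away(self):
        poses = [("left", "left")] * 10
        poses[4] = ("right", "right")
        tl = build_timeline(poses, frame_interval=10, smoothing_window=5)
        assert len(tl.episodes) == 1
        assert tl.episodes[0].body_pose == "left"

    def test_missing_frames_inherit_previous_label(self):
        poses = [("left", "left"), None, None, ("left", "left")]
        tl = build_timeline(poses, frame_interval=10, smoothing_window=1)
        assert len(tl.episodes) == 1

    def test_all_frames_missing_rejected(self):
        with pytest.raises(ValueError):
            build_timeline([None, None], frame_interval=1)

    def test_generator_timeline_round_trips(self):
        spec = TimelineSpec(120, (
            TimelineEpisodeSpec("supine", "supine", 45),
            TimelineEpisodeSpec("left", "left", 45),
            TimelineEpisodeSpec("right", "left", 30)), frame_interval_s=30)
        sample = generate_posture_timeline(spec)
        poses = list(zip(sample.head_poses, sample.body_poses))
        tl = build_timeline(poses, times=sample.frame_times,
                            smoothing_window=1,
                            end_time=sample.timeline.end)
        got = [(e.head_pose, e.body_pose, e.start, e.end)
               for e in tl.episodes]
        want = [(e.head_pose, e.body_pose, e.start, e.end)
                for e in sample.timeline.episodes]
        assert got == want

    def test_long_motion_events_flagged_as_wake(self):
        poses = [("left", "left")] * 60
        tl = build_timeline(poses, motion_events=[(100, 500)],
                            frame_interval=10, smoothing_window=1,
                            wake_min_event_s=300)
        wake_time = sum(e.duration_s for e in tl.episodes if e.wake_flag)
        assert wake_time == pytest.approx(400, abs=10)


class TestIndicators:
    def test_single_episode_has_zero_shifts(self):
        tl = _timeline([60], ["supine"])
        assert compute_shifts_per_hour(tl) == 0.0

    def test_two_transitions_over_eight_hours(self):
        assert compute_shifts_per_hour(EIGHT_HOURS) == pytest.approx(0.25)

    def test_alternating_episodes_count_transitions(self):
        tl = _timeline([10] * 6, ["left", "right"] * 3)
        assert compute_shifts_per_hour(tl) == pytest.approx(5.0)

    def test_head_only_changes_do_not_count_as_shifts(self):
        tl = _timeline([30, 30], ["supine", "supine"],
                       head_poses=["left", "right"])
        assert compute_shifts_per_hour(tl) == 0.0

    def test_short_episodes_do_not_count_as_long(self):
        tl = _timeline([10, 10, 10], ["left", "right", "left"])
        assert compute_long_posture_rate(tl) == 0.0

    def test_long_posture_rate_hand_case(self):
        assert compute_long_posture_rate(EIGHT_HOURS) == pytest.approx(0.375)

    def test_boundary_fifteen_minutes_excluded(self):
        tl = _timeline([15, 45], ["left", "right"])
        # strictly longer than 15 min: only the 45-min episode counts
        assert compute_long_posture_rate(tl) == pytest.approx(1.0)

    def test_average_duration_hand_case(self):
        assert compute_average_duration(EIGHT_HOURS) == pytest.approx(160.0)

    def test_average_duration_of_equal_episodes(self):
        tl = _timeline([25, 25, 25], ["left", "right", "left"])
        assert compute_average_duration(tl) == pytest.approx(25.0)

    def test_efficiency_without_motion_is_hundred(self):
        assert compute_sleep_efficiency(EIGHT_HOURS, []) == 100.0

    def test_efficiency_hand_case(self):
        # 48 minutes of turning in 8 hours -> 90%
        events = [(1000.0, 1000.0 + 48 * 60)]
        assert compute_sleep_efficiency(EIGHT_HOURS, events) \
            == pytest.approx(90.0)

    def test_motion_covering_whole_span_gives_zero(self):
        assert compute_sleep_efficiency(
            EIGHT_HOURS, [(0.0, EIGHT_HOURS.span_s)]) == 0.0

    def test_short_motion_events_ignored(self):
        events = [(100.0, 105.0)]  # below the 10 s floor
        assert compute_sleep_efficiency(EIGHT_HOURS, events) == 100.0

    def test_motion_exceeding_span_rejected(self):
        with pytest.raises(ValueError):
            compute_sleep_efficiency(_timeline([10], ["left"]),
                                     [(0.0, 10 * 3600.0)])

    def test_bundle_matches_hand_computed_quadruple(self):
        events = [(0.0, 24 * 60.0)]
        ind = compute_indicators(EIGHT_HOURS, events)
        assert ind.shifts_per_hour == pytest.approx(0.25)
        assert ind.long_postures_per_hour == pytest.approx(0.375)
        assert ind.average_duration_min == pytest.approx(160.0)
        assert ind.sleep_efficiency_pct == pytest.approx(95.0)

    def test_single_long_episode_night(self):
        tl = _timeline([480], ["supine"])
        ind = compute_indicators(tl, [])
        assert ind.shifts_per_hour == 0.0
        assert ind.long_postures_per_hour == pytest.approx(0.125)
        assert ind.average_duration_min == pytest.approx(480.0)
        assert ind.sleep_efficiency_pct == 100.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["supine", "prone", "left",
                                               "right"]),
                              st.floats(1.0, 120.0)),
                    min_size=1, max_size=12))
    def test_shift_count_times_span_is_integer(self, spec):
        eps, t = [], 0.0
        for pose, dur in spec:
            if eps and eps[-1].body_pose == pose:
                pose = "prone" if pose != "prone" else "left"
            eps.append(PostureEpisode(t, t + dur * 60, pose, pose))
            t += dur * 60
        tl = PostureTimeline(eps)
        n = compute_shifts_per_hour(tl) * tl.span_s / 3600.0
        assert n == pytest.approx(round(n))
        assert round(n) == len(eps) - 1

    def test_indicators_invariant_to_frame_resampling(self):
        spec = TimelineSpec(60, (TimelineEpisodeSpec("supine", "supine", 30),
                                 TimelineEpisodeSpec("left", "left", 30)))
        for interval in (10, 30, 60):
            sample = generate_posture_timeline(
                TimelineSpec(60, spec.episodes, frame_interval_s=interval))
            tl = build_timeline(list(zip(sample.head_poses,
                                         sample.body_poses)),
                                times=sample.frame_times, smoothing_window=1,
                                end_time=3600.0)
            assert compute_shifts_per_hour(tl) == pytest.approx(1.0)
            assert compute_average_duration(tl) == pytest.approx(30.0)


class TestSynopsis:
    def test_arc_extents_proportional_to_durations(self):
        arcs = synopsis_arcs(EIGHT_HOURS, dial_hours=12.0)
        widths = np.array([w for _, w, _ in arcs])
        durations = np.array([e.duration_s for e in EIGHT_HOURS.episodes])
        np.testing.assert_allclose(widths / widths.sum(),
                                   durations / durations.sum())
        assert widths.sum() == pytest.approx(2 * np.pi * 8 / 12)

    def test_no_grey_arcs_without_wake(self):
        arcs = synopsis_arcs(EIGHT_HOURS)
        assert all(c != "#9e9e9e" for _, _, c in arcs)

    def test_wake_episode_drawn_grey(self):
        tl = _timeline([60, 30, 60], ["left", "left", "right"],
                       wake=[False, True, False])
        colors = [c for _, _, c in synopsis_arcs(tl)]
        assert colors[1] == "#9e9e9e"

    def test_file_written_and_valid(self, tmp_path):
        out = tmp_path / "synopsis.png"
        render_synopsis(EIGHT_HOURS, out)
        import imageio.v3 as iio
        img = iio.imread(out)
        assert img.ndim >= 2 and img.size > 0

    def test_span_exceeding_dial_rejected(self):
        with pytest.raises(ValueError):
            synopsis_arcs(EIGHT_HOURS, dial_hours=6.0)


def test_timeline_csv_round_trip(tmp_path):
    spec = TimelineSpec(30, (TimelineEpisodeSpec("supine", "supine", 20),
                             TimelineEpisodeSpec("left", "left", 10)),
                        frame_interval_s=60)
    sample = generate_posture_timeline(spec)
    path = tmp_path / "timeline.csv"
    timeline_to_csv(sample.frame_times, sample.head_poses, sample.body_poses,
                    sample.wake_flags, path)
    tl = timeline_from_csv(path)
    assert len(tl.episodes) == 2
    assert [e.body_pose for e in tl.episodes] == ["supine", "left"]
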