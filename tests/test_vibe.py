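"""ViBe background subtraction: classification rule, update odds,
morphological cleanup, and motion-event triggering."""

import numpy as np
import pytest

from oracles import clean_mask_oracle, vibe_classify_oracle
from sleepose.synthetic import desk_spec, generate_motion_video
from sleepose.vibe import (BackgroundModel, ViBeParams, classify_frame,
                           clean_mask, detect_motion_events,
                           equalize_histogram, init_background_model,
                           update_background_model)


def _model_from(samples):
    samples = np.asarray(samples, dtype=float)
    return BackgroundModel(samples, samples.shape[1:])


class TestEqualize:
    def test_constant_frame_unchanged(self):
        frame = np.full((8, 8), 77, dtype=np.uint8)
        np.testing.assert_array_equal(equalize_histogram(frame), frame)

    def test_two_level_frame_maps_to_extremes(self):
        frame = np.zeros((10, 10), dtype=np.uint8)
        frame[5:] = 255
        out = equalize_histogram(frame)
        assert set(np.unique(out)) == {0, 255}
        assert (out[5:] == 255).all() and (out[:5] == 0).all()

    def test_random_frame_output_cdf_near_uniform(self, rng):
        frame = rng.integers(0, 256, size=(256, 256)).astype(np.uint8)
        out = equalize_histogram(frame)
        hist = np.bincount(out.ravel(), minlength=256)
        cdf = np.cumsum(hist) / out.size
        uniform = (np.arange(256) + 1) / 256
        assert np.abs(cdf - uniform).max() <= 1 / 256 + 1e-9

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            equalize_histogram(np.zeros((0, 4)))


class TestInit:
    def test_constant_frame_gives_constant_samples(self):
        model = init_background_model(np.full((6, 6), 42.0),
                                      ViBeParams(), seed=0)
        assert (model.samples == 42.0).all()
        assert model.samples.shape == (20, 6, 6)

    def test_seeded_init_reproducible(self, rng):
        frame = rng.integers(0, 256, size=(12, 12)).astype(float)
        a = init_background_model(frame, ViBeParams(), seed=3)
        b = init_background_model(frame, ViBeParams(), seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_samples_come_from_pixel_neighborhood(self, rng):
        frame = rng.integers(0, 256, size=(9, 9)).astype(float)
        model = init_background_model(frame, ViBeParams(n_samples=10), seed=1)
        h, w = frame.shape
        for y in range(h):
            for x in range(w):
                hood = {frame[min(max(y + dy, 0), h - 1),
                              min(max(x + dx, 0), w - 1)]
                        for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                        if (dy, dx) != (0, 0)}
                assert set(model.samples[:, y, x]).issubset(hood)


class TestClassify:
    def test_value_equal_to_all_samples_is_background(self):
        model = _model_from(np.full((5, 3, 3), 100.0))
        mask = classify_frame(np.full((3, 3), 100.0), model,
                              ViBeParams(n_samples=5, match_radius=1.0))
        assert (mask == 0).all()

    def test_hand_evaluated_match_count(self):
        # samples {10,12,30}, R=5, min 2, v=11 -> two matches -> background
        samples = np.array([10.0, 12.0, 30.0]).reshape(3, 1, 1)
        model = _model_from(samples)
        params = ViBeParams(n_samples=3, match_radius=5.0, min_matches=2)
        assert classify_frame(np.array([[11.0]]), model, params)[0, 0] == 0
        # v=17: only {12..22} window holds no two samples -> foreground
        assert classify_frame(np.array([[17.0]]), model, params)[0, 0] == 1

    def test_value_beyond_radius_of_all_samples_is_foreground(self):
        samples = np.stack([np.full((4, 4), v) for v in (10.0, 20.0, 30.0)])
        params = ViBeParams(n_samples=3, match_radius=7.0, min_matches=1)
        frame = np.full((4, 4), 30.0 + 7.0 + 1.0)
        mask = classify_frame(frame, _model_from(samples), params)
        assert (mask == 1).all()

    def test_shape_mismatch_rejected(self):
        model = _model_from(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError):
            classify_frame(np.zeros((5, 5)), model,
                           ViBeParams(n_samples=3))

    def test_matches_per_pixel_oracle(self, rng):
        params_pool = [(5, 10.0, 1), (8, 20.0, 2), (4, 5.0, 3)]
        for i in range(110):
            n, radius, mmin = params_pool[i % len(params_pool)]
            samples = rng.integers(0, 256, size=(n, 8, 8)).astype(float)
            frame = rng.integers(0, 256, size=(8, 8)).astype(float)
            params = ViBeParams(n_samples=n, match_radius=radius,
                                min_matches=mmin)
            got = classify_frame(frame, _model_from(samples.copy()), params)
            want = vibe_classify_oracle(frame, samples, radius, mmin)
            np.testing.assert_array_equal(got, want)


class TestUpdate:
    def test_all_foreground_mask_leaves_model_unchanged(self):
        samples = np.arange(3 * 4 * 4, dtype=float).reshape(3, 4, 4)
        model = _model_from(samples.copy())
        update_background_model(np.full((4, 4), 99.0), np.ones((4, 4)),
                                model, ViBeParams(n_samples=3,
                                                  update_subsampling=1),
                                seed=0)
        np.testing.assert_array_equal(model.samples, samples)

    def test_subsampling_one_forces_update_everywhere(self):
        model = _model_from(np.zeros((4, 6, 6)))
        frame = np.full((6, 6), 55.0)
        update_background_model(frame, np.zeros((6, 6)), model,
                                ViBeParams(n_samples=4, update_subsampling=1,
                                           neighbor_update=False), seed=0)
        assert (model.samples == 55.0).any(axis=0).all()

    def test_update_rate_matches_one_in_sixteen(self):
        """Monte-Carlo estimate over 1e5 background pixel-frames falls
        within three standard errors of the printed 1/16 odds."""
        h, w = 250, 400  # 1e5 pixels
        model = _model_from(np.zeros((8, h, w)))
        frame = np.full((h, w), 77.0)  # distinct marker value
        params = ViBeParams(n_samples=8, update_subsampling=16,
                            neighbor_update=False)
        update_background_model(frame, np.zeros((h, w)), model, params,
                                seed=11)
        frac = (model.samples == 77.0).any(axis=0).mean()
        p = 1 / 16
        se = np.sqrt(p * (1 - p) / (h * w))
        assert abs(frac - p) < 3 * se

    def test_update_restricted_to_background_pixels(self):
        h, w = 100, 100
        model = _model_from(np.zeros((4, h, w)))
        mask = np.zeros((h, w))
        mask[:, 50:] = 1  # right half foreground
        params = ViBeParams(n_samples=4, update_subsampling=2,
                            neighbor_update=False)
        update_background_model(np.full((h, w), 9.0), mask, model, params,
                                seed=2)
        touched = (model.samples == 9.0).any(axis=0)
        assert not touched[:, 50:].any()
        assert abs(touched[:, :50].mean() - 0.5) < 0.05


class TestCleanMask:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[6, 6] = 1
        assert clean_mask(mask, kernel_size=3, min_area=4).sum() == 0

    def test_interior_hole_filled(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[3:13, 3:13] = 1
        mask[7:9, 7:9] = 0
        out = clean_mask(mask, kernel_size=3, min_area=4)
        assert (out[7:9, 7:9] == 1).all()

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError):
            clean_mask(np.full((4, 4), 3))

    def test_matches_brute_force_morphology_oracle(self, rng):
        for _ in range(110):
            mask = (rng.random((16, 16)) < 0.45).astype(np.uint8)
            got = clean_mask(mask, kernel_size=3, min_area=4)
            want = clean_mask_oracle(mask, kernel_size=3, min_area=4)
            np.testing.assert_array_equal(got, want)


class TestMotionEvents:
    def test_static_noisy_video_has_no_events(self):
        spec = desk_spec(seed=1, noise_sd=3.0)
        frames, _ = generate_motion_video(spec, 40, [])
        events = detect_motion_events(frames, trigger_fraction=0.02,
                                      min_event_frames=3, seed=0)
        assert events == []

    def test_moving_object_yields_one_overlapping_event(self):
        spec = desk_spec(seed=2, noise_sd=2.0)
        path = [(10, 40)] * 20 + [(10 + 3 * t, 40) for t in range(21)] \
            + [(70, 40)] * 19
        frames, _ = generate_motion_video(spec, 60, path)
        events = detect_motion_events(frames, trigger_fraction=0.01,
                                      min_event_frames=3, seed=0)
        assert len(events) == 1
        ev = events[0]
        assert ev.start_frame <= 40 and ev.end_frame >= 20

    def test_zero_trigger_gives_single_full_span_event(self):
        spec = desk_spec(seed=3, noise_sd=1.0)
        frames, _ = generate_motion_video(spec, 10, [])
        events = detect_motion_events(frames, trigger_fraction=0.0,
                                      min_event_frames=1, seed=0)
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (0, 9)

    def test_requires_two_frames(self):
        with pytest.raises(ValueError):
            detect_motion_events(np.zeros((1, 8, 8)))


def test_ghost_absorbed_only_with_neighbor_diffusion():
    """A region whose object leaves (a ghost) is reabsorbed into the
    background via the spatial-diffusion update, and persists without it."""
    h = w = 64
    rng = np.random.default_rng(0)

    def frame(with_obj, r):
        f = np.full((h, w), 80.0) + r.normal(0, 2, (h, w))
        if with_obj:
            f[20:30, 24:34] = 180.0
        return f

    results = {}
    for neighbor in (True, False):
        params = ViBeParams(update_subsampling=16, neighbor_update=neighbor)
        model = init_background_model(frame(True, rng), params, seed=0)
        r = np.random.default_rng(7)
        frac = None
        for _ in range(300):
            f = frame(False, r)  # object gone
            mask = classify_frame(f, model, params)
            frac = clean_mask(mask).mean()
            update_background_model(f, mask, model, params, r)
        results[neighbor] = frac
    assert results[True] < 0.002
    assert results[False] > 0.01


def test_masks_stay_binary_through_the_chain(rng):
    spec = desk_spec(seed=4, noise_sd=2.0)
    frames, _ = generate_motion_video(spec, 6, [(10, 10)])
    params = ViBeParams()
    model = init_background_model(frames[0], params, seed=0)
    for f in frames[1:]:
        mask = classify_frame(f.astype(float), model, params)
        assert set(np.unique(mask)).issubset({0, 1})
        cleaned = clean_mask(mask)
        assert set(np.unique(cleaned)).issubset({0, 1})
        update_background_model(f.astype(float), mask, model, params, rng)
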