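"""Detection pipeline: greyscale, background model, binarization, particles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvatrack import (
    BackgroundModel,
    BehaviorParams,
    FrameStack,
    RenderParams,
    build_background,
    detect_particles,
    render_frames,
    simulate_trajectory,
    subtract_and_binarize,
    to_greyscale,
    track_stack,
)
from conftest import oracle_particles


class TestToGreyscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((200, 200, 200), 200), ((255, 0, 0), 85), ((0, 0, 0), 0), ((1, 2, 2), 2)],
    )
    def test_channel_mean_rounded_half_up(self, rgb, expected):
        frame = np.full((4, 4, 3), rgb, dtype=np.uint8)
        out = to_greyscale(frame)
        assert out.shape == (4, 4)
        assert (out == expected).all()

    def test_single_channel_passes_through(self):
        frame = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert to_greyscale(frame) is frame

    def test_bad_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_greyscale(np.zeros((4, 4, 4), dtype=np.uint8))


class TestBuildBackground:
    def test_pixelwise_mean(self):
        f1 = np.full((3, 3), 10, dtype=np.uint8)
        f2 = np.full((3, 3), 20, dtype=np.uint8)
        bg = build_background(FrameStack(frames=[f1, f2]))
        assert (bg.image == 15.0).all()

    def test_identical_frames_reproduce_the_frame(self):
        f = np.arange(9, dtype=np.uint8).reshape(3, 3)
        bg = build_background(FrameStack(frames=[f, f, f]))
        assert np.array_equal(bg.image, f.astype(float))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        frames = [rng.integers(0, 255, (5, 5)).astype(np.uint8) for _ in range(6)]
        bg1 = build_background(FrameStack(frames=frames))
        bg2 = build_background(FrameStack(frames=frames[::-1]))
        assert np.allclose(bg1.image, bg2.image)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            FrameStack(frames=[np.zeros((3, 3), dtype=np.uint8)])


class TestSubtractAndBinarize:
    def test_frame_equal_to_background_gives_empty_mask(self):
        f = np.full((8, 8), 40, dtype=np.uint8)
        bg = BackgroundModel(image=f.astype(float))
        assert not subtract_and_binarize(f, bg, method="otsu").any()
        assert not subtract_and_binarize(f, bg, method="fixed:50").any()

    def test_fixed_threshold_selects_exactly_the_bright_patch(self):
        bg = BackgroundModel(image=np.full((20, 20), 10.0))
        frame = np.full((20, 20), 10, dtype=np.uint8)
        frame[5:10, 7:12] = 200
        mask = subtract_and_binarize(frame, bg, method="fixed:50")
        expected = np.zeros((20, 20), dtype=bool)
        expected[5:10, 7:12] = True
        assert np.array_equal(mask, expected)

    def test_absolute_difference_catches_dark_larva_too(self):
        bg = BackgroundModel(image=np.full((10, 10), 200.0))
        frame = np.full((10, 10), 200, dtype=np.uint8)
        frame[2:4, 2:4] = 20
        mask = subtract_and_binarize(frame, bg, method="fixed:50")
        assert mask.sum() == 4 and mask[2:4, 2:4].all()

    def test_otsu_guard_declares_noise_only_frames_empty(self):
        rng = np.random.default_rng(1)
        bg = BackgroundModel(image=np.full((50, 50), 30.0))
        frame = np.clip(30 + rng.normal(0, 2, (50, 50)), 0, 255).astype(np.uint8)
        assert not subtract_and_binarize(frame, bg, method="otsu", min_fg_level=10).any()

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_raising_fixed_threshold_never_adds_pixels(self, t1, t2, seed):
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(seed)
        frame = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        bg = BackgroundModel(image=np.full((16, 16), 100.0))
        m_lo = subtract_and_binarize(frame, bg, method=f"fixed:{lo}")
        m_hi = subtract_and_binarize(frame, bg, method=f"fixed:{hi}")
        assert not (m_hi & ~m_lo).any()

    def test_dimension_mismatch_rejected(self):
        bg = BackgroundModel(image=np.zeros((4, 4)))
        with pytest.raises(ValueError):
            subtract_and_binarize(np.zeros((5, 5), dtype=np.uint8), bg)


class TestDetectParticles:
    def test_square_block_centroid_and_area(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[20:23, 10:13] = True  # top-left pixel (x=10, y=20)
        (det,) = detect_particles(mask, min_area=1)
        assert det.centroid == (11.0, 21.0)
        assert det.area_px == 9

    def test_min_area_filters_small_components(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:4, 1:4] = True  # area 9
        mask[10:12, 10:12] = True  # area 4
        dets = detect_particles(mask, min_area=5)
        assert len(dets) == 1 and dets[0].area_px == 9

    def test_output_sorted_by_area_descending(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[1:3, 1:3] = True  # 4 px
        mask[10:14, 10:14] = True  # 16 px
        mask[20:23, 20:23] = True  # 9 px
        areas = [d.area_px for d in detect_particles(mask, min_area=1)]
        assert areas == [16, 9, 4]

    def test_empty_mask_gives_empty_list(self):
        assert detect_particles(np.zeros((5, 5), dtype=bool)) == []

    def test_diagonal_pixels_are_one_component(self):
        mask = np.eye(4, dtype=bool)
        dets = detect_particles(mask, min_area=1)
        assert len(dets) == 1 and dets[0].area_px == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_flood_fill_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(64, 64)) < 0.4
        got = {
            (d.area_px, round(d.centroid[0], 9), round(d.centroid[1], 9))
            for d in detect_particles(mask, min_area=1)
        }
        assert got == oracle_particles(mask, min_area=1)


class TestTrackStack:
    def test_identical_frames_yield_no_detections(self):
        f = np.full((20, 20), 30, dtype=np.uint8)
        det = track_stack(FrameStack(frames=[f.copy() for _ in range(5)]))
        assert det.empty

    def test_moving_larva_detected_in_every_frame(self, small_arena):
        params = BehaviorParams(bout_rate_per_h=40.0, bout_duration_mean_s=600.0)
        truth = simulate_trajectory(small_arena, params, 0.05, seed=11)
        stack, _ = render_frames(truth, small_arena, RenderParams(noise_sd=0.0), seed=11)
        det = track_stack(stack)
        assert set(det["frame"]) == set(range(truth.n_frames))

    def test_noiseless_centroids_within_half_pixel_of_truth(self, small_arena):
        # near-continuous movement keeps the average-background model valid
        # (a dwelling larva leaves a background ghost, as in real recordings);
        # no food blob: crossing it erodes the mask edge and shifts the centroid
        from dataclasses import replace

        arena = replace(small_arena, food_radius_px=0.0)
        params = BehaviorParams(bout_rate_per_h=200.0, bout_duration_mean_s=2000.0)
        truth = simulate_trajectory(arena, params, 0.17, seed=12)
        stack, _ = render_frames(truth, arena, RenderParams(noise_sd=0.0), seed=12)
        det = track_stack(stack)
        best = det.sort_values("area", ascending=False).groupby("frame").first()
        err = np.hypot(
            best["x"].to_numpy() - truth.positions[best.index, 0],
            best["y"].to_numpy() - truth.positions[best.index, 1],
        )
        assert err.max() < 0.5
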