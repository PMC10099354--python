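"""Sliding-window grid geometry and probability-canvas reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maseg import tiling
from maseg.tiling import (ProbabilityCanvas, TilingConfig, accumulate,
                          compute_grid, extract_rois, finalize_map,
                          threshold_map)


def _coverage_count(plan):
    count = np.zeros(plan.image_size, dtype=int)
    w = plan.window
    for r, c in plan.origins:
        count[r:r + w, c:c + w] += 1
    return count


class TestComputeGrid:
    def test_full_frame_reference_geometry(self):
        """A 2056x2124 frame, 576px window, 30% overlap: stride 403 and one
        edge-anchored extra origin per axis, 25 windows total."""
        cfg = TilingConfig(window=576, overlap=0.30)
        assert cfg.stride == 403
        plan = compute_grid((2056, 2124), cfg)
        rows = sorted({r for r, _ in plan.origins})
        cols = sorted({c for _, c in plan.origins})
        assert rows == [0, 403, 806, 1209, 1480]
        assert cols == [0, 403, 806, 1209, 1548]
        assert len(plan) == 25
        assert (_coverage_count(plan) >= 1).all()

    def test_window_equal_to_image_gives_single_origin(self):
        for overlap in (0.0, 0.30, 0.75):
            plan = compute_grid((576, 576), TilingConfig(window=576, overlap=overlap))
            assert plan.origins == ((0, 0),)

    def test_edge_anchor_added_when_stride_overshoots(self):
        plan = compute_grid((576, 700), TilingConfig(window=576, overlap=0.30))
        assert sorted({c for _, c in plan.origins}) == [0, 124]
        assert sorted({r for r, _ in plan.origins}) == [0]
        assert len(plan) == 2

    def test_image_smaller_than_window_is_an_error(self):
        with pytest.raises(ValueError, match="smaller"):
            compute_grid((100, 700), TilingConfig(window=576))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(h=st.integers(32, 200), w=st.integers(32, 200),
           overlap=st.floats(0.0, 0.9))
    def test_coverage_property(self, h, w, overlap):
        plan = compute_grid((h, w), TilingConfig(window=32, overlap=overlap))
        assert (_coverage_count(plan) >= 1).all()
        assert len(set(plan.origins)) == len(plan.origins)

    def test_more_overlap_never_fewer_origins(self):
        counts = [len(compute_grid((500, 500), TilingConfig(window=64, overlap=o)))
                  for o in np.linspace(0.0, 0.9, 10)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestExtractRois:
    def test_all_black_image_discards_every_patch(self, caplog):
        cfg = TilingConfig(window=576, overlap=0.30)
        img = np.zeros((2056, 2124, 3), dtype=np.uint8)
        plan = compute_grid(img.shape[:2], cfg)
        assert extract_rois(img, plan, cfg) == []
        assert len(plan) == 25

    def test_single_bright_pixel_keeps_only_covering_windows(self):
        cfg = TilingConfig(window=32, overlap=0.5)
        img = np.zeros((96, 96, 3), dtype=np.uint8)
        img[0, 0] = 200
        plan = compute_grid(img.shape[:2], cfg)
        kept = extract_rois(img, plan, cfg)
        expected = [(r, c) for r, c in plan.origins
                    if r <= 0 < r + 32 and c <= 0 < c + 32]
        assert [o for o, _ in kept] == expected

    def test_value_one_pixel_survives_strict_black_rule(self):
        cfg = TilingConfig(window=32, overlap=0.0)
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[10, 10, 1] = 1
        plan = compute_grid(img.shape[:2], cfg)
        assert len(extract_rois(img, plan, cfg)) == 1

    def test_plan_image_mismatch_is_an_error(self):
        cfg = TilingConfig(window=32)
        plan = compute_grid((96, 96), cfg)
        with pytest.raises(ValueError, match="plan"):
            extract_rois(np.zeros((64, 64, 3), np.uint8), plan, cfg)


class TestCanvas:
    def test_single_patch_accumulation(self):
        canvas = ProbabilityCanvas.empty((8, 8))
        accumulate(canvas, (2, 2), np.full((4, 4), 0.7))
        assert canvas.prob_sum[2:6, 2:6] == pytest.approx(0.7)
        assert (canvas.count[2:6, 2:6] == 1).all()
        assert canvas.count.sum() == 16

    def test_overlapping_patches_add(self):
        canvas = ProbabilityCanvas.empty((4, 4))
        accumulate(canvas, (0, 0), np.full((4, 4), 0.2))
        accumulate(canvas, (0, 0), np.full((4, 4), 0.8))
        np.testing.assert_allclose(canvas.prob_sum, 1.0)
        assert (canvas.count == 2).all()

    def test_accumulation_order_is_irrelevant(self, rng):
        patches = [((int(r), int(c)), rng.uniform(size=(8, 8)))
                   for r, c in rng.integers(0, 24, size=(10, 2))]
        c1 = ProbabilityCanvas.empty((32, 32))
        c2 = ProbabilityCanvas.empty((32, 32))
        for o, p in patches:
            accumulate(c1, o, p)
        for i in rng.permutation(len(patches)):
            accumulate(c2, *patches[i])
        np.testing.assert_allclose(c1.prob_sum, c2.prob_sum)
        np.testing.assert_array_equal(c1.count, c2.count)

    def test_out_of_bounds_origin_rejected(self):
        canvas = ProbabilityCanvas.empty((8, 8))
        with pytest.raises(ValueError, match="origin"):
            accumulate(canvas, (6, 6), np.zeros((4, 4)))

    def test_finalize_averages_overlap(self):
        canvas = ProbabilityCanvas.empty((2, 2))
        for v in (0.3, 0.6, 0.9):
            accumulate(canvas, (0, 0), np.full((2, 2), v))
        np.testing.assert_allclose(finalize_map(canvas), 0.6)

    def test_finalize_rejects_uncovered_pixels(self):
        canvas = ProbabilityCanvas.empty((8, 8))
        accumulate(canvas, (0, 0), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="covering"):
            finalize_map(canvas)

    def test_round_trip_reconstructs_source_map(self, rng):
        """Patches cut from one probability map re-accumulate to that map:
        overlapping contributions are equal so their mean is the source."""
        prob = rng.uniform(size=(100, 120))
        cfg = TilingConfig(window=32, overlap=0.3)
        plan = compute_grid(prob.shape, cfg)
        canvas = ProbabilityCanvas.empty(prob.shape)
        for r, c in plan.origins:
            accumulate(canvas, (r, c), prob[r:r + 32, c:c + 32])
        np.testing.assert_allclose(finalize_map(canvas), prob, atol=1e-12)


class TestThreshold:
    def test_exact_half_is_background(self):
        out = threshold_map(np.array([[0.5, 0.51], [0.49, 1.0]]))
        np.testing.assert_array_equal(out, [[False, True], [False, True]])

    def test_all_zero_map_is_all_background(self):
        assert not threshold_map(np.zeros((5, 5))).any()

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            threshold_map(np.zeros((2, 2)), tau=1.5)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            threshold_map(np.array([[1.2]]))
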