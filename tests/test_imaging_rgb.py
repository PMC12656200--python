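"""Histogram, thresholding, grid gap analysis and cover-metric algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopysense.imaging_rgb import (
    BimodalityError,
    GapCounts,
    Histogram256,
    SkyCanopyMask,
    analytic_lai,
    binarize_sky_canopy,
    channel_histogram,
    cover_metrics,
    detect_valley_threshold,
    grid_gap_counts,
    process_frame,
)


def _frame_with_blue(blue: np.ndarray) -> np.ndarray:
    frame = np.zeros(blue.shape + (3,), dtype=np.uint8)
    frame[..., 2] = blue
    return frame


def brute_force_gap_counts(labels, rows=5, cols=5, lgf=0.75):
    """Independent nested-loop tally with the same remainder-merge rule."""
    h, w = labels.shape
    rb = h // rows
    cb = w // cols
    large = 0
    for i in range(rows):
        for j in range(cols):
            r1 = h if i == rows - 1 else (i + 1) * rb
            c1 = w if j == cols - 1 else (j + 1) * cb
            sky = 0
            size = 0
            for r in range(i * rb, r1):
                for c in range(j * cb, c1):
                    size += 1
                    sky += bool(labels[r, c])
            if sky >= lgf * size:
                large += sky
    return int(labels.sum()), large


class TestChannelHistogram:
    def test_uniform_image(self):
        frame = _frame_with_blue(np.full((10, 10), 100, dtype=np.uint8))
        hist = channel_histogram(frame, "blue")
        assert hist.counts[100] == 100
        assert hist.counts.sum() == 100

    def test_two_tone(self):
        blue = np.full(100, 220, dtype=np.uint8)
        blue[:30] = 50
        hist = channel_histogram(_frame_with_blue(blue.reshape(10, 10)), "blue")
        assert hist.counts[50] == 30 and hist.counts[220] == 70

    def test_matches_per_pixel_tally(self, rng):
        frame = rng.integers(0, 256, (17, 23, 3), dtype=np.uint8)
        for channel, idx in (("red", 0), ("green", 1), ("blue", 2)):
            hist = channel_histogram(frame, channel)
            expected = np.zeros(256, dtype=int)
            for r in range(17):
                for c in range(23):
                    expected[frame[r, c, idx]] += 1
            assert np.array_equal(hist.counts, expected)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            channel_histogram(np.empty((0, 0, 3), dtype=np.uint8))


class TestValleyThreshold:
    def test_gaussian_mixture_valley(self, rng):
        draws = np.concatenate(
            [rng.normal(80, 10, 5000), rng.normal(200, 10, 5000)]
        )
        counts = np.bincount(
            np.clip(np.round(draws), 0, 255).astype(int), minlength=256
        )
        thr = detect_valley_threshold(Histogram256(counts, "blue"))
        assert 110 <= thr <= 170

    def test_flat_valley_tie_breaks_low(self):
        counts = np.zeros(256, dtype=int)
        counts[50], counts[220] = 30, 70
        thr = detect_valley_threshold(Histogram256(counts, "blue"))
        assert thr == 51

    def test_unimodal_raises(self):
        counts = np.zeros(256, dtype=int)
        counts[100:140] = 50
        with pytest.raises(BimodalityError):
            detect_valley_threshold(Histogram256(counts, "blue"))


class TestBinarize:
    @pytest.mark.parametrize("blue,expected_sky", [(255, True), (0, False)])
    def test_saturated_frames(self, blue, expected_sky):
        mask = binarize_sky_canopy(
            _frame_with_blue(np.full((8, 8), blue, dtype=np.uint8)), 128
        )
        assert mask.labels.all() == expected_sky
        assert mask.threshold_used == 128

    def test_matches_per_pixel_comparison(self, rng):
        frame = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        mask = binarize_sky_canopy(frame, 130)
        assert np.array_equal(mask.labels, frame[..., 2] > 130)

    def test_pixel_conservation(self, rng):
        frame = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        mask = binarize_sky_canopy(frame, 100)
        assert mask.labels.sum() + (~mask.labels).sum() == 400


class TestGridGapCounts:
    def test_all_sky(self):
        mask = SkyCanopyMask(np.ones((100, 100), bool), 128)
        gc = grid_gap_counts(mask)
        assert gc.gap_pixels_total == 10000 and gc.large_gap_pixels == 10000

    def test_all_canopy(self):
        mask = SkyCanopyMask(np.zeros((100, 100), bool), 128)
        gc = grid_gap_counts(mask)
        assert gc.gap_pixels_total == 0 and gc.large_gap_pixels == 0

    def test_one_open_subimage(self):
        labels = np.zeros((100, 100), bool)
        labels[20:40, 40:60] = True  # exactly one 20x20 grid cell
        gc = grid_gap_counts(SkyCanopyMask(labels, 128))
        assert gc.gap_pixels_total == 400 and gc.large_gap_pixels == 400

    @pytest.mark.parametrize("shape", [(100, 100), (103, 97), (57, 200)])
    def test_matches_bruteforce_on_random_masks(self, shape, rng):
        for _ in range(3):
            labels = rng.random(shape) < rng.uniform(0.2, 0.9)
            gc = grid_gap_counts(SkyCanopyMask(labels, 0))
            gap, large = brute_force_gap_counts(labels)
            assert (gc.gap_pixels_total, gc.large_gap_pixels) == (gap, large)
            assert gc.large_gap_pixels <= gc.gap_pixels_total <= gc.total_pixels

    def test_too_small_mask_rejected(self):
        with pytest.raises(ValueError):
            grid_gap_counts(SkyCanopyMask(np.ones((3, 3), bool), 0))


class TestCoverMetrics:
    def test_open_sky_gives_zero_lai(self):
        gc = GapCounts(10000, 10000, 10000, 5, 5, 0.75)
        cm = cover_metrics(gc)
        assert cm.lai == 0.0 and cm.laie == 0.0

    def test_worked_example(self):
        # fc=0.8, ff=0.56 -> phi=0.3; Beer-Lambert and clumping by hand
        gc = GapCounts(10000, 4400, 2000, 5, 5, 0.75)
        cm = cover_metrics(gc, k=0.5)
        assert cm.ff == pytest.approx(0.56)
        assert cm.fc == pytest.approx(0.8)
        assert cm.phi == pytest.approx(0.3)
        assert cm.lai == pytest.approx(1.926, abs=5e-3)
        assert cm.omega0 == pytest.approx(0.852, abs=5e-3)
        assert cm.laie == pytest.approx(1.642, abs=5e-3)

    def test_closed_canopy_limit(self):
        # ff -> 0 with fc > 0: phi clamps near 1 and LAI collapses to ~0
        gc = GapCounts(10000, 9999, 5000, 5, 5, 0.75)
        cm = cover_metrics(gc)
        assert cm.phi == pytest.approx(1.0, abs=1e-3)
        assert cm.lai < 0.01

    def test_zero_pixels_rejected(self):
        with pytest.raises(ValueError):
            cover_metrics(GapCounts(0, 0, 0, 5, 5, 0.75))

    @given(
        total=st.integers(100, 10_000),
        gap_frac=st.floats(0.05, 0.95),
        large_frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_identities(self, total, gap_frac, large_frac):
        """laie = lai * omega0 and ff = fc (1 - phi) hold for any tallies."""
        gap = int(gap_frac * total)
        large = int(large_frac * gap)
        cm = cover_metrics(GapCounts(total, gap, large, 5, 5, 0.75))
        assert cm.laie == pytest.approx(cm.lai * cm.omega0, abs=1e-10)
        if 1e-3 < cm.phi < 1 - 1e-3:  # identity only meaningful unclamped
            assert cm.ff == pytest.approx(cm.fc * (1 - cm.phi), abs=1e-10)

    def test_lai_decreases_with_porosity(self):
        fc = 0.7
        lais = [analytic_lai(fc, phi) for phi in np.linspace(0.1, 0.9, 9)]
        assert all(a > b for a, b in zip(lais, lais[1:]))

    def test_laie_below_lai_when_clumped(self):
        gc = GapCounts(10000, 4400, 2000, 5, 5, 0.75)
        cm = cover_metrics(gc)
        assert cm.omega0 <= 1 and cm.laie <= cm.lai


class TestFullFrameRecovery:
    def test_synthetic_scene_recovery(self, small_scene):
        rgb, truth = small_scene
        thr, cm = process_frame(rgb)
        assert abs(cm.fc - truth.fc) <= 0.03
        analytic = analytic_lai(truth.fc, truth.phi)
        assert abs(cm.lai - analytic) / max(analytic, 0.1) <= 0.10

    def test_manual_threshold_respected(self, small_scene):
        rgb, _ = small_scene
        thr, _ = process_frame(rgb, threshold=140)
        assert thr == 140
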