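"""LAFM reconstruction: interpolation, peak detection, probability contracts."""

import numpy as np
import pytest

from lafmkit.lafm import LAFMParams, compose_lafm, detect_peaks, expand, render_peaks
from lafmkit.simafm import AtomSet, ImageStack, ScanGrid, TipModel, render_stack


def _gaussian_bump(shape=(21, 21), center=(10, 10), sigma=3.0, height=8.0):
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return height * np.exp(-((r - center[0]) ** 2 + (c - center[1]) ** 2) / (2 * sigma**2))


class TestExpand:
    def test_factor_one_is_identity(self):
        img = np.random.default_rng(0).random((8, 8))
        np.testing.assert_array_equal(expand(img, 1), img)

    def test_constant_image_is_preserved(self):
        img = np.full((6, 6), 3.7)
        np.testing.assert_allclose(expand(img, 4), 3.7, atol=1e-12)

    def test_linear_ramp_reproduced_at_interior_samples(self):
        # bicubic splines reproduce degree-1 polynomials; the mirror-boundary
        # kink influence decays geometrically (~0.268^k per input sample), so
        # compare away from the border
        h = w = 32
        f = 3
        ramp = 0.5 * np.arange(h)[:, None] + 0.25 * np.arange(w)[None, :] + 1.0
        out = expand(ramp, f)
        # corner-aligned: output pixel j samples input coordinate j / f
        rows = np.arange(h * f) / f
        cols = np.arange(w * f) / f
        analytic = 0.5 * rows[:, None] + 0.25 * cols[None, :] + 1.0
        interior = np.s_[10 * f : -10 * f, 10 * f : -10 * f]
        np.testing.assert_allclose(out[interior], analytic[interior], atol=1e-6)

    def test_original_samples_survive_expansion_exactly(self):
        img = np.random.default_rng(1).random((9, 9)) * 5.0
        out = expand(img, 3)
        np.testing.assert_allclose(out[::3, ::3], img, atol=1e-9)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            expand(np.zeros((4, 4)), 0)


class TestDetectPeaks:
    def test_single_bump_yields_one_peak_at_argmax(self):
        img = _gaussian_bump()
        peaks = detect_peaks(img)
        assert peaks.shape[0] == 1
        assert tuple(peaks[0, :2].astype(int)) == (10, 10)
        assert peaks[0, 2] == pytest.approx(img.max())

    def test_constant_image_has_no_strict_maxima(self):
        assert detect_peaks(np.full((10, 10), 2.0)).shape[0] == 0

    def test_two_separated_bumps_match_exhaustive_scan(self):
        img = _gaussian_bump((31, 31), (7, 7), 2.0) + _gaussian_bump((31, 31), (22, 24), 2.0)
        peaks = detect_peaks(img, min_peak_height=0.1)
        # exhaustive neighborhood-scan oracle
        expected = []
        for r in range(1, 30):
            for c in range(1, 30):
                nb = img[r - 1 : r + 2, c - 1 : c + 2].copy()
                v = nb[1, 1]
                nb[1, 1] = -np.inf
                if v > nb.max() and v > 0.1:
                    expected.append((r, c))
        assert sorted(map(tuple, peaks[:, :2].astype(int))) == sorted(expected)
        assert peaks.shape[0] == 2

    def test_floor_suppresses_low_peaks(self):
        img = _gaussian_bump(height=1.0)
        assert detect_peaks(img, min_peak_height=2.0).shape[0] == 0

    def test_border_pixels_excluded(self):
        img = np.zeros((8, 8))
        img[0, 3] = 5.0  # maximum on the border
        assert detect_peaks(img).shape[0] == 0


class TestRenderPeaks:
    def test_peak_at_stack_max_renders_amplitude_one(self):
        out = render_peaks(np.array([[5, 5, 10.0]]), 10.0, (11, 11), 1.5)
        assert out[5, 5] == pytest.approx(1.0)

    def test_no_peaks_renders_zero_frame(self):
        assert np.all(render_peaks(np.empty((0, 3)), 10.0, (8, 8), 1.5) == 0.0)

    def test_half_height_peak_follows_gaussian_decay(self):
        sigma = 2.0
        out = render_peaks(np.array([[8, 8, 5.0]]), 10.0, (17, 17), sigma)
        assert out[8, 8] == pytest.approx(0.5)
        for s in (1, 2, 3):
            assert out[8, 8 + s] == pytest.approx(0.5 * np.exp(-(s**2) / (2 * sigma**2)))

    def test_overlapping_peaks_combine_by_maximum(self):
        peaks = np.array([[5, 5, 10.0], [5, 7, 10.0]])
        out = render_peaks(peaks, 10.0, (11, 11), 2.0)
        assert out.max() <= 1.0 + 1e-12

    def test_degenerate_stack_max_rejected(self):
        with pytest.raises(ValueError):
            render_peaks(np.array([[5, 5, 1.0]]), 0.0, (8, 8), 1.0)


class TestComposeLAFM:
    def _single_peak_stack(self, n=5, height=6.0):
        img = _gaussian_bump((16, 16), (8, 8), 2.0, height)
        return ImageStack(np.stack([img] * n).astype(np.float32), 4.0)

    def test_identical_frames_give_single_frame_probability(self):
        stack = self._single_peak_stack()
        out = compose_lafm(stack, LAFMParams(expansion_factor=2))
        assert out.probability_map.max() == pytest.approx(1.0, abs=1e-3)
        assert out.probability_map.min() >= 0.0
        assert out.probability_map.max() <= 1.0

    def test_alternating_peaks_average_to_half(self):
        a = _gaussian_bump((24, 24), (6, 6), 1.5, 8.0)
        b = _gaussian_bump((24, 24), (18, 18), 1.5, 8.0)
        stack = ImageStack(np.stack([a, b]).astype(np.float32), 4.0)
        out = compose_lafm(stack, LAFMParams(expansion_factor=1, kernel_sigma=1.0))
        assert out.probability_map[6, 6] == pytest.approx(0.5, abs=0.02)
        assert out.probability_map[18, 18] == pytest.approx(0.5, abs=0.02)

    def test_all_zero_stack_degenerates_to_zero_image(self):
        stack = ImageStack(np.zeros((3, 8, 8), dtype=np.float32), 4.0)
        out = compose_lafm(stack)
        assert np.all(out.values == 0.0)
        assert np.all(out.probability_map == 0.0)

    def test_frame_permutation_invariance_is_bitwise(self):
        rng = np.random.default_rng(3)
        frames = np.stack([_gaussian_bump((16, 16), (8 + rng.integers(-2, 3), 8), 2.0, 6.0)
                           for _ in range(6)])
        stack = ImageStack(frames.astype(np.float32), 4.0)
        perm = rng.permutation(6)
        shuffled = ImageStack(frames[perm].astype(np.float32), 4.0)
        a = compose_lafm(stack)
        b = compose_lafm(shuffled)
        np.testing.assert_array_equal(a.values, b.values)

    def test_values_equal_probability_times_mean_height(self):
        stack = self._single_peak_stack()
        out = compose_lafm(stack)
        np.testing.assert_allclose(out.values, out.probability_map * out.mean_height_map)
        assert np.all(out.values <= out.mean_height_map + 1e-12)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            compose_lafm(ImageStack(np.zeros((0, 8, 8), dtype=np.float32), 4.0))

    def test_localization_beats_pixel_grid(self):
        # a single atom fluctuating sub-pixel: the LAFM argmax localizes its
        # mean position within one expanded pixel
        rng = np.random.default_rng(5)
        grid = ScanGrid.centered(10.0, 2.0)
        tip = TipModel(20.0)
        true_xy = np.array([0.35, -0.42])  # Å, sub-pixel at 2 Å/px
        frames = []
        for _ in range(60):
            xy = true_xy + rng.normal(0.0, 0.5, 2)
            frames.append(AtomSet(np.array([[xy[0], xy[1], 6.0]]), np.array([2.0]), 0.0))
        stack = render_stack(frames, tip, grid)
        f = 5
        out = compose_lafm(stack, LAFMParams(expansion_factor=f, kernel_sigma=1.5))
        r, c = np.unravel_index(np.argmax(out.values), out.values.shape)
        ex_pix = 2.0 / f
        # corner-aligned expansion: expanded sample j sits at input pixel j/f
        x = grid.x_min + (c / f + 0.5) * 2.0
        y = grid.y_min + (r / f + 0.5) * 2.0
        assert abs(x - true_xy[0]) <= ex_pix
        assert abs(y - true_xy[1]) <= ex_pix
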