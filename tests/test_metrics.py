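"""Masked SSIM, weighted loss, quality profiles, Jaccard consistency."""

import numpy as np
import pytest

from lafmkit.lafm import LAFMParams, compose_lafm
from lafmkit.metrics import (
    MaskSpec,
    SSIMConfig,
    jaccard_consistency,
    masked_ssim,
    pair_mask,
    quality_profile,
    ssim_map,
    weighted_ssim_loss,
)
from lafmkit.simafm import ImageStack


def _blob(shape, center, sigma, height):
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return height * np.exp(-((r - center[0]) ** 2 + (c - center[1]) ** 2) / (2 * sigma**2))


@pytest.fixture
def pair():
    x = _blob((32, 32), (14, 14), 4.0, 10.0)
    y = _blob((32, 32), (17, 15), 4.0, 9.0)
    return x, y


class TestSSIMMap:
    def test_self_similarity_is_one_everywhere(self, pair):
        x, _ = pair
        np.testing.assert_allclose(ssim_map(x, x), 1.0, atol=1e-12)

    def test_constant_offset_matches_closed_form(self):
        c1v, offset, L = 4.0, 1.0, 10.0
        x = np.full((24, 24), c1v)
        y = x + offset
        cfg = SSIMConfig(data_range=L)
        m = ssim_map(x, y, cfg)
        C1 = (cfg.K1 * L) ** 2
        expected = (2 * c1v * (c1v + offset) + C1) / (c1v**2 + (c1v + offset) ** 2 + C1)
        np.testing.assert_allclose(m, expected, atol=1e-10)
        assert m.max() < 1.0

    def test_bounded_even_for_anticorrelated_patches(self):
        rng = np.random.default_rng(0)
        x = rng.random((20, 20))
        y = x.max() - x  # anti-correlated
        m = ssim_map(x, y)
        assert m.min() >= -1.0 - 1e-12 and m.max() <= 1.0 + 1e-12
        assert m.min() < 0  # locally negative somewhere

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim_map(np.zeros((4, 4)), np.zeros((5, 5)))


class TestMaskedSSIM:
    def test_self_score_is_exactly_one(self, pair):
        x, _ = pair
        assert masked_ssim(x, x) == 1.0

    def test_symmetry(self, pair):
        x, y = pair
        assert masked_ssim(x, y) == pytest.approx(masked_ssim(y, x), abs=1e-12)

    def test_threshold_is_five_percent_of_pair_max(self, pair):
        x, y = pair  # pair max 10 Å -> threshold 0.5 Å
        m = pair_mask(x, y, MaskSpec())
        expected = (x > 0.5) | (y > 0.5)
        np.testing.assert_array_equal(m, expected)

    def test_matches_direct_recomputation_oracle(self):
        # two disjoint single-blob images: recompute mean-over-mask by hand
        x = _blob((40, 40), (10, 10), 3.0, 8.0)
        y = _blob((40, 40), (30, 30), 3.0, 6.0)
        cfg, spec = SSIMConfig(), MaskSpec()
        score = masked_ssim(x, y, cfg, spec)
        thr = 0.05 * max(x.max(), y.max())
        mask = (x > thr) | (y > thr)
        oracle = ssim_map(x, y, cfg)[mask].mean()
        assert score == pytest.approx(oracle, abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            masked_ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestWeightedLoss:
    def test_perfect_reconstruction_gives_zero(self, pair):
        x, _ = pair
        assert weighted_ssim_loss(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_only_reduces_to_global_term(self, pair):
        x, y = pair
        loss = weighted_ssim_loss(x, y, alpha=1.0, beta=0.0)
        assert loss == pytest.approx(1.0 - ssim_map(x, y).mean(), abs=1e-12)

    def test_equal_weights_recompose_from_parts(self, pair):
        x, y = pair
        loss = weighted_ssim_loss(x, y, alpha=0.5, beta=0.5)
        expected = 1.0 - 0.5 * (ssim_map(x, y).mean() + masked_ssim(x, y))
        assert loss == pytest.approx(expected, abs=1e-12)

    def test_normalization_makes_weight_scale_irrelevant(self, pair):
        x, y = pair
        assert weighted_ssim_loss(x, y, 0.5, 0.5) == pytest.approx(
            weighted_ssim_loss(x, y, 1.0, 1.0), abs=1e-12
        )

    def test_zero_weights_rejected(self, pair):
        x, y = pair
        with pytest.raises(ValueError):
            weighted_ssim_loss(x, y, 0.0, 0.0)


class TestQualityProfile:
    def _stack(self, rng, blur):
        from scipy.ndimage import gaussian_filter

        frames = []
        for _ in range(6):
            img = _blob((24, 24), (12 + rng.normal(0, 0.6), 12 + rng.normal(0, 0.6)), 2.0, 8.0)
            frames.append(gaussian_filter(img, blur) if blur else img)
        return ImageStack(np.stack(frames).astype(np.float32), 2.0)

    def test_benchmark_against_itself_scores_one_cell(self):
        rng = np.random.default_rng(1)
        stack = self._stack(rng, 0.0)
        params = LAFMParams(expansion_factor=2)
        bench = compose_lafm(stack, params)
        prof = quality_profile({(2.0, 2.0): stack}, bench, params)
        assert prof.scores[(2.0, 2.0)] == pytest.approx(1.0, abs=1e-9)

    def test_score_degrades_with_blur_and_equals_standalone_call(self):
        rng = np.random.default_rng(2)
        clean = self._stack(rng, 0.0)
        params = LAFMParams(expansion_factor=2)
        bench = compose_lafm(clean, params)
        stacks = {(2.0, 2.0): clean,
                  (10.0, 2.0): self._stack(np.random.default_rng(2), 1.0),
                  (20.0, 2.0): self._stack(np.random.default_rng(2), 2.5)}
        prof = quality_profile(stacks, bench, params)
        s = prof.scores
        assert s[(2.0, 2.0)] >= s[(10.0, 2.0)] >= s[(20.0, 2.0)]
        standalone = masked_ssim(compose_lafm(stacks[(10.0, 2.0)], params).values, bench.values)
        assert s[(10.0, 2.0)] == pytest.approx(standalone, abs=1e-12)


class TestJaccard:
    def test_identical_labelings_score_one(self):
        labels = np.repeat([0, 1, 2], 50)
        assert all(v == 1.0 for v in jaccard_consistency(labels, labels).values())

    def test_swapped_ids_score_one_after_matching(self):
        a = np.repeat([0, 1], 50)
        b = np.repeat([1, 0], 50)
        assert all(v == 1.0 for v in jaccard_consistency(a, b).values())

    def test_single_moved_frame_counts(self):
        a = np.repeat([0, 1], 100)
        b = a.copy()
        b[0] = 1  # one frame moves cluster 0 -> 1
        # cluster 0: intersection 99 of union 100; cluster 1: 100 of 101
        ji = jaccard_consistency(a, b)
        assert ji[0] == pytest.approx(99 / 100)
        assert ji[1] == pytest.approx(100 / 101)

    def test_empty_labelings_rejected(self):
        with pytest.raises(ValueError):
            jaccard_consistency(np.array([]), np.array([]))
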