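"""Image similarity metrics for AFM/LAFM comparison.

Topographs have a large, perfectly flat zero background; a plain SSIM over
the whole image is dominated by trivially identical background and inflates
similarity.  The masked SSIM used here computes a standard local-statistics
SSIM map, then averages only over pixels where either image exceeds a small
fraction (default 5%) of the pair's maximum height — the protein footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .lafm import LAFMImage, compose_lafm
from .simafm import ImageStack

__all__ = [
    "SSIMConfig",
    "MaskSpec",
    "QualityProfile",
    "ssim_map",
    "masked_ssim",
    "weighted_ssim_loss",
    "quality_profile",
    "jaccard_consistency",
]


@dataclass(frozen=True)
class SSIMConfig:
    """Standard SSIM internals (literature defaults), all overridable."""

    window: int = 11
    window_sigma: float = 1.5
    K1: float = 0.01
    K2: float = 0.03
    data_range: float | None = None  # default: max over the compared pair

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("K1, K2 must be positive")


@dataclass(frozen=True)
class MaskSpec:
    threshold_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1)")


@dataclass
class QualityProfile:
    """Masked-SSIM scores of LAFM images indexed by (tip radius R, pixel size P)."""

    scores: dict  # (R, P) -> score
    benchmark_code: str | None = None
    bands: tuple[float, float, float] = (0.9, 0.7, 0.5)  # very good / good / acceptable

    def as_rows(self) -> list[tuple[float, float, float]]:
        return [(r, p, s) for (r, p), s in sorted(self.scores.items())]


def _resolve_range(x: np.ndarray, y: np.ndarray, cfg: SSIMConfig) -> float:
    if cfg.data_range is not None:
        return cfg.data_range
    dr = float(max(x.max(), y.max()))
    return dr if dr > 0 else 1.0


def ssim_map(x: np.ndarray, y: np.ndarray, cfg: SSIMConfig = SSIMConfig()) -> np.ndarray:
    """Per-pixel SSIM map (Gaussian-weighted local statistics)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must have the same shape")
    _, smap = structural_similarity(
        x,
        y,
        win_size=cfg.window,
        gaussian_weights=True,
        sigma=cfg.window_sigma,
        K1=cfg.K1,
        K2=cfg.K2,
        data_range=_resolve_range(x, y, cfg),
        use_sample_covariance=False,
        full=True,
    )
    return smap


def pair_mask(x: np.ndarray, y: np.ndarray, mask: MaskSpec = MaskSpec()) -> np.ndarray:
    """Foreground mask: pixels above the threshold in either image."""
    t = mask.threshold_fraction * float(max(x.max(), y.max()))
    return (x > t) | (y > t)


def masked_ssim(
    x: np.ndarray,
    y: np.ndarray,
    cfg: SSIMConfig = SSIMConfig(),
    mask: MaskSpec = MaskSpec(),
) -> float:
    """Mean SSIM over the protein-footprint mask; in [-1, 1]."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must have the same shape")
    m = pair_mask(x, y, mask)
    if not m.any():
        raise ValueError("empty mask: no pixel above the foreground threshold")
    return float(ssim_map(x, y, cfg)[m].mean())


def weighted_ssim_loss(
    x: np.ndarray,
    x_rec: np.ndarray,
    alpha: float = 0.5,
    beta: float = 0.5,
    cfg: SSIMConfig = SSIMConfig(),
    mask: MaskSpec = MaskSpec(),
) -> float:
    """Reconstruction loss 1 - (α·SSIM + β·SSIM_masked) / (α + β).

    The global term keeps the background faithful; the masked term focuses
    on protein features.  Normalizing by α+β makes equal weights at any
    scale agree and keeps the loss in [0, 2] with 0 iff SSIM-perfect.
    """
    if alpha < 0 or beta < 0 or alpha + beta == 0:
        raise ValueError("weights must be >= 0 with alpha + beta > 0")
    total = 0.0
    if alpha > 0:
        total += alpha * float(ssim_map(x, x_rec, cfg).mean())
    if beta > 0:
        total += beta * masked_ssim(x, x_rec, cfg, mask)
    return 1.0 - total / (alpha + beta)


def quality_profile(
    stacks: Mapping[tuple[float, float], ImageStack],
    benchmark: LAFMImage,
    lafm_params=None,
    cfg: SSIMConfig = SSIMConfig(),
    mask: MaskSpec = MaskSpec(),
    benchmark_code: str | None = None,
) -> QualityProfile:
    """Masked-SSIM of each stack's LAFM against a finest-grid benchmark.

    Every stack is reconstructed, bicubically resampled onto the benchmark
    grid (the stacks must share physical scan bounds), and scored.
    """
    from .lafm import LAFMParams

    if lafm_params is None:
        lafm_params = LAFMParams()
    bench = benchmark.values
    scores = {}
    for (r, p), stack in stacks.items():
        img = compose_lafm(stack, lafm_params).values
        if img.shape != bench.shape:
            img = np.maximum(
                resize(img, bench.shape, order=3, mode="edge", anti_aliasing=False,
                       preserve_range=True),
                0.0,
            )
        scores[(r, p)] = masked_ssim(img, bench, cfg, mask)
    return QualityProfile(scores=scores, benchmark_code=benchmark_code)


def jaccard_consistency(labels_a, labels_b) -> dict[int, float]:
    """Per-cluster Jaccard indices between two labelings of the same frames.

    Clusters are matched greedily by maximal overlap (label identities are
    arbitrary); returns {cluster_id_in_a: |A∩B| / |A∪B| of its match}.
    Unmatched clusters score 0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty labelings")
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same frames")
    ids_a, ids_b = np.unique(a), np.unique(b)
    overlaps = []
    for ia in ids_a:
        for ib in ids_b:
            inter = int(np.sum((a == ia) & (b == ib)))
            if inter:
                overlaps.append((inter, ia, ib))
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b = set(), set()
    out = {int(ia): 0.0 for ia in ids_a}
    for inter, ia, ib in overlaps:
        if ia in used_a or ib in used_b:
            continue
        union = int(np.sum((a == ia) | (b == ib)))
        out[int(ia)] = inter / union
        used_a.add(ia)
        used_b.add(ib)
    return out
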