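"""Hierarchical deep spectral clustering (HDSC).

An MD-like stack contains both metastable conformations and transient
frames recorded mid-transition.  HDSC peels off stable conformational
clusters iteratively: cluster the (remaining) stack at n = 2 and build a
LAFM image per cluster; if the two LAFM images are near-identical
(masked SSIM at or above the stability threshold) the split was spurious —
merge and halt.  Otherwise recluster the same affinity matrix at n = 3 and
cross-compare the n = 3 LAFM images with the n = 2 ones: an n = 3 cluster
whose LAFM matches an n = 2 LAFM represents a conformation that survived
the refinement and is emitted, its frames removed.  The loop repeats on
the reduced stack and affinity submatrix until nothing stable remains or
too few frames are left.  Emitted clusters at or above the minimum
cluster size are stable conformations; smaller ones are transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dsc import CAEConfig, ClusterSet, dsc, spectral_cluster
from .lafm import LAFMImage, LAFMParams, compose_lafm
from .metrics import MaskSpec, SSIMConfig, masked_ssim
from .simafm import ImageStack

__all__ = [
    "HDSCConfig",
    "EmittedCluster",
    "HDSCResult",
    "hdsc",
    "classify_stability",
    "occupancy_series",
]


@dataclass(frozen=True)
class HDSCConfig:
    stable_match_threshold: float = 0.8
    min_cluster_size: float = 0.05  # int (frames) or fraction of the stack
    max_rounds: int = 10
    lafm_params: LAFMParams = field(default_factory=LAFMParams)
    cae: CAEConfig = field(default_factory=CAEConfig)
    retrain_per_round: bool = False
    ssim: SSIMConfig = field(default_factory=SSIMConfig)
    mask: MaskSpec = field(default_factory=MaskSpec)

    def __post_init__(self) -> None:
        if not 0.0 < self.stable_match_threshold < 1.0:
            raise ValueError("stable_match_threshold must lie in (0, 1)")
        if self.min_cluster_size <= 0:
            raise ValueError("min_cluster_size must be positive")

    def resolve_min_size(self, n_frames: int) -> int:
        if self.min_cluster_size < 1:
            return max(int(np.ceil(self.min_cluster_size * n_frames)), 1)
        return int(self.min_cluster_size)


@dataclass
class EmittedCluster:
    frames: np.ndarray  # original stack indices
    lafm: LAFMImage
    stable: bool
    round_index: int


@dataclass
class HDSCResult:
    clusters: list[EmittedCluster]
    residual: np.ndarray  # original stack indices never emitted
    audit: list[dict]

    @property
    def stable_clusters(self) -> list[EmittedCluster]:
        return [c for c in self.clusters if c.stable]

    def labels(self, n_frames: int) -> np.ndarray:
        """Per-frame labels: cluster index, or -1 for residual frames."""
        lab = np.full(n_frames, -1, dtype=int)
        for i, c in enumerate(self.clusters):
            lab[c.frames] = i
        return lab


def classify_stability(member_count: int, min_cluster_size: int) -> str:
    """A cluster is stable iff its population reaches the minimum size."""
    return "stable" if member_count >= min_cluster_size else "transient"


def occupancy_series(labels: np.ndarray, bin_width: int) -> np.ndarray:
    """Per-bin occupancy counts per cluster over a trajectory-ordered labeling.

    Returns (n_bins, n_labels) counts; label ids are the sorted unique
    labels.  Bins partition the frame axis (last bin may be shorter).
    """
    if bin_width < 1:
        raise ValueError("bin width must be >= 1")
    labels = np.asarray(labels)
    ids = np.unique(labels)
    n_bins = int(np.ceil(labels.size / bin_width))
    out = np.zeros((n_bins, ids.size), dtype=int)
    for b in range(n_bins):
        chunk = labels[b * bin_width : (b + 1) * bin_width]
        for j, i in enumerate(ids):
            out[b, j] = int(np.sum(chunk == i))
    return out


def _sub_stack(stack: ImageStack, idx: np.ndarray) -> ImageStack:
    sub = ImageStack(stack.heights[idx], stack.pixel_size, code=stack.code)
    sub.meta = dict(stack.meta)
    return sub


def _cluster_lafms(
    stack: ImageStack, idx: np.ndarray, clusters: ClusterSet, cfg: HDSCConfig
) -> list[LAFMImage]:
    return [
        compose_lafm(_sub_stack(stack, idx[clusters.members(c)]), cfg.lafm_params)
        for c in range(clusters.n)
    ]


def hdsc(stack: ImageStack, cfg: HDSCConfig = HDSCConfig()) -> HDSCResult:
    """Iteratively extract conformational clusters from an aligned stack."""
    n_frames = len(stack)
    min_size = cfg.resolve_min_size(n_frames)
    if n_frames < 2 * min_size:
        raise ValueError("stack too small for the configured minimum cluster size")

    # one CAE/affinity for the whole stack; submatrices are reused per round
    result = dsc(stack, 2, cfg.cae)
    affinity = result.affinity

    residual = np.arange(n_frames)
    emitted: list[EmittedCluster] = []
    audit: list[dict] = []

    for round_index in range(cfg.max_rounds):
        if residual.size < max(2 * min_size, cfg.cae.k_scale + 2):
            audit.append({"round": round_index, "event": "halt_residual_too_small",
                          "residual": int(residual.size)})
            break
        if cfg.retrain_per_round and round_index > 0:
            sub_res = dsc(_sub_stack(stack, residual), 2, cfg.cae)
            sub_aff = sub_res.affinity
        else:
            sub_aff = affinity[np.ix_(residual, residual)]

        c2 = spectral_cluster(sub_aff, 2, cfg.cae.seed)
        lafm2 = _cluster_lafms(stack, residual, c2, cfg)
        pair_score = masked_ssim(lafm2[0].values, lafm2[1].values, cfg.ssim, cfg.mask)
        if pair_score >= cfg.stable_match_threshold:
            # spurious split: combine and halt
            lafm_all = compose_lafm(_sub_stack(stack, residual), cfg.lafm_params)
            emitted.append(EmittedCluster(
                frames=residual.copy(), lafm=lafm_all,
                stable=classify_stability(residual.size, min_size) == "stable",
                round_index=round_index,
            ))
            audit.append({"round": round_index, "event": "merge_and_halt",
                          "pair_ssim": pair_score})
            residual = np.array([], dtype=int)
            break

        c3 = spectral_cluster(sub_aff, 3, cfg.cae.seed)
        lafm3 = _cluster_lafms(stack, residual, c3, cfg)
        # cross-compare: greedy best pair; each n=2 LAFM certifies <= 1 cluster
        scores = [
            (masked_ssim(lafm3[i].values, lafm2[j].values, cfg.ssim, cfg.mask), i, j)
            for i in range(c3.n)
            for j in range(c2.n)
        ]
        scores.sort(key=lambda t: -t[0])
        used3: set[int] = set()
        used2: set[int] = set()
        matched: list[tuple[int, float]] = []
        for score, i, j in scores:
            if score < cfg.stable_match_threshold or i in used3 or j in used2:
                continue
            used3.add(i)
            used2.add(j)
            matched.append((i, score))
        audit.append({
            "round": round_index, "event": "cross_compare",
            "pair_ssim_n2": pair_score,
            "scores": [(round(s, 4), i, j) for s, i, j in scores],
            "matched": [(i, round(s, 4)) for i, s in matched],
        })
        if not matched:
            audit.append({"round": round_index, "event": "halt_no_stable"})
            break
        remove_mask = np.zeros(residual.size, dtype=bool)
        for i, score in matched:
            members = c3.members(i)
            emitted.append(EmittedCluster(
                frames=residual[members], lafm=lafm3[i],
                stable=classify_stability(members.size, min_size) == "stable",
                round_index=round_index,
            ))
            remove_mask[members] = True
        residual = residual[~remove_mask]

    return HDSCResult(clusters=emitted, residual=residual, audit=audit)
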