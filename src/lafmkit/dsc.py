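"""Deep spectral clustering (DSC) of AFM image stacks.

A convolutional autoencoder is trained on the stack (rescaled to [0, 1] by
the global stack maximum) with a weighted 1-SSIM reconstruction loss; the
encoder's latent feature vectors (LFVs) are compared pairwise with a
locally scaled affinity

    A_ij = exp(-d(i, j)**2 / (sigma_i * sigma_j)),

where d is the Euclidean LFV distance and sigma_i is the distance from
frame i to its k-th nearest neighbor (self-tuning scaling, k = 7 by
default).  Spectral clustering of A yields the conformational labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import SpectralClustering

from .nn import CAE
from .simafm import ImageStack

__all__ = [
    "CAEConfig",
    "ClusterSet",
    "DSCResult",
    "train_cae",
    "extract_lfv",
    "local_affinity",
    "spectral_cluster",
    "dsc",
]


@dataclass(frozen=True)
class CAEConfig:
    """Autoencoder and clustering hyperparameters (one seed drives all RNG)."""

    latent_dim: int = 64
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    epochs: int = 25
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    loss: str = "ssim"
    loss_weights: tuple[float, float] = (0.5, 0.5)
    k_scale: int = 7

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ClusterSet:
    """Partition of frame indices into n nonempty clusters."""

    n: int
    labels: np.ndarray  # per-frame label in [0, n)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n)


@dataclass
class DSCResult:
    clusters: ClusterSet
    lfv: np.ndarray
    affinity: np.ndarray
    cae: CAE
    config: CAEConfig = field(repr=False, default=None)


def _normalize(stack: ImageStack) -> np.ndarray:
    m = stack.max_height()
    imgs = stack.heights.astype(np.float64)
    return imgs / m if m > 0 else imgs


def train_cae(stack: ImageStack, cfg: CAEConfig = CAEConfig()) -> CAE:
    """Train the autoencoder on a stack; deterministic given cfg.seed."""
    imgs = _normalize(stack)
    if len(stack) < 1:
        raise ValueError("empty stack")
    cae = CAE(
        imgs.shape[1:],
        latent_dim=cfg.latent_dim,
        conv_channels=cfg.conv_channels,
        seed=cfg.seed,
    )
    cae.fit(
        imgs,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        loss=cfg.loss,
        loss_weights=cfg.loss_weights,
    )
    return cae


def extract_lfv(cae: CAE, stack: ImageStack, batch_size: int = 256) -> np.ndarray:
    """Encoder output per frame, in stack order."""
    imgs = _normalize(stack)
    if imgs.shape[1:] != cae.input_shape:
        raise ValueError(
            f"stack shape {imgs.shape[1:]} does not match training shape {cae.input_shape}"
        )
    return np.concatenate(
        [cae.encode(imgs[i : i + batch_size]) for i in range(0, imgs.shape[0], batch_size)]
    )


def local_affinity(lfv: np.ndarray, k_scale: int = 7) -> np.ndarray:
    """Locally scaled affinity matrix of latent feature vectors.

    sigma_i is the distance to the k_scale-th nearest neighbor; frames with
    >= k_scale exact duplicates fall back to their smallest positive
    neighbor distance.  Raises on an all-duplicate input.
    """
    lfv = np.asarray(lfv, dtype=np.float64)
    n = lfv.shape[0]
    if n <= k_scale:
        raise ValueError(f"need more than k_scale={k_scale} frames (got {n})")
    d = squareform(pdist(lfv))
    d_sorted = np.sort(d, axis=1)  # column 0 is the self-distance 0
    sigma = d_sorted[:, k_scale]
    if np.any(sigma == 0):
        pos = np.where(d_sorted > 0, d_sorted, np.inf).min(axis=1)
        if not np.all(np.isfinite(pos[sigma == 0])):
            raise ValueError("degenerate input: all latent vectors identical")
        sigma = np.where(sigma > 0, sigma, pos)
    a = np.exp(-(d**2) / np.outer(sigma, sigma))
    np.fill_diagonal(a, 0.0)
    return np.clip(a, 0.0, 1.0)


def spectral_cluster(affinity: np.ndarray, n: int, seed: int = 0) -> ClusterSet:
    """Normalized-cut spectral clustering of a precomputed affinity matrix."""
    affinity = np.asarray(affinity, dtype=np.float64)
    m = affinity.shape[0]
    if not 1 <= n <= m:
        raise ValueError("cluster count must lie in [1, n_frames]")
    if n == 1:
        return ClusterSet(1, np.zeros(m, dtype=int))
    if n == m:
        return ClusterSet(n, np.arange(m))
    sc = SpectralClustering(
        n_clusters=n,
        affinity="precomputed",
        assign_labels="kmeans",
        random_state=seed,
        n_init=10,
    )
    labels = sc.fit_predict(affinity)
    # relabel so cluster ids are contiguous in [0, n_used)
    _, labels = np.unique(labels, return_inverse=True)
    return ClusterSet(int(labels.max()) + 1, labels)


def dsc(stack: ImageStack, n: int, cfg: CAEConfig = CAEConfig()) -> DSCResult:
    """Full DSC pipeline: CAE -> LFVs -> locally scaled affinity -> spectral."""
    cae = train_cae(stack, cfg)
    lfv = extract_lfv(cae, stack)
    affinity = local_affinity(lfv, cfg.k_scale)
    clusters = spectral_cluster(affinity, n, cfg.seed)
    return DSCResult(clusters=clusters, lfv=lfv, affinity=affinity, cae=cae, config=cfg)


def with_seed(cfg: CAEConfig, seed: int) -> CAEConfig:
    return replace(cfg, seed=int(seed) % (2**31))
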