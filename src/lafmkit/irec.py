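"""Registration-and-clustering (REC) and its iterative fixed point (IREC).

An unaligned stack cannot be clustered directly: drift dominates the
latent representation.  REC couples the two problems — register every
frame to a reference, cluster the registered stack with DSC, keep the
cluster that contains the reference (those frames registered well), and
promote the frame with the highest silhouette score in each cluster to be
the refined reference.  IREC iterates REC over the reference set until the
references reproduce themselves, a cycle is detected, or an iteration cap
is reached.  Scanning the cluster count n upward and comparing the
per-cluster LAFM images (mutually registered, masked SSIM) selects the
number of conformations: the first n at which two LAFM images look the
same is one past the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dsc import CAEConfig, dsc
from .lafm import LAFMImage, LAFMParams, compose_lafm
from .metrics import MaskSpec, SSIMConfig, masked_ssim, ssim_map
from .registration import RigidTransform, apply_rigid, estimate_rigid, register_stack
from .simafm import ImageStack

__all__ = [
    "IRECConfig",
    "RECResult",
    "IRECResult",
    "IRECNode",
    "rec",
    "silhouette_scores",
    "silhouette_select",
    "select_initial_reference",
    "irec",
    "select_cluster_count",
    "hierarchical_irec",
]


@dataclass(frozen=True)
class IRECConfig:
    # per-cluster LAFM images are built from far fewer frames than a whole
    # stack, so the redundancy comparison uses a broader rendering kernel:
    # probability-map sampling noise scales like 1/sqrt(cluster size) and a
    # narrow kernel would penalize same-conformation pairs for graininess
    cae: CAEConfig = field(default_factory=CAEConfig)
    lafm: LAFMParams = field(
        default_factory=lambda: LAFMParams(expansion_factor=2, kernel_sigma=2.5)
    )
    similarity_threshold: float = 0.9
    max_iter: int = 10
    n_max: int = 5
    min_cluster_size: float = 0.05
    rotation_search: bool = True
    ssim: SSIMConfig = field(default_factory=SSIMConfig)
    mask: MaskSpec = field(default_factory=MaskSpec)

    def resolve_min_size(self, n_frames: int) -> int:
        if self.min_cluster_size < 1:
            return max(int(np.ceil(self.min_cluster_size * n_frames)), 1)
        return int(self.min_cluster_size)


@dataclass
class RECResult:
    clusters: list[np.ndarray]  # original frame indices, one per reference
    refined_references: list[int]
    references: list[int]
    lfv_per_reference: list[np.ndarray]
    transforms_per_reference: list[list[RigidTransform]]
    registration_scores: list[np.ndarray]  # per-reference, per-frame (-SSD)
    cluster_quality: list[float]  # mean silhouette of each retained cluster
    audit: dict

    @property
    def quality(self) -> float:
        return float(np.mean(self.cluster_quality)) if self.cluster_quality else 0.0


@dataclass
class IRECResult:
    clusters: list[np.ndarray]  # disjoint frame-index arrays
    references: list[int]
    termination: str  # converged | cycle | max_iter
    trace: list[dict]
    unassigned: np.ndarray
    final_rec: RECResult


@dataclass
class IRECNode:
    frames: np.ndarray
    n_selected: int
    result: "IRECResult | None"
    children: list["IRECNode"]


# -- silhouette ------------------------------------------------------------


def silhouette_scores(lfv: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette s = (b - a) / max(a, b) in latent space.

    a is the mean distance to co-members, b the smallest mean distance to
    another cluster; singletons get s = 0 by convention.
    """
    lfv = np.asarray(lfv, dtype=np.float64)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    n = lfv.shape[0]
    if ids.size < 2:
        return np.zeros(n)
    from scipy.spatial.distance import cdist

    d = cdist(lfv, lfv)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, labels == c].mean() for c in ids if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s


def silhouette_select(members: np.ndarray, lfv: np.ndarray, labels: np.ndarray) -> int:
    """Frame with the maximum silhouette score within a cluster.

    Ties break to the lowest frame index.  With a single-cluster labeling
    the silhouette is undefined and the cluster medoid is returned.
    """
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("empty cluster")
    if np.unique(labels).size < 2:
        from scipy.spatial.distance import cdist

        d = cdist(lfv[members], lfv[members])
        return int(members[np.argmin(d.mean(axis=1))])
    s = silhouette_scores(lfv, labels)
    return int(members[np.argmax(s[members])])


def select_initial_reference(stack: ImageStack, seed: int = 0, subsample: int = 48) -> int:
    """Default R0: the stack's medoid frame by mean pairwise SSIM on a subsample."""
    n = len(stack)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=min(subsample, n), replace=False))
    imgs = stack.heights[idx].astype(np.float64)
    dr = float(imgs.max()) or 1.0
    cfg = SSIMConfig(data_range=dr)
    m = len(idx)
    means = np.zeros(m)
    for i in range(m):
        tot = 0.0
        for j in range(m):
            if i != j:
                tot += float(ssim_map(imgs[i], imgs[j], cfg).mean())
        means[i] = tot / max(m - 1, 1)
    return int(idx[np.argmax(means)])


# -- REC -------------------------------------------------------------------


def _sub_stack(stack: ImageStack, idx: np.ndarray) -> ImageStack:
    sub = ImageStack(stack.heights[np.asarray(idx)], stack.pixel_size, code=stack.code)
    sub.meta = dict(stack.meta)
    return sub


def rec(
    stack: ImageStack,
    references: list[int],
    n: int,
    cfg: IRECConfig = IRECConfig(),
) -> RECResult:
    """One registration-and-clustering pass.

    Single-reference mode (``len(references) == 1`` with ``n`` clusters)
    bootstraps: the registered stack is clustered into n groups and every
    cluster is returned with its max-silhouette reference.  Multi-reference
    mode (``n == len(references)``) registers the stack separately to each
    reference, clusters each registered stack, and retains only the cluster
    containing its own reference (those frames are well registered).
    """
    n_frames = len(stack)
    for r in references:
        if not 0 <= r < n_frames:
            raise ValueError(f"reference index {r} out of range")
    single = len(references) == 1 and n > 1
    if not single and len(references) != n:
        raise ValueError("multi-reference mode requires one reference per cluster")

    clusters: list[np.ndarray] = []
    refined: list[int] = []
    lfvs: list[np.ndarray] = []
    transforms: list[list[RigidTransform]] = []
    scores: list[np.ndarray] = []
    quality: list[float] = []
    audit: dict = {"mode": "single" if single else "multi", "well_registered": []}

    def _reg_score(reg_frames: np.ndarray, ref_image: np.ndarray) -> np.ndarray:
        diff = reg_frames.astype(np.float64) - ref_image[None]
        return -np.sum(diff * diff, axis=(1, 2))

    def _quality(members: np.ndarray, lfv: np.ndarray, labels: np.ndarray) -> float:
        if np.unique(labels).size < 2:
            return 0.0
        return float(silhouette_scores(lfv, labels)[members].mean())

    if single:
        ref = references[0]
        reg = register_stack(stack, ref, cfg.rotation_search)
        reg_stack = ImageStack(reg.frames, stack.pixel_size, code=stack.code)
        result = dsc(reg_stack, n, cfg.cae)
        labels = result.clusters.labels
        score = _reg_score(reg.frames, stack.heights[ref].astype(np.float64))
        for c in range(result.clusters.n):
            members = result.clusters.members(c)
            clusters.append(members)
            refined.append(silhouette_select(members, result.lfv, labels))
            lfvs.append(result.lfv)
            transforms.append(reg.transforms)
            scores.append(score)
            quality.append(_quality(members, result.lfv, labels))
            if labels[ref] == c:
                audit["well_registered"].append(c)
    else:
        for ci, ref in enumerate(references):
            reg = register_stack(stack, ref, cfg.rotation_search)
            reg_stack = ImageStack(reg.frames, stack.pixel_size, code=stack.code)
            result = dsc(reg_stack, n, cfg.cae)
            labels = result.clusters.labels
            own = int(labels[ref])
            members = result.clusters.members(own)
            clusters.append(members)
            refined.append(silhouette_select(members, result.lfv, labels))
            lfvs.append(result.lfv)
            transforms.append(reg.transforms)
            scores.append(_reg_score(reg.frames, stack.heights[ref].astype(np.float64)))
            quality.append(_quality(members, result.lfv, labels))
            audit["well_registered"].append(ci)
        # flag heavily overlapping retained clusters (degenerate references)
        overlaps = []
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                inter = np.intersect1d(clusters[i], clusters[j]).size
                denom = min(len(clusters[i]), len(clusters[j]))
                if denom and inter / denom > 0.5:
                    overlaps.append((i, j, inter))
        audit["degenerate_overlaps"] = overlaps

    return RECResult(
        clusters=clusters,
        refined_references=refined,
        references=list(references),
        lfv_per_reference=lfvs,
        transforms_per_reference=transforms,
        registration_scores=scores,
        cluster_quality=quality,
        audit=audit,
    )


# -- IREC ------------------------------------------------------------------


def _partition(
    clusters: list[np.ndarray],
    scores: list[np.ndarray],
    n_frames: int,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Resolve overlapping retained clusters into a disjoint partition.

    A frame claimed by several retained clusters goes to the reference it
    registered best to (highest similarity, i.e. least SSD); frames claimed
    by no cluster are reported as unassigned.
    """
    labels = np.full(n_frames, -1, dtype=int)
    best = np.full(n_frames, -np.inf)
    for i, members in enumerate(clusters):
        s = scores[i]
        for f in members:
            if s[f] > best[f]:
                best[f] = s[f]
                labels[f] = i
    parts = [np.nonzero(labels == i)[0] for i in range(len(clusters))]
    return parts, np.nonzero(labels < 0)[0]


def irec(
    stack: ImageStack,
    r0: "int | None",
    n: int,
    cfg: IRECConfig = IRECConfig(),
) -> IRECResult:
    """Fixed-point iteration of REC over the registration reference set."""
    if r0 is None:
        r0 = select_initial_reference(stack, cfg.cae.seed)
    n_frames = len(stack)

    if n == 1:
        boot = rec(stack, [r0], 1, cfg)
    else:
        boot = rec(stack, [r0], n, cfg)
    refs = boot.refined_references
    trace = [{"iteration": 0, "references": list(refs), "bootstrap": True}]
    seen = {frozenset(boot.references), frozenset(refs)}
    result = boot
    history: list = []
    termination = "max_iter"

    for it in range(1, cfg.max_iter + 1):
        result = rec(stack, refs, n, cfg)
        history.append(result)
        new_refs = result.refined_references
        trace.append({"iteration": it, "references": list(new_refs),
                      "quality": result.quality})
        if frozenset(new_refs) == frozenset(refs):
            termination = "converged"
            break
        key = frozenset(new_refs)
        if key in seen:
            # return the best-silhouette iteration seen so far
            termination = "cycle"
            result = max(history, key=lambda r: r.quality)
            break
        seen.add(key)
        refs = new_refs

    clusters, unassigned = _partition(result.clusters, result.registration_scores, n_frames)
    return IRECResult(
        clusters=clusters,
        references=list(result.refined_references),
        termination=termination,
        trace=trace,
        unassigned=unassigned,
        final_rec=result,
    )


def _cluster_lafm(stack: ImageStack, members: np.ndarray, ref: int,
                  cfg: IRECConfig) -> LAFMImage:
    """LAFM of one cluster: its frames registered to the cluster reference."""
    sub = _sub_stack(stack, members)
    reg = register_stack(sub, stack.heights[ref].astype(np.float64), cfg.rotation_search)
    return compose_lafm(ImageStack(reg.frames, stack.pixel_size), cfg.lafm)


def cluster_lafms(stack: ImageStack, result: IRECResult, cfg: IRECConfig) -> list[LAFMImage]:
    """Per-cluster LAFM images for the redundancy test.

    Uses the retained clusters as REC produced them (possibly
    overlapping): two references that converged onto the same conformation
    retain near-identical member sets and hence near-identical LAFM
    images — exactly the redundancy the cross-comparison must detect.
    The disjoint score-resolved partition is for the final output only.
    """
    return [
        _cluster_lafm(stack, members, ref, cfg)
        for members, ref in zip(result.final_rec.clusters, result.references)
        if members.size
    ]


def _mutual_ssim(lafms: list[LAFMImage], cfg: IRECConfig) -> list[tuple[int, int, float]]:
    """Pairwise masked SSIM, registering each pair directly.

    Each pair is aligned on its own: two images of the same conformation
    register tightly onto each other, whereas routing the alignment
    through a third, dissimilar image would mask genuine redundancy.
    """
    out = []
    for i in range(len(lafms)):
        for j in range(i + 1, len(lafms)):
            t = estimate_rigid(lafms[j].values, lafms[i].values, cfg.rotation_search)
            moved = apply_rigid(lafms[j].values, t)
            out.append((i, j, masked_ssim(lafms[i].values, moved, cfg.ssim, cfg.mask)))
    return out


def select_cluster_count(
    stack: ImageStack,
    r0: "int | None" = None,
    cfg: IRECConfig = IRECConfig(),
) -> tuple[int, IRECResult, list[dict]]:
    """Scan n upward until two clustered LAFM images look the same.

    Returns (selected n, the IRECResult at that n, scan log).  If no
    redundancy appears by ``cfg.n_max`` the scan stops there, flagged
    non-converged in the log.
    """
    if r0 is None:
        r0 = select_initial_reference(stack, cfg.cae.seed)
    log: list[dict] = []
    prev_n, prev = 1, irec(stack, r0, 1, cfg)
    for n in range(2, cfg.n_max + 1):
        result = irec(stack, r0, n, cfg)
        lafms = cluster_lafms(stack, result, cfg)
        if len(lafms) < 2:
            log.append({"n": n, "note": "fewer than two nonempty clusters"})
            return prev_n, prev, log
        pairs = _mutual_ssim(lafms, cfg)
        best = max(p[2] for p in pairs)
        log.append({"n": n, "pair_ssim": [(i, j, round(s, 4)) for i, j, s in pairs],
                    "max_pair_ssim": round(best, 4),
                    "termination": result.termination})
        if best >= cfg.similarity_threshold:
            return prev_n, prev, log
        prev_n, prev = n, result
    log.append({"n": cfg.n_max, "note": "n_max reached without redundancy"})
    return cfg.n_max, prev, log


def hierarchical_irec(
    stack: ImageStack,
    cfg: IRECConfig = IRECConfig(),
    _frames: "np.ndarray | None" = None,
) -> IRECNode:
    """Recursive IREC: partition by gross morphology first, then refine.

    Each node runs select_cluster_count on its sub-stack; clusters large
    enough to split again are recursed on until n = 1 is selected or the
    sub-stack falls below twice the minimum cluster size.
    """
    frames = np.arange(len(stack)) if _frames is None else _frames
    min_size = cfg.resolve_min_size(len(stack))
    n_sel, result, _log = select_cluster_count(stack, None, cfg)
    node = IRECNode(frames=frames, n_selected=n_sel,
                    result=result if n_sel > 1 else None, children=[])
    if n_sel <= 1:
        return node
    for members in result.clusters:
        if members.size < max(2 * min_size, cfg.cae.k_scale + 2):
            node.children.append(IRECNode(frames=frames[members], n_selected=1,
                                          result=None, children=[]))
            continue
        child = hierarchical_irec(_sub_stack(stack, members), cfg, frames[members])
        node.children.append(child)
    return node
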