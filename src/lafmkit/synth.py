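"""Synthetic pseudo-proteins with discrete conformational states.

The generator emulates the statistical structure of an MD-derived AFM
image stack of a flexible membrane protein: a handful of discrete
conformers of unequal occupancy (dominant metastable states plus rare
transients), per-frame thermal jitter of atom positions, and — for
unaligned stacks — slow rigid in-plane translational/rotational drift
modeled as a random walk, so misregistration is temporally correlated.

Each conformer is a rigid arrangement of Gaussian atom "domains"; the
conformers of a recipe typically share core domains and differ in the
placement of one mobile arm, the smallest structure that makes
conformational clustering nontrivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simafm import AtomSet, ImageStack

__all__ = [
    "Domain",
    "ConformerSpec",
    "MotionModel",
    "StackRecipe",
    "GroundTruth",
    "generate_atom_frames",
    "add_pixel_noise",
    "default_recipe",
    "two_state_recipe",
    "single_state_recipe",
    "morphology_recipe",
]


@dataclass(frozen=True)
class Domain:
    """Gaussian cloud of atoms: center (Å), atom count, spread (Å), vdW radius (Å)."""

    center: tuple[float, float, float]
    n_atoms: int
    spread: float
    atom_radius: float

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        if self.atom_radius <= 0:
            raise ValueError("atom_radius must be > 0")


@dataclass(frozen=True)
class ConformerSpec:
    conformer_id: int
    domains: tuple[Domain, ...]
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if not self.domains:
            raise ValueError("a conformer needs at least one domain")


@dataclass(frozen=True)
class MotionModel:
    """Per-frame jitter and rigid in-plane drift (random-walk steps)."""

    jitter_sigma: float = 0.0  # Å, per atom per frame
    drift_translation_sigma: float = 0.0  # Å per frame step
    drift_rotation_sigma: float = 0.0  # degrees per frame step
    aligned: bool = True

    def __post_init__(self) -> None:
        for s in (self.jitter_sigma, self.drift_translation_sigma, self.drift_rotation_sigma):
            if s < 0:
                raise ValueError("motion sigmas must be >= 0")
        if self.aligned and (self.drift_translation_sigma or self.drift_rotation_sigma):
            # aligned stacks have no drift by definition
            object.__setattr__(self, "drift_translation_sigma", 0.0)
            object.__setattr__(self, "drift_rotation_sigma", 0.0)


@dataclass(frozen=True)
class StackRecipe:
    conformers: tuple[ConformerSpec, ...]
    motion: MotionModel
    n_frames: int
    state_sequence_mode: str = "block"  # "block" | "markov"
    seed: int = 0
    markov_stay_prob: float = 0.97
    background_z: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.state_sequence_mode not in ("block", "markov"):
            raise ValueError("state_sequence_mode must be 'block' or 'markov'")
        total = sum(c.occupancy for c in self.conformers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"conformer occupancies must sum to 1 (got {total})")


@dataclass
class GroundTruth:
    """Per-frame conformer labels and rigid drift transforms."""

    labels: np.ndarray  # (n_frames,) conformer_id
    rotations_deg: np.ndarray  # (n_frames,)
    translations: np.ndarray  # (n_frames, 2) Å
    noise_level: float = 0.0
    seed: int = 0


def _state_sequence(recipe: StackRecipe, rng: np.random.Generator) -> np.ndarray:
    occ = np.array([c.occupancy for c in recipe.conformers])
    ids = np.array([c.conformer_id for c in recipe.conformers])
    n = recipe.n_frames
    if recipe.state_sequence_mode == "block":
        counts = np.floor(occ * n).astype(int)
        # distribute the rounding remainder to the largest fractional parts
        rem = n - counts.sum()
        order = np.argsort(-(occ * n - counts))
        counts[order[:rem]] += 1
        return np.repeat(ids, counts)
    # markov: persistent chain whose jump distribution follows the occupancies
    p_stay = recipe.markov_stay_prob
    labels = np.empty(n, dtype=int)
    state = int(rng.choice(len(ids), p=occ))
    labels[0] = ids[state]
    for t in range(1, n):
        if rng.random() > p_stay:
            state = int(rng.choice(len(ids), p=occ))
        labels[t] = ids[state]
    return labels


def _conformer_atoms(
    conformer: ConformerSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the rigid atom arrangement of one conformer (once per recipe)."""
    pos, rad = [], []
    for dom in conformer.domains:
        p = np.asarray(dom.center, dtype=float) + rng.normal(0.0, dom.spread, (dom.n_atoms, 3))
        pos.append(p)
        rad.append(np.full(dom.n_atoms, dom.atom_radius))
    return np.concatenate(pos), np.concatenate(rad)


def generate_atom_frames(recipe: StackRecipe) -> tuple[list[AtomSet], GroundTruth]:
    """Realize a recipe into per-frame atom sets plus ground truth.

    Frame ``t``'s atoms are the selected conformer's rigid arrangement,
    jittered per atom, then rigidly transformed by the accumulated drift
    (rotation about the z axis through the origin, then xy translation).
    Deterministic given ``recipe.seed``.
    """
    rng = np.random.default_rng(recipe.seed)
    labels = _state_sequence(recipe, rng)
    templates = {c.conformer_id: _conformer_atoms(c, rng) for c in recipe.conformers}

    n = recipe.n_frames
    m = recipe.motion
    if m.aligned:
        rot = np.zeros(n)
        trans = np.zeros((n, 2))
    else:
        rot = np.cumsum(rng.normal(0.0, m.drift_rotation_sigma, n))
        trans = np.cumsum(rng.normal(0.0, m.drift_translation_sigma, (n, 2)), axis=0)

    frames: list[AtomSet] = []
    for t in range(n):
        pos, rad = templates[labels[t]]
        pos = pos.copy()
        if m.jitter_sigma > 0:
            pos += rng.normal(0.0, m.jitter_sigma, pos.shape)
        if not m.aligned:
            a = np.deg2rad(rot[t])
            c, s = np.cos(a), np.sin(a)
            xy = pos[:, :2] @ np.array([[c, s], [-s, c]])
            pos = np.column_stack([xy + trans[t], pos[:, 2]])
        frames.append(AtomSet(pos, rad.copy(), recipe.background_z))

    gt = GroundTruth(
        labels=labels,
        rotations_deg=rot,
        translations=trans,
        noise_level=0.0,
        seed=recipe.seed,
    )
    return frames, gt


def add_pixel_noise(stack: ImageStack, level: float, seed: int = 0) -> ImageStack:
    """Add Gaussian pixel noise with sd = ``level`` x (stack max height).

    Negative values are clipped at 0 since heights are non-negative.
    ``level=0`` returns an unchanged copy.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("noise level must lie in [0, 1]")
    heights = stack.heights.astype(np.float64)
    if level > 0:
        rng = np.random.default_rng(seed)
        heights = heights + rng.normal(0.0, level * stack.max_height(), heights.shape)
        heights = np.maximum(heights, 0.0)
    out = ImageStack(heights.astype(np.float32), stack.pixel_size, code=stack.code)
    out.meta = dict(stack.meta)
    out.meta["noise_level"] = level
    return out


# --------------------------------------------------------------------------
# Stock recipes.  The study conditions they encode: conformers share two
# core domains and differ in the placement of one mobile arm (mimicking a
# flexible cytoplasmic loop); major/minor occupancies mirror the
# dominant-plus-transient split typical of a metastable trajectory.

# Asymmetric three-lobe core: no nontrivial rotation maps the core onto
# itself, so rigid registration cannot alias one conformer onto another.
_CORE = (
    Domain((-7.0, -4.0, 6.0), 26, 2.0, 1.8),
    Domain((7.0, -4.0, 6.0), 26, 2.0, 1.8),
    Domain((0.0, 6.0, 4.0), 14, 1.5, 1.8),
)


def _arm(x: float, y: float, z: float = 9.0) -> Domain:
    return Domain((x, y, z), 20, 1.8, 1.8)


def default_recipe(
    n_frames: int = 200,
    aligned: bool = True,
    jitter_sigma: float = 0.5,
    seed: int = 0,
    mode: str = "block",
) -> StackRecipe:
    """Two major conformers (0.45/0.45) plus one minor transient (0.10)."""
    conformers = (
        ConformerSpec(0, _CORE + (_arm(-8.0, 9.0),), 0.45),
        ConformerSpec(1, _CORE + (_arm(8.0, 9.0),), 0.45),
        ConformerSpec(2, _CORE + (_arm(0.0, 1.0, 10.0),), 0.10),
    )
    motion = MotionModel(
        jitter_sigma=jitter_sigma,
        drift_translation_sigma=0.0 if aligned else 0.4,
        drift_rotation_sigma=0.0 if aligned else 0.8,
        aligned=aligned,
    )
    return StackRecipe(conformers, motion, n_frames, mode, seed)


def two_state_recipe(
    n_frames: int = 200,
    aligned: bool = True,
    jitter_sigma: float = 0.5,
    seed: int = 0,
    occupancies: tuple[float, float] = (0.5, 0.5),
    mode: str = "block",
) -> StackRecipe:
    """Two well-separated conformers with configurable occupancies."""
    conformers = (
        ConformerSpec(0, _CORE + (_arm(-8.0, 9.0),), occupancies[0]),
        ConformerSpec(1, _CORE + (_arm(8.0, 9.0),), occupancies[1]),
    )
    motion = MotionModel(
        jitter_sigma=jitter_sigma,
        drift_translation_sigma=0.0 if aligned else 0.4,
        drift_rotation_sigma=0.0 if aligned else 0.8,
        aligned=aligned,
    )
    return StackRecipe(conformers, motion, n_frames, mode, seed)


def single_state_recipe(
    n_frames: int = 100,
    aligned: bool = True,
    jitter_sigma: float = 0.5,
    seed: int = 0,
) -> StackRecipe:
    """One conformer only; homogeneous stack."""
    conformers = (ConformerSpec(0, _CORE + (_arm(0.0, 8.0),), 1.0),)
    motion = MotionModel(
        jitter_sigma=jitter_sigma,
        drift_translation_sigma=0.0 if aligned else 0.4,
        drift_rotation_sigma=0.0 if aligned else 0.8,
        aligned=aligned,
    )
    return StackRecipe(conformers, motion, n_frames, "block", seed)


def morphology_recipe(
    kind: str,
    n_frames: int = 100,
    aligned: bool = False,
    jitter_sigma: float = 0.5,
    seed: int = 0,
    n_states: int = 1,
) -> StackRecipe:
    """Two gross morphologies for merged-stack experiments.

    ``kind='tall'`` is a compact tall blob (cytoplasmic-like); with
    ``n_states=2`` it carries two sub-conformers.  ``kind='ring'`` is a flat
    ring of small domains (periplasmic-like), always one state.
    """
    if kind == "tall":
        # off-center secondary lobe breaks rotational symmetry
        base = (
            Domain((0.0, 0.0, 9.0), 30, 2.5, 1.8),
            Domain((0.0, -8.0, 5.0), 14, 1.5, 1.8),
        )
        if n_states == 2:
            conformers = (
                ConformerSpec(0, base + (_arm(-8.0, 6.0),), 0.5),
                ConformerSpec(1, base + (_arm(8.0, 6.0),), 0.5),
            )
        else:
            conformers = (ConformerSpec(0, base + (_arm(0.0, 7.0),), 1.0),)
    elif kind == "ring":
        ring = tuple(
            Domain((9.0 * np.cos(a), 9.0 * np.sin(a), 3.5), 10, 1.2, 1.8)
            for a in np.linspace(0.0, 2.0 * np.pi, 5, endpoint=False)
        )
        conformers = (ConformerSpec(0, ring, 1.0),)
    else:
        raise ValueError("kind must be 'tall' or 'ring'")
    motion = MotionModel(
        jitter_sigma=jitter_sigma,
        drift_translation_sigma=0.0 if aligned else 0.4,
        drift_rotation_sigma=0.0 if aligned else 0.8,
        aligned=aligned,
    )
    return StackRecipe(conformers, motion, n_frames, "block", seed)
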