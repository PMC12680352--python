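"""Shared fixtures: small synthetic stacks rendered once per session."""

import numpy as np
import pytest

from lafmkit.simafm import ScanGrid, TipModel, render_stack
from lafmkit.synth import (
    default_recipe,
    generate_atom_frames,
    single_state_recipe,
    two_state_recipe,
)


@pytest.fixture(scope="session")
def grid():
    return ScanGrid.centered(32.0, 2.0)


@pytest.fixture(scope="session")
def tip():
    return TipModel(20.0)


@pytest.fixture(scope="session")
def two_state_small(grid, tip):
    """60-frame aligned two-conformer stack with ground truth."""
    recipe = two_state_recipe(n_frames=60, aligned=True, seed=4)
    frames, gt = generate_atom_frames(recipe)
    return render_stack(frames, tip, grid), gt


@pytest.fixture(scope="session")
def three_state_small(grid, tip):
    """120-frame aligned 0.45/0.45/0.10 stack with ground truth."""
    recipe = default_recipe(n_frames=120, aligned=True, seed=7)
    frames, gt = generate_atom_frames(recipe)
    return render_stack(frames, tip, grid), gt


@pytest.fixture(scope="session")
def homogeneous_small(grid, tip):
    # 100 frames: large enough that the two halves' LAFM probability maps
    # are not dominated by sampling noise
    recipe = single_state_recipe(n_frames=100, seed=2)
    frames, gt = generate_atom_frames(recipe)
    return render_stack(frames, tip, grid), gt


@pytest.fixture(scope="session")
def sharp_frame(tip):
    """A single registered frame on a fine 64x64 grid (1 Å/px)."""
    recipe = two_state_recipe(n_frames=1, aligned=True, seed=3)
    frames, _ = generate_atom_frames(recipe)
    fine = ScanGrid.centered(32.0, 1.0)
    return render_stack(frames, tip, fine).heights[0].astype(np.float64)
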