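"""Tip-dilation geometry: closed form vs the brute-force lowering oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lafmkit.simafm import AtomSet, ScanGrid, TipModel, contact_height, orient_side, render_frame, render_stack
from oracles import brute_contact_height, brute_render_frame, random_atomset


class TestContactHeight:
    def test_axial_contact_is_tip_independent(self):
        # at d=0 the tip bottom rests on the sphere top: h = z + r for any R, theta
        for R in (2.0, 20.0, 80.0):
            for theta in (10.0, 18.0, 40.0):
                assert contact_height((0, 0, 5.0), 2.0, TipModel(R, theta), 0.0) == pytest.approx(7.0)

    def test_sphere_regime_matches_hand_value(self):
        h = contact_height((0, 0, 5.0), 2.0, TipModel(20.0, 18.0), 10.0)
        assert h == pytest.approx(5.0 + np.sqrt(484.0 - 100.0) - 20.0, abs=1e-12)
        assert h == pytest.approx(4.5959, abs=1e-4)

    def test_cone_regime_matches_hand_value(self):
        th = np.deg2rad(18.0)
        expected = 5.0 + 22.0 / np.sin(th) - 20.0 - 30.0 / np.tan(th)
        h = contact_height((0, 0, 5.0), 2.0, TipModel(20.0, 18.0), 30.0)
        assert h == pytest.approx(expected, abs=1e-12)
        assert h < 0  # clipped to background during rendering

    def test_continuity_at_regime_boundary(self):
        tip = TipModel(20.0, 18.0)
        d_crit = 22.0 * np.cos(np.deg2rad(18.0))
        left = contact_height((0, 0, 5.0), 2.0, tip, d_crit - 1e-9)
        right = contact_height((0, 0, 5.0), 2.0, tip, d_crit + 1e-9)
        assert abs(left - right) < 1e-7

    @settings(max_examples=30, deadline=None)
    @given(
        z=st.floats(0.0, 12.0),
        r=st.floats(1.0, 2.5),
        R=st.floats(2.0, 80.0),
        theta=st.floats(8.0, 45.0),
        d=st.floats(0.0, 40.0),
    )
    def test_matches_brute_force_oracle(self, z, r, R, theta, d):
        analytic = contact_height((0, 0, z), r, TipModel(R, theta), d)
        brute = brute_contact_height(z, r, R, theta, d, n_samples=20001)
        assert analytic == pytest.approx(brute, abs=1e-4)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            contact_height((0, 0, 5.0), 2.0, TipModel(20.0), -1.0)


class TestRenderFrame:
    def test_no_atoms_above_background_gives_zero_image(self):
        grid = ScanGrid.centered(8.0, 2.0)
        atoms = AtomSet(np.array([[0.0, 0.0, -5.0]]), np.array([2.0]), 0.0)
        assert np.all(render_frame(atoms, TipModel(20.0), grid) == 0.0)

    def test_empty_atomset_gives_zero_image(self):
        grid = ScanGrid.centered(8.0, 2.0)
        atoms = AtomSet(np.empty((0, 3)), np.empty(0), 0.0)
        assert np.all(render_frame(atoms, TipModel(20.0), grid) == 0.0)

    @pytest.mark.parametrize("R", [2.0, 20.0, 80.0])
    def test_centered_atom_pixel_equals_z_plus_r(self, R):
        # grid with a pixel center exactly at the origin
        grid = ScanGrid(-8.0, 8.0, -8.0, 8.0, 2.0)
        ys, xs = grid.pixel_centers()
        assert 0.0 not in xs  # centers at odd multiples of 1
        grid = ScanGrid(-9.0, 9.0, -9.0, 9.0, 2.0)
        ys, xs = grid.pixel_centers()
        i = np.argmin(np.abs(xs))
        assert xs[i] == pytest.approx(0.0)
        atoms = AtomSet(np.array([[0.0, 0.0, 5.0]]), np.array([2.0]), 0.0)
        img = render_frame(atoms, TipModel(R), grid)
        assert img[i, i] == pytest.approx(7.0)

    def test_matches_brute_force_render(self):
        rng = np.random.default_rng(42)
        grid = ScanGrid.centered(16.0, 4.0)
        atoms = random_atomset(rng, 50)
        tip = TipModel(20.0)
        fast = render_frame(atoms, tip, grid)
        brute = brute_render_frame(atoms, tip, grid, n_samples=8001)
        assert np.max(np.abs(fast - brute)) < 1e-3

    def test_dilation_monotone_in_tip_radius(self):
        # rendered pixel values with a blunt tip dominate those of a sharp tip
        # (grayscale dilation ordering); verified per pixel on fixture frames
        from lafmkit.synth import generate_atom_frames, two_state_recipe

        frames, _ = generate_atom_frames(two_state_recipe(n_frames=5, seed=4))
        grid = ScanGrid.centered(32.0, 2.0)
        small = render_stack(frames, TipModel(2.0), grid).heights
        big = render_stack(frames, TipModel(20.0), grid).heights
        assert np.all(big >= small - 1e-9)


class TestRenderStack:
    def test_single_frame_stack_matches_render_frame(self):
        rng = np.random.default_rng(1)
        atoms = random_atomset(rng, 10)
        grid = ScanGrid.centered(16.0, 4.0)
        tip = TipModel(20.0)
        stack = render_stack([atoms], tip, grid)
        assert len(stack) == 1
        np.testing.assert_allclose(stack.heights[0], render_frame(atoms, tip, grid), rtol=1e-6)

    def test_zero_jitter_frames_render_identically(self):
        from lafmkit.synth import generate_atom_frames, single_state_recipe

        recipe = single_state_recipe(n_frames=4, jitter_sigma=0.0, seed=0)
        frames, _ = generate_atom_frames(recipe)
        stack = render_stack(frames, TipModel(20.0), ScanGrid.centered(16.0, 2.0))
        for i in range(1, 4):
            np.testing.assert_array_equal(stack.heights[i], stack.heights[0])

    def test_heights_nonnegative(self, two_state_small):
        stack, _ = two_state_small
        assert stack.heights.min() >= 0.0


class TestOrientSide:
    def _atoms(self):
        rng = np.random.default_rng(0)
        return AtomSet(rng.normal(0, 5, (20, 3)) + [0, 0, 15], np.full(20, 1.7), 12.0)

    def test_cytoplasmic_is_identity(self):
        atoms = self._atoms()
        out = orient_side(atoms, "C")
        np.testing.assert_array_equal(out.positions, atoms.positions)
        assert out.background_z == atoms.background_z

    def test_flip_is_involution(self):
        atoms = self._atoms()
        twice = orient_side(orient_side(atoms, "P"), "P")
        np.testing.assert_allclose(twice.positions, atoms.positions, atol=1e-9)

    def test_height_above_background_preserved(self):
        # an atom protruding 5 Å below the lower leaflet (at -12) protrudes
        # 5 Å above the background in the flipped frame's own convention
        atoms = AtomSet(np.array([[3.0, 4.0, -17.0]]), np.array([1.7]), 12.0)
        flipped = orient_side(atoms, "P", lower_leaflet_z=-12.0)
        assert flipped.positions[0, 2] - flipped.background_z == pytest.approx(5.0)

    def test_invalid_side_rejected(self):
        with pytest.raises(ValueError):
            orient_side(self._atoms(), "X")
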