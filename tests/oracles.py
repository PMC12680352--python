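"""Independent brute-force oracles used by the test suite.

The tip-lowering oracle never uses the closed-form contact expressions: it
samples the physical tip surface densely and lowers it until first contact
with an atom sphere, reducing the 3D problem to the 2D cross-section
through the tip axis and the atom center (valid by the tip's rotational
symmetry).
"""

import numpy as np


def tip_surface_height(u: np.ndarray, R: float, theta_deg: float) -> np.ndarray:
    """Tip surface height above its lowest point at radial offset u."""
    th = np.deg2rad(theta_deg)
    u = np.abs(u)
    sphere = R - np.sqrt(np.maximum(R**2 - np.minimum(u, R * np.cos(th)) ** 2, 0.0))
    cone = R - R * np.sin(th) + (u - R * np.cos(th)) / np.tan(th)
    return np.where(u <= R * np.cos(th), sphere, cone)


def brute_contact_height(
    atom_z: float,
    atom_r: float,
    R: float,
    theta_deg: float,
    d: float,
    n_samples: int = 4001,
) -> float:
    """Lower a densely sampled tip surface until it first touches the sphere.

    In the cross-section the atom is a circle of radius atom_r at lateral
    distance d; for a tip surface point at lateral offset x from the tip
    axis the contact height is atom_z + sqrt(atom_r^2 - (x - d)^2) -
    tip_surface(x); the first contact is the maximum over x.
    """
    s = np.linspace(-atom_r, atom_r, n_samples)
    x = d + s
    heights = atom_z + np.sqrt(np.maximum(atom_r**2 - s**2, 0.0)) - tip_surface_height(
        x, R, theta_deg
    )
    return float(heights.max())


def brute_render_frame(atoms, tip, grid, n_samples: int = 1501) -> np.ndarray:
    """Per-pixel tip-lowering render (max over atoms), clipped at background."""
    h, w = grid.shape
    ys, xs = grid.pixel_centers()
    gx, gy = np.meshgrid(xs, ys)
    image = np.full((h, w), -np.inf)
    for pos, r in zip(atoms.positions, atoms.radii):
        if pos[2] + r <= atoms.background_z:
            continue
        d = np.sqrt((gx - pos[0]) ** 2 + (gy - pos[1]) ** 2).ravel()
        s = np.linspace(-r, r, n_samples)
        x = d[:, None] + s[None, :]
        contact = (
            pos[2]
            + np.sqrt(np.maximum(r**2 - s**2, 0.0))[None, :]
            - tip_surface_height(x, tip.R, tip.theta)
        )
        np.maximum(image, contact.max(axis=1).reshape(h, w), out=image)
    return np.maximum(image - atoms.background_z, 0.0)


def random_atomset(rng: np.random.Generator, n_atoms: int = 50):
    """Random atom configuration within the default scan footprint."""
    from lafmkit.simafm import AtomSet

    positions = np.column_stack([
        rng.uniform(-20, 20, n_atoms),
        rng.uniform(-20, 20, n_atoms),
        rng.uniform(-2, 12, n_atoms),
    ])
    radii = rng.uniform(1.2, 2.2, n_atoms)
    return AtomSet(positions, radii, 0.0)
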