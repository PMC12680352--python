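"""Simulated AFM imaging by tip-shape dilation of van der Waals spheres.

A topographic AFM image is modeled as the grayscale morphological dilation
of the sample surface by the tip shape: at every lateral grid position the
tip — a cone of half-angle ``theta`` terminated by a spherical apex of
radius ``R`` — is lowered until it first touches any atom sphere, and the
height of the tip's lowest point at contact is recorded.

For a single atom (center ``(x, y, z)``, van der Waals radius ``r``) at
lateral distance ``d`` from the tip axis, the contact height has a closed
form obtained by dilating the tip surface by ``r``:

* apex-sphere contact, ``d <= (R + r) cos(theta)``::

      h(d) = z + sqrt((R + r)**2 - d**2) - R

* cone-flank contact, ``d > (R + r) cos(theta)``::

      h(d) = z + (R + r) / sin(theta) - R - d / tan(theta)

The two regimes join continuously at ``d = (R + r) cos(theta)``.  A pixel's
value is the maximum contact height over all atoms, measured above the
membrane background plane and clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomSet",
    "TipModel",
    "ScanGrid",
    "ImageStack",
    "contact_height",
    "render_frame",
    "render_stack",
    "orient_side",
]


@dataclass
class AtomSet:
    """3D points with van der Waals radii above a membrane plane.

    Atoms whose sphere top ``z + r`` does not exceed ``background_z``
    cannot be touched by the tip and contribute nothing to the image.
    """

    positions: np.ndarray  # (n, 3) Å
    radii: np.ndarray  # (n,) Å
    background_z: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if self.positions.shape[0] != self.radii.shape[0]:
            raise ValueError("positions and radii length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError("van der Waals radii must be positive")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def protruding(self) -> "AtomSet":
        """Subset of atoms whose spheres rise above the background plane."""
        keep = self.positions[:, 2] + self.radii > self.background_z
        return AtomSet(self.positions[keep], self.radii[keep], self.background_z)


@dataclass(frozen=True)
class TipModel:
    """Cone with a spherical apex: radius ``R`` (Å), half-angle ``theta`` (deg)."""

    R: float
    theta: float = 18.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("tip radius must be positive")
        if not 0.0 < self.theta < 90.0:
            raise ValueError("half-angle must lie in (0, 90) degrees")


@dataclass(frozen=True)
class ScanGrid:
    """Uniform scan grid; pixel centers at ``min + (i + 0.5) * pixel_size``."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("grid extents must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        h = int(round((self.y_max - self.y_min) / self.pixel_size))
        w = int(round((self.x_max - self.x_min) / self.pixel_size))
        return max(h, 1), max(w, 1)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (ys, xs) center coordinates, row 0 at y_min."""
        h, w = self.shape
        xs = self.x_min + (np.arange(w) + 0.5) * self.pixel_size
        ys = self.y_min + (np.arange(h) + 0.5) * self.pixel_size
        return ys, xs

    @classmethod
    def centered(cls, half_extent: float, pixel_size: float) -> "ScanGrid":
        return cls(-half_extent, half_extent, -half_extent, half_extent, pixel_size)


@dataclass
class ImageStack:
    """N x H x W stack of height maps (Å above background, >= 0)."""

    heights: np.ndarray
    pixel_size: float
    code: "object | None" = None  # StackCode; kept loose to avoid import cycle
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float32)
        if self.heights.ndim == 2:
            self.heights = self.heights[None]
        if self.heights.ndim != 3:
            raise ValueError("stack must be N x H x W")

    def __len__(self) -> int:
        return self.heights.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.heights.shape

    def max_height(self) -> float:
        return float(self.heights.max()) if self.heights.size else 0.0


def contact_height(
    position: Sequence[float],
    radius: float,
    tip: TipModel,
    lateral_distance: "float | np.ndarray",
) -> "float | np.ndarray":
    """Height of the tip's lowest point when it first contacts one atom.

    Returns the raw (unclipped) contact height; image rendering subtracts
    the background and clips at zero.
    """
    d = np.asarray(lateral_distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("lateral distance must be non-negative")
    z = float(position[2])
    rr = tip.R + float(radius)
    th = np.deg2rad(tip.theta)
    d_crit = rr * np.cos(th)
    sphere = z + np.sqrt(np.maximum(rr**2 - np.minimum(d, d_crit) ** 2, 0.0)) - tip.R
    cone = z + rr / np.sin(th) - tip.R - d / np.tan(th)
    out = np.where(d <= d_crit, sphere, cone)
    return float(out) if out.ndim == 0 else out


def render_frame(atoms: AtomSet, tip: TipModel, grid: ScanGrid) -> np.ndarray:
    """Scan the tip over the grid; pixel = max contact height above background.

    Pixels touched by no atom are exactly 0 (the membrane background).
    """
    h, w = grid.shape
    image = np.zeros((h, w), dtype=np.float64)
    sub = atoms.protruding()
    if len(sub) == 0:
        return image
    ys, xs = grid.pixel_centers()
    gx = xs[None, :]  # (1, w)
    gy = ys[:, None]  # (h, 1)
    th = np.deg2rad(tip.theta)
    sin_th, cot_th = np.sin(th), 1.0 / np.tan(th)
    for pos, r in zip(sub.positions, sub.radii):
        rr = tip.R + r
        d2 = (gx - pos[0]) ** 2 + (gy - pos[1]) ** 2
        d_crit = rr * np.cos(th)
        hs = pos[2] + np.sqrt(np.maximum(rr**2 - np.minimum(d2, d_crit**2), 0.0)) - tip.R
        hc = pos[2] + rr / sin_th - tip.R - np.sqrt(d2) * cot_th
        np.maximum(image, np.where(d2 <= d_crit**2, hs, hc), out=image)
    return np.maximum(image - atoms.background_z, 0.0)


def render_stack(
    frames: Iterable[AtomSet],
    tip: TipModel,
    grid: ScanGrid,
    code=None,
) -> ImageStack:
    """Render every frame on a fixed grid, preserving input order."""
    images = [render_frame(f, tip, grid) for f in frames]
    if not images:
        raise ValueError("at least one frame is required")
    stack = ImageStack(np.stack(images).astype(np.float32), grid.pixel_size, code=code)
    stack.meta.update({"tip_radius_A": tip.R, "theta_deg": tip.theta})
    return stack


def orient_side(atoms: AtomSet, side: str, lower_leaflet_z: "float | None" = None) -> AtomSet:
    """Rotate the structure so the membrane side of interest faces +Z.

    Cytoplasmic ("C") is the identity.  Periplasmic ("P") flips the structure
    180 degrees about the X axis (y -> -y, z -> -z) and sets the background
    to the flipped lower-leaflet plane.  By default the membrane is assumed
    symmetric about z = 0, i.e. the lower leaflet sits at ``-background_z``.
    """
    if side not in ("C", "P"):
        raise ValueError("side must be 'C' or 'P'")
    if side == "C":
        return AtomSet(atoms.positions.copy(), atoms.radii.copy(), atoms.background_z)
    if lower_leaflet_z is None:
        lower_leaflet_z = -atoms.background_z
    flipped = atoms.positions * np.array([1.0, -1.0, -1.0])
    return AtomSet(flipped, atoms.radii.copy(), -float(lower_leaflet_z))
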