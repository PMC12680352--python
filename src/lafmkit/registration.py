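"""Rigid-body registration of AFM image frames.

Only rotation and in-plane translation are estimated and applied — no
scaling or shearing, which the transform parameterization forbids
structurally.  Estimation is intensity-based: a log-polar spectral
correlation proposes the rotation (the Fourier magnitude is translation
invariant; its 180-degree ambiguity is resolved by trying both
candidates), phase cross-correlation proposes the translation, and a
Powell refinement of the sum-of-squared-differences polishes all three
parameters jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation
from skimage.transform import warp_polar

from .simafm import ImageStack

__all__ = [
    "RigidTransform",
    "RegisteredStack",
    "estimate_rigid",
    "apply_rigid",
    "register_stack",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, about the image center) then translation (pixels)."""

    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)  # (drow, dcol)

    def inverse(self) -> "RigidTransform":
        a = np.deg2rad(self.rotation)
        c, s = np.cos(a), np.sin(a)
        dr, dc = self.translation
        # inverse of v -> R v + t is v -> R^T (v - t)
        return RigidTransform(
            rotation=-self.rotation,
            translation=(-(c * dr + s * dc), -(-s * dr + c * dc)),
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        a = np.deg2rad(self.rotation)
        c, s = np.cos(a), np.sin(a)
        odr, odc = other.translation
        dr, dc = self.translation
        return RigidTransform(
            rotation=self.rotation + other.rotation,
            translation=(c * odr - s * odc + dr, s * odr + c * odc + dc),
        )


@dataclass
class RegisteredStack:
    frames: np.ndarray  # transformed N x H x W
    transforms: list[RigidTransform]
    reference_index: int | None = None


def _rot_matrix(rotation_deg: float) -> np.ndarray:
    a = np.deg2rad(rotation_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def apply_rigid(image: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Warp an image by a rigid transform (bilinear, zero fill).

    A feature at position v (row, col) moves to ``R (v - center) + center
    + translation``; out-of-bounds areas are filled with 0 (membrane
    background), preserving the non-negative height contract.
    """
    image = np.asarray(image, dtype=np.float64)
    center = (np.array(image.shape) - 1) / 2.0
    rot = _rot_matrix(t.rotation)
    # affine_transform maps output coords to input coords: v_in = M v_out + off
    m = rot.T
    off = center - m @ (center + np.asarray(t.translation))
    return affine_transform(image, m, offset=off, order=1, mode="constant", cval=0.0)


def _ssd(moving: np.ndarray, reference: np.ndarray, params) -> float:
    t = RigidTransform(params[0], (params[1], params[2]))
    return float(np.sum((apply_rigid(moving, t) - reference) ** 2))


def estimate_rigid(
    moving: np.ndarray,
    reference: np.ndarray,
    rotation_search: bool = True,
) -> RigidTransform:
    """Estimate the rigid transform mapping ``moving`` onto ``reference``."""
    moving = np.asarray(moving, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if moving.shape != reference.shape:
        raise ValueError("images must have the same shape")
    if moving.max() <= 0 or reference.max() <= 0:
        raise ValueError("cannot register blank images")

    candidates = [0.0]
    if rotation_search:
        radius = min(moving.shape) // 2
        f_mov = np.abs(np.fft.fftshift(np.fft.fft2(moving)))
        f_ref = np.abs(np.fft.fftshift(np.fft.fft2(reference)))
        p_mov = warp_polar(f_mov, radius=radius, output_shape=(360, radius))
        p_ref = warp_polar(f_ref, radius=radius, output_shape=(360, radius))
        shift, _, _ = phase_cross_correlation(p_ref, p_mov, upsample_factor=10,
                                              normalization=None)
        angle = -float(shift[0])  # degrees; spectrum has a 180-deg ambiguity
        candidates = [angle, angle + 180.0 if angle < 0 else angle - 180.0]

    best = None
    for angle in candidates:
        rotated = apply_rigid(moving, RigidTransform(angle))
        shift, _, _ = phase_cross_correlation(reference, rotated, upsample_factor=20,
                                              normalization=None)
        params = np.array([angle, shift[0], shift[1]])
        ssd = _ssd(moving, reference, params)
        if best is None or ssd < best[0]:
            best = (ssd, params)

    res = minimize(
        lambda p: _ssd(moving, reference, p),
        best[1],
        method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 200},
    )
    rot = ((res.x[0] + 180.0) % 360.0) - 180.0
    return RigidTransform(float(rot), (float(res.x[1]), float(res.x[2])))


def register_stack(
    stack: ImageStack,
    reference,
    rotation_search: bool = True,
) -> RegisteredStack:
    """Align every frame of a stack to a reference frame or image."""
    if isinstance(reference, (int, np.integer)):
        ref_index = int(reference)
        if not 0 <= ref_index < len(stack):
            raise ValueError("reference index out of range")
        ref_image = stack.heights[ref_index].astype(np.float64)
    else:
        ref_index = None
        ref_image = np.asarray(reference, dtype=np.float64)

    frames = np.empty_like(stack.heights, dtype=np.float64)
    transforms: list[RigidTransform] = []
    for i, frame in enumerate(stack.heights):
        if ref_index is not None and i == ref_index:
            t = RigidTransform()
        else:
            t = estimate_rigid(frame.astype(np.float64), ref_image, rotation_search)
        transforms.append(t)
        frames[i] = apply_rigid(frame.astype(np.float64), t)
    return RegisteredStack(frames=frames.astype(np.float32), transforms=transforms,
                           reference_index=ref_index)
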