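"""In-plane rigid registration of on-treatment slices to the first-fraction scan.

Body-composition areas are only comparable across fractions if every scan is
measured at the same anatomical level and position, so each on-treatment image
is rigidly registered (3 DOF: in-plane translation + rotation about the image
center) to the patient's first-fraction image before areas are extracted.
The problem is mono-modal (T2w to T2w), so normalized cross-correlation (NCC)
is the similarity objective, optimized coarse-to-fine with a cross-correlation
translation initializer and multi-start Powell refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .exceptions import RegistrationFailureError

__all__ = [
    "RigidTransform2D",
    "estimate_rigid",
    "resample_to_fixed",
    "ncc",
]


@dataclass(frozen=True)
class RigidTransform2D:
    """Rigid in-plane transform: rotation ``theta_deg`` about the image center
    followed by translation ``(tx_mm, ty_mm)``.

    Maps a physical point p (mm, origin at the image center, x along columns,
    y along rows) to ``R(theta) @ p + t``.
    """

    tx_mm: float = 0.0
    ty_mm: float = 0.0
    theta_deg: float = 0.0

    def is_identity(self, atol: float = 1e-12) -> bool:
        return (
            abs(self.tx_mm) <= atol
            and abs(self.ty_mm) <= atol
            and abs(self.theta_deg) <= atol
        )

    @property
    def matrix(self) -> np.ndarray:
        """2x2 rotation matrix acting on (x, y) column vectors."""
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])

    def apply_points(self, pts_xy_mm: np.ndarray) -> np.ndarray:
        """Transform an (N, 2) array of (x, y) points in mm."""
        pts = np.asarray(pts_xy_mm, dtype=float)
        return pts @ self.matrix.T + np.array([self.tx_mm, self.ty_mm])

    def inverse(self) -> "RigidTransform2D":
        rinv = self.matrix.T
        t = -rinv @ np.array([self.tx_mm, self.ty_mm])
        return RigidTransform2D(float(t[0]), float(t[1]), -self.theta_deg)

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        r = self.matrix @ other.matrix
        t = self.matrix @ np.array([other.tx_mm, other.ty_mm]) + np.array(
            [self.tx_mm, self.ty_mm]
        )
        theta = self.theta_deg + other.theta_deg
        return RigidTransform2D(float(t[0]), float(t[1]), float(theta))

    def as_dict(self) -> dict:
        return {
            "tx_mm": float(self.tx_mm),
            "ty_mm": float(self.ty_mm),
            "theta_deg": float(self.theta_deg),
        }


def _pixel_affine(t: RigidTransform2D, shape: tuple, spacing: float):
    """Affine (matrix, offset) in (row, col) pixel coordinates for
    scipy.ndimage.affine_transform such that output(q) = input(T^-1 q)."""
    rinv = t.matrix.T  # inverse rotation acting on (x, y)
    # Swap to (row, col) = (y, x) ordering.
    a = np.array([[rinv[1, 1], rinv[1, 0]], [rinv[0, 1], rinv[0, 0]]])
    c = (np.array(shape, dtype=float) - 1.0) / 2.0  # center in (row, col) px
    t_px = np.array([t.ty_mm, t.tx_mm]) / spacing
    offset = c - a @ (c + t_px)
    return a, offset


def resample_to_fixed(
    grid: np.ndarray,
    t: RigidTransform2D,
    spacing: float = 1.0,
    is_label: bool = False,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``grid`` under the rigid transform ``t``.

    Intensities use linear interpolation, label maps nearest-neighbor (so the
    label vocabulary is preserved exactly). Out-of-field pixels are set to
    ``cval`` (background).
    """
    if t.is_identity():
        return grid.copy()
    a, offset = _pixel_affine(t, grid.shape, spacing)
    order = 0 if is_label else 1
    out = ndimage.affine_transform(
        grid.astype(grid.dtype if is_label else np.float32, copy=False),
        a,
        offset=offset,
        order=order,
        mode="constant",
        cval=cval,
    )
    return out.astype(grid.dtype, copy=False) if is_label else out


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation between two images (1.0 = identical up to
    affine intensity scaling)."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(img, dtype=np.float32)
    sm = ndimage.uniform_filter(np.asarray(img, dtype=np.float32), size=factor)
    return sm[factor // 2 :: factor, factor // 2 :: factor]


def _translation_init(moving: np.ndarray, fixed: np.ndarray, spacing: float):
    """Integer-pixel translation estimate via FFT cross-correlation of
    mean-subtracted images."""
    m = moving - moving.mean()
    f = fixed - fixed.mean()
    corr = np.real(np.fft.ifft2(np.fft.fft2(f) * np.conj(np.fft.fft2(m))))
    shift = np.unravel_index(np.argmax(corr), corr.shape)
    dy, dx = shift
    if dy > moving.shape[0] // 2:
        dy -= moving.shape[0]
    if dx > moving.shape[1] // 2:
        dx -= moving.shape[1]
    return dx * spacing, dy * spacing


def estimate_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    spacing: float = 1.0,
    similarity_floor: float = 0.70,
    theta_starts=(-3.0, 0.0, 3.0),
) -> tuple[RigidTransform2D, float]:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Runs a two-level pyramid: an FFT cross-correlation translation initializer
    and multi-start Powell over (tx, ty, theta) maximizing NCC at half
    resolution, then a full-resolution Powell refinement from the best coarse
    optimum.

    Returns ``(transform, similarity)`` where ``resample_to_fixed(moving,
    transform) ≈ fixed``. Raises :class:`RegistrationFailureError` when the
    final NCC falls below ``similarity_floor`` — such scans are excluded from
    longitudinal analysis rather than measured badly.
    """
    moving = np.asarray(moving, dtype=np.float32)
    fixed = np.asarray(fixed, dtype=np.float32)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed images must share shape")

    factor = 2 if min(moving.shape) >= 64 else 1
    mov_c = _downsample(moving, factor)
    fix_c = _downsample(fixed, factor)
    sp_c = spacing * factor

    def neg_ncc(params, mov, fix, sp):
        t = RigidTransform2D(params[0], params[1], params[2])
        return -ncc(resample_to_fixed(mov, t, sp), fix)

    tx0, ty0 = _translation_init(mov_c, fix_c, sp_c)
    best = None
    for th0 in theta_starts:
        res = optimize.minimize(
            neg_ncc,
            x0=np.array([tx0, ty0, th0]),
            args=(mov_c, fix_c, sp_c),
            method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res

    res = optimize.minimize(
        neg_ncc,
        x0=best.x,
        args=(moving, fixed, spacing),
        method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-9, "maxiter": 2},
    )
    t = RigidTransform2D(float(res.x[0]), float(res.x[1]), float(res.x[2]))
    similarity = -float(res.fun)
    if similarity < similarity_floor:
        raise RegistrationFailureError(
            f"registration similarity {similarity:.3f} below floor {similarity_floor}"
        )
    return t, similarity
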