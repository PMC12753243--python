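"""ROI mask algebra and physical area measurement.

Implements the compartment definitions used for body-composition monitoring:

* the bowel-and-bone (BB) region — the convex hull of the SAT mask minus SAT
  and muscle, isolating internal structures (bowel gas, sacrum) whose
  intensities overlap muscle;
* intramuscular adipose tissue (IMAT) — muscle pixels brighter than the
  per-image ``mean + 1 SD`` of muscle intensities (a myosteatosis marker,
  derived in post-processing and never a segmentation class);
* lean muscle — muscle with IMAT removed;
* physical cross-sectional areas in cm², averaged over the three axial slices
  bracketing the S1 level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import EmptyROIError

__all__ = [
    "MaskSet", "AreaRecord", "build_bb_mask", "extract_imat", "lean_muscle",
    "roi_area", "mean_area_over_slices",
]


@dataclass
class MaskSet:
    """Per-scan binary ROI masks on a common grid."""

    muscle: np.ndarray
    sat: np.ndarray
    spacing: float
    bb: np.ndarray | None = None
    imat: np.ndarray | None = None
    lean_muscle: np.ndarray | None = None

    def __post_init__(self):
        grids = [g for g in (self.muscle, self.sat, self.bb, self.imat,
                             self.lean_muscle) if g is not None]
        if any(g.shape != self.muscle.shape for g in grids):
            raise ValueError("all masks must share shape")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if np.any(self.muscle & self.sat):
            raise ValueError("muscle and SAT masks must be disjoint")
        if self.imat is not None and np.any(self.imat & ~self.muscle):
            raise ValueError("imat must be a subset of muscle")

    def as_dict(self) -> dict:
        d = {"muscle": self.muscle, "sat": self.sat}
        for k in ("bb", "imat", "lean_muscle"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


@dataclass(frozen=True)
class AreaRecord:
    """One ROI area measurement: the mean over the S1±1 slices, in cm²."""

    patient_id: str
    timepoint_index: int
    acquisition_day: float
    roi: str
    area_cm2: float
    n_slices_used: int

    def __post_init__(self):
        if self.area_cm2 < 0:
            raise ValueError("area must be non-negative")
        if self.n_slices_used not in (1, 2, 3):
            raise ValueError("n_slices_used must be 1, 2 or 3")


def build_bb_mask(sat: np.ndarray, muscle: np.ndarray) -> np.ndarray:
    """Bowel-and-bone mask: ``convex_hull(sat) \\ sat \\ muscle``.

    The hull is taken over SAT pixel *centers*; a pixel belongs to the hull
    if its center lies inside or on the hull polygon (inclusive ties). The
    result is disjoint from both inputs by construction.
    """
    sat = np.asarray(sat, dtype=bool)
    muscle = np.asarray(muscle, dtype=bool)
    if sat.shape != muscle.shape:
        raise ValueError("sat and muscle masks must share shape")
    if not sat.any():
        raise EmptyROIError("cannot form convex hull of an empty SAT mask")

    pts = np.column_stack(np.nonzero(sat)).astype(float)
    hull_mask = np.zeros_like(sat)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # Degenerate (collinear / too few) point set: the hull has no interior,
        # so hull membership reduces to the SAT pixels themselves.
        hull_mask[sat] = True
    else:
        rows, cols = np.nonzero(~np.zeros_like(sat))  # all pixel centers
        all_pts = np.column_stack([rows, cols]).astype(float)
        a = hull.equations[:, :2]
        b = hull.equations[:, 2]
        inside = np.all(all_pts @ a.T + b <= 1e-9, axis=1)
        hull_mask = inside.reshape(sat.shape)
    return hull_mask & ~sat & ~muscle


def extract_imat(image: np.ndarray, muscle: np.ndarray) -> np.ndarray:
    """IMAT mask: muscle pixels with intensity strictly above the muscle-pixel
    ``mean + 1 SD`` of *this* image (population SD, per-image threshold)."""
    muscle = np.asarray(muscle, dtype=bool)
    if image.shape != muscle.shape:
        raise ValueError("image and muscle mask must share shape")
    if not muscle.any():
        raise EmptyROIError("IMAT threshold undefined for an empty muscle mask")
    vals = np.asarray(image, dtype=np.float64)[muscle]
    threshold = vals.mean() + vals.std(ddof=0)
    out = np.zeros_like(muscle)
    out[muscle] = np.asarray(image, dtype=np.float64)[muscle] > threshold
    return out


def lean_muscle(muscle: np.ndarray, imat: np.ndarray) -> np.ndarray:
    """Lean-muscle mask: ``muscle \\ imat``. Requires ``imat ⊆ muscle``."""
    muscle = np.asarray(muscle, dtype=bool)
    imat = np.asarray(imat, dtype=bool)
    if muscle.shape != imat.shape:
        raise ValueError("masks must share shape")
    if np.any(imat & ~muscle):
        raise ValueError("imat must be a subset of muscle")
    return muscle & ~imat


def roi_area(mask: np.ndarray, spacing: float) -> float:
    """Mask area in cm² (pixel count × spacing² mm² / 100)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return float(np.count_nonzero(mask)) * spacing ** 2 / 100.0


def mean_area_over_slices(masks, spacing: float, *, patient_id: str = "",
                          timepoint_index: int = 0, acquisition_day: float = 0.0,
                          roi: str = "") -> AreaRecord:
    """Arithmetic mean of per-slice areas over the 1–3 provided S1±1 slices."""
    masks = list(masks)
    if not masks:
        raise EmptyROIError("at least one slice mask is required")
    if len(masks) > 3:
        raise ValueError("at most three S1±1 slices are expected")
    areas = [roi_area(m, spacing) for m in masks]
    return AreaRecord(
        patient_id=patient_id,
        timepoint_index=timepoint_index,
        acquisition_day=acquisition_day,
        roi=roi,
        area_cm2=float(np.mean(areas)),
        n_slices_used=len(masks),
    )
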