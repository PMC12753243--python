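"""Segmentation-quality metrics: Dice, mean surface distance, HD95.

Conventions (stated so tabulated results are reproducible):

* surfaces are boundary pixel centers — mask pixels with at least one
  4-neighbor outside the mask, the grid border counting as outside;
* MSD symmetrizes by averaging the two directed mean boundary distances;
* HD95 is the 95th percentile (linear-interpolation method) of the *pooled*
  directed boundary distances from both masks;
* an empty mask makes surface distances undefined — that is a segmentation
  failure event, reported as an error rather than an infinite distance;
* cross-validation summaries are fold means with t-distribution 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .exceptions import InsufficientFoldsError, UndefinedMetricError

__all__ = [
    "dice", "boundary_points", "msd", "hd95", "summarize_cv", "CVSummary",
    "MetricsReport",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|a∩b| / (|a| + |b|)``; 1.0 when both
    masks are empty (perfect agreement on absence)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(N, 2) array of (row, col) boundary pixel coordinates: mask pixels with
    a 4-neighbor outside the mask (grid border counts as outside)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.column_stack(np.nonzero(mask & ~interior))


def _directed_distances(a: np.ndarray, b: np.ndarray, spacing: float):
    """Euclidean distances (mm) from each boundary point of ``a`` to the
    nearest boundary point of ``b``, and vice versa."""
    pa = boundary_points(a)
    pb = boundary_points(b)
    if len(pa) == 0 or len(pb) == 0:
        raise UndefinedMetricError(
            "surface distance undefined for an empty mask (segmentation failure)")
    d_ab = cKDTree(pb).query(pa)[0] * spacing
    d_ba = cKDTree(pa).query(pb)[0] * spacing
    return d_ab, d_ba


def msd(a: np.ndarray, b: np.ndarray, spacing: float = 1.0) -> float:
    """Mean surface distance (mm): average of the two directed mean boundary
    distances."""
    d_ab, d_ba = _directed_distances(a, b, spacing)
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))


def hd95(a: np.ndarray, b: np.ndarray, spacing: float = 1.0) -> float:
    """95th-percentile Hausdorff distance (mm) of the pooled directed boundary
    distances, linear-interpolation percentile."""
    d_ab, d_ba = _directed_distances(a, b, spacing)
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


@dataclass(frozen=True)
class CVSummary:
    mean: float
    ci_lo: float
    ci_hi: float
    n_folds: int


def summarize_cv(fold_values) -> CVSummary:
    """Mean and t-distribution 95% CI across cross-validation folds
    (df = n_folds − 1)."""
    vals = np.asarray(list(fold_values), dtype=float)
    n = len(vals)
    if n < 2:
        raise InsufficientFoldsError("at least two folds are required")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(n))
    half = float(stats.t.ppf(0.975, n - 1)) * sem
    return CVSummary(mean=mean, ci_lo=mean - half, ci_hi=mean + half, n_folds=n)


@dataclass
class MetricsReport:
    """Per-(ROI, model-variant) metric summaries across CV folds."""

    entries: dict = field(default_factory=dict)  # (roi, variant) -> {metric: CVSummary}

    def add(self, roi: str, variant: str, metric: str, fold_values) -> None:
        self.entries.setdefault((roi, variant), {})[metric] = summarize_cv(fold_values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (roi, variant), metrics in sorted(self.entries.items()):
            row = {"roi": roi, "variant": variant}
            for metric, s in metrics.items():
                row[f"{metric}_mean"] = s.mean
                row[f"{metric}_ci_lo"] = s.ci_lo
                row[f"{metric}_ci_hi"] = s.ci_hi
                row["n_folds"] = s.n_folds
            rows.append(row)
        return pd.DataFrame(rows)
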