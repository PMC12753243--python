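"""Longitudinal body-composition statistics.

Per-patient ROI areas become relative-change series (% vs the first fraction),
measurements with |change| > 10% are screened out as segmentation/registration
outliers, group trajectories are summarized with normal-approximation 95% CIs,
and distributions are compared with two-sided Mann–Whitney U tests (exact for
small tie-free samples, normal approximation with tie and continuity
correction otherwise). Raw p-values are reported; an optional
Benjamini–Hochberg adjustment can be switched on but is off by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import UndefinedChangeError

__all__ = [
    "ChangeSeries", "GroupComparison", "relative_change", "filter_outliers",
    "group_trajectory", "end_of_treatment_change", "mann_whitney_u",
    "benjamini_hochberg", "run_full_analysis",
]

OUTLIER_THRESHOLD_PCT = 10.0


@dataclass
class ChangeSeries:
    """Per-patient, per-ROI relative area changes vs the first fraction."""

    patient_id: str
    roi: str
    timepoint_index: list
    acquisition_day: list
    change_pct: list
    excluded: list = field(default_factory=list)       # bool per timepoint
    exclusion_reason: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.timepoint_index)
        if not self.excluded:
            self.excluded = [False] * n
        if not self.exclusion_reason:
            self.exclusion_reason = [""] * n


@dataclass(frozen=True)
class GroupComparison:
    comparison: str          # baseline_area | end_change | within_group_roi
    group_a: str
    group_b: str
    roi_a: str
    roi_b: str
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int


def relative_change(areas, timepoint_index=None, acquisition_day=None,
                    patient_id: str = "", roi: str = "") -> ChangeSeries:
    """Percentage differences from the first-fraction value:
    ``100 * (area_t - area_1) / area_1``."""
    areas = np.asarray(list(areas), dtype=float)
    if len(areas) == 0:
        raise UndefinedChangeError("empty area series")
    baseline = areas[0]
    if baseline <= 0:
        raise UndefinedChangeError("first-fraction area must be positive")
    changes = 100.0 * (areas - baseline) / baseline
    n = len(areas)
    tp = list(timepoint_index) if timepoint_index is not None else list(range(n))
    days = list(acquisition_day) if acquisition_day is not None else [float(i) for i in range(n)]
    return ChangeSeries(patient_id, roi, tp, days, [float(c) for c in changes])


def filter_outliers(series: ChangeSeries,
                    threshold_pct: float = OUTLIER_THRESHOLD_PCT) -> tuple:
    """Flag timepoints with |change| strictly greater than ``threshold_pct``.

    Exclusion is per measurement (a single ROI at a single timepoint), not per
    patient. Returns ``(series_with_flags, n_excluded)``; exactly ±threshold is
    kept.
    """
    out = ChangeSeries(
        series.patient_id, series.roi, list(series.timepoint_index),
        list(series.acquisition_day), list(series.change_pct),
        list(series.excluded), list(series.exclusion_reason),
    )
    n_excluded = 0
    for i, c in enumerate(out.change_pct):
        if abs(c) > threshold_pct and not out.excluded[i]:
            out.excluded[i] = True
            out.exclusion_reason[i] = f"relative_change_gt_{threshold_pct:g}pct"
            n_excluded += 1
    return out, n_excluded


def group_trajectory(series_list) -> pd.DataFrame:
    """Per-timepoint group mean and normal-approximation 95% CI
    (mean ± 1.96·SEM), after exclusions. Timepoints with fewer than two
    contributors get NaN CI bounds and ``ci_defined = False``."""
    rows = {}
    for s in series_list:
        for tp, day, c, ex in zip(s.timepoint_index, s.acquisition_day,
                                  s.change_pct, s.excluded):
            if not ex:
                rows.setdefault((tp, day), []).append(c)
    out = []
    for (tp, day), vals in sorted(rows.items()):
        vals = np.asarray(vals, dtype=float)
        mean = float(vals.mean())
        n = len(vals)
        if n >= 2:
            sem = float(vals.std(ddof=1) / np.sqrt(n))
            lo, hi = mean - 1.96 * sem, mean + 1.96 * sem
            defined = True
        else:
            sem, lo, hi, defined = np.nan, np.nan, np.nan, False
        out.append({"timepoint_index": tp, "acquisition_day": day, "mean_pct": mean,
                    "sem_pct": sem, "ci_lo_pct": lo, "ci_hi_pct": hi,
                    "n": n, "ci_defined": defined})
    return pd.DataFrame(out)


def end_of_treatment_change(series: ChangeSeries) -> float | None:
    """The final timepoint's relative change (first-to-last fraction), or
    ``None`` when that measurement was excluded (patient omitted from the
    comparison)."""
    if not series.change_pct:
        return None
    if series.excluded[-1]:
        return None
    return float(series.change_pct[-1])


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Returns ``(U, p)`` with ``U = min(U1, U2)`` under midrank tie handling.
    The p-value is exact (enumeration over placements) when ``n1 + n2 <= 16``
    and the pooled sample is tie-free, otherwise the normal approximation with
    tie and continuity corrections. p is capped at 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 16 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u1 = float(res.statistic)
    u = min(u1, len(x) * len(y) - u1)
    return u, float(min(res.pvalue, 1.0))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional multiplicity control)."""
    p = np.asarray(list(p_values), dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Full analysis over a tidy area table
# ---------------------------------------------------------------------------

_REQUIRED_COLS = {"patient_id", "group", "roi", "timepoint_index",
                  "acquisition_day", "area_cm2"}


def _series_by_patient(areas: pd.DataFrame,
                       threshold_pct: float) -> dict:
    """(group, roi) -> list of outlier-filtered ChangeSeries."""
    out: dict = {}
    for (pid, grp, roi), sub in areas.groupby(["patient_id", "group", "roi"]):
        sub = sub.sort_values("timepoint_index")
        s = relative_change(sub["area_cm2"].to_numpy(),
                            timepoint_index=sub["timepoint_index"].tolist(),
                            acquisition_day=sub["acquisition_day"].tolist(),
                            patient_id=pid, roi=roi)
        s, _ = filter_outliers(s, threshold_pct)
        out.setdefault((grp, roi), []).append(s)
    return out


def run_full_analysis(areas: pd.DataFrame, rois=("muscle", "sat", "imat"),
                      threshold_pct: float = OUTLIER_THRESHOLD_PCT,
                      adjust_p: bool = False,
                      allow_single_group: bool = False) -> dict:
    """The complete longitudinal report from a tidy area table.

    Input columns: patient_id, group, roi, timepoint_index, acquisition_day,
    area_cm2. Produces baseline-area comparisons for every group pair × ROI,
    end-of-treatment change comparisons for every group pair × ROI,
    within-group ROI-vs-ROI change comparisons, per-group trajectory tables,
    and the exclusion tally.
    """
    missing = _REQUIRED_COLS - set(areas.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    groups = sorted(areas["group"].unique())
    if len(groups) < 2 and not allow_single_group:
        raise ValueError("at least two groups are required")

    series = _series_by_patient(areas, threshold_pct)
    n_excluded = sum(sum(s.excluded) for ss in series.values() for s in ss)

    # (i) baseline areas
    comparisons = []
    first_tp = areas["timepoint_index"].min()
    baseline = areas[areas["timepoint_index"] == first_tp]
    for roi in rois:
        for ga, gb in itertools.combinations(groups, 2):
            xa = baseline[(baseline["group"] == ga) & (baseline["roi"] == roi)]["area_cm2"]
            xb = baseline[(baseline["group"] == gb) & (baseline["roi"] == roi)]["area_cm2"]
            if len(xa) == 0 or len(xb) == 0:
                continue
            u, p = mann_whitney_u(xa, xb)
            comparisons.append(GroupComparison("baseline_area", ga, gb, roi, roi,
                                               u, p, len(xa), len(xb)))

    # (ii) end-of-treatment changes, between groups
    end_changes: dict = {}
    for (grp, roi), ss in series.items():
        end_changes[(grp, roi)] = [v for v in map(end_of_treatment_change, ss)
                                   if v is not None]
    for roi in rois:
        for ga, gb in itertools.combinations(groups, 2):
            xa = end_changes.get((ga, roi), [])
            xb = end_changes.get((gb, roi), [])
            if not xa or not xb:
                continue
            u, p = mann_whitney_u(xa, xb)
            comparisons.append(GroupComparison("end_change", ga, gb, roi, roi,
                                               u, p, len(xa), len(xb)))

    # (iii) within-group ROI-vs-ROI change comparisons
    for grp in groups:
        for ra, rb in itertools.combinations(rois, 2):
            xa = end_changes.get((grp, ra), [])
            xb = end_changes.get((grp, rb), [])
            if not xa or not xb:
                continue
            u, p = mann_whitney_u(xa, xb)
            comparisons.append(GroupComparison("within_group_roi", grp, grp,
                                               ra, rb, u, p, len(xa), len(xb)))

    comp_df = pd.DataFrame([c.__dict__ for c in comparisons])
    if adjust_p and len(comp_df):
        comp_df["p_adjusted"] = benjamini_hochberg(comp_df["p_value"])

    trajectories = []
    for (grp, roi), ss in series.items():
        t = group_trajectory(ss)
        t.insert(0, "group", grp)
        t.insert(1, "roi", roi)
        trajectories.append(t)
    traj_df = pd.concat(trajectories, ignore_index=True) if trajectories else pd.DataFrame()

    end_rows = [
        {"group": grp, "roi": roi, "mean_pct": float(np.mean(v)),
         "sem_pct": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
         "n": len(v)}
        for (grp, roi), v in sorted(end_changes.items()) if v
    ]

    return {
        "comparisons": comp_df,
        "trajectories": traj_df,
        "end_of_treatment": pd.DataFrame(end_rows),
        "n_excluded": int(n_excluded),
    }
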