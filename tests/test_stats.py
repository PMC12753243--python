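"""Longitudinal statistics: relative changes, outlier filter, trajectories,
Mann-Whitney U against an exhaustive permutation oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mrbodycomp.exceptions import UndefinedChangeError
from mrbodycomp.stats import (benjamini_hochberg, end_of_treatment_change,
                              filter_outliers, group_trajectory,
                              mann_whitney_u, relative_change,
                              run_full_analysis)


class TestRelativeChange:
    def test_basic_percentages(self):
        s = relative_change([100.0, 99.0])
        assert s.change_pct == pytest.approx([0.0, -1.0])

    def test_constant_series_all_zero(self):
        s = relative_change([7.5] * 5)
        assert s.change_pct == pytest.approx([0.0] * 5)

    def test_exact_ten_percent_not_excluded(self):
        s = relative_change([50.0, 55.0])
        assert s.change_pct == pytest.approx([0.0, 10.0])
        s, n = filter_outliers(s)
        assert n == 0 and not any(s.excluded)

    def test_zero_baseline_raises(self):
        with pytest.raises(UndefinedChangeError):
            relative_change([0.0, 1.0])


class TestOutlierFilter:
    def test_threshold_rule(self):
        s = relative_change([100, 99, 88])  # 0, -1, -12 %
        s, n = filter_outliers(s)
        assert n == 1
        assert s.excluded == [False, False, True]
        assert "10" in s.exclusion_reason[2]

    def test_nothing_excluded_within_band(self):
        s = relative_change([100, 95, 105, 109.9])
        s, n = filter_outliers(s)
        assert n == 0

    def test_exclusion_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            areas = 100 * (1 + rng.normal(0, 0.08, size=6))
            areas[0] = 100.0
            s = relative_change(areas)
            kept = []
            for thr in (15.0, 10.0, 5.0, 2.0):
                filtered, _ = filter_outliers(s, thr)
                kept.append(sum(not e for e in filtered.excluded))
            assert kept == sorted(kept, reverse=True)

    def test_end_of_treatment_omits_excluded_endpoint(self):
        s = relative_change([100, 99, 80])
        s, _ = filter_outliers(s)
        assert end_of_treatment_change(s) is None
        s2 = relative_change([100, 99, 97])
        s2, _ = filter_outliers(s2)
        assert end_of_treatment_change(s2) == pytest.approx(-3.0)


class TestGroupTrajectory:
    def test_identical_patients_zero_width(self):
        series = [relative_change([100, 98]) for _ in range(4)]
        t = group_trajectory(series)
        assert t["ci_hi_pct"].iloc[1] == pytest.approx(t["ci_lo_pct"].iloc[1])

    def test_two_patient_closed_form(self):
        s1 = relative_change([100, 99])   # -1%
        s2 = relative_change([100, 97])   # -3%
        t = group_trajectory([s1, s2])
        row = t[t["timepoint_index"] == 1].iloc[0]
        assert row["mean_pct"] == pytest.approx(-2.0)
        assert row["sem_pct"] == pytest.approx(1.0)
        assert row["ci_lo_pct"] == pytest.approx(-3.96)
        assert row["ci_hi_pct"] == pytest.approx(-0.04)

    def test_baseline_timepoint_degenerate(self):
        series = [relative_change([100, 99]), relative_change([80, 79])]
        t = group_trajectory(series)
        assert t["mean_pct"].iloc[0] == pytest.approx(0.0)
        assert t["ci_hi_pct"].iloc[0] - t["ci_lo_pct"].iloc[0] == pytest.approx(0.0)

    def test_single_contributor_flagged(self):
        t = group_trajectory([relative_change([100, 99])])
        assert not t["ci_defined"].iloc[1]


def _mwu_oracle(x, y):
    """Exhaustive enumeration over all placements of the pooled tie-free
    sample; two-sided p from the exact null distribution of U1."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u1_obs = sum(1 for xi in x for yi in y if xi > yi)
    u_min = min(u1_obs, n1 * (len(pooled) - n1) - u1_obs)
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), n1):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        u1 = sum(1 for xi in xs for yi in ys if xi > yi)
        u2 = n1 * len(ys) - u1
        if min(u1, u2) <= u_min:
            count += 1
        total += 1
    return u_min, count / total


class TestMannWhitney:
    def test_extreme_placement(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            u, p = mann_whitney_u(x, y)
            u_o, p_o = _mwu_oracle(x, y)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_zero_signal_false_positive_rate(self):
        """Null calibration: ~5% of comparisons significant at alpha=0.05
        across 200 replicates of zero-signal measurement noise."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(0.0, 1.0, size=12)
            y = rng.normal(0.0, 1.0, size=12)
            _, p = mann_whitney_u(x, y)
            if p < 0.05:
                hits += 1
        rate = hits / n_rep
        sd = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + 3 * sd  # one-sided: anti-conservative is the failure mode
        assert rate >= 0.0


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, size=17)
        got = benjamini_hochberg(p)
        want = multipletests(p, method="fdr_bh")[1]
        assert got == pytest.approx(want)


class TestFullAnalysis:
    @staticmethod
    def _toy_areas():
        rows = []
        rng = np.random.default_rng(5)
        for g, drift in (("fast", -0.02), ("slow", 0.0)):
            for i in range(8):
                base = rng.uniform(80, 120)
                for tp, day in enumerate([0, 7, 14, 21, 27]):
                    for roi in ("muscle", "sat", "imat"):
                        area = base * (1 + drift * tp) * (1 + rng.normal(0, 0.002))
                        rows.append({"patient_id": f"{g}{i}", "group": g,
                                     "roi": roi, "timepoint_index": tp,
                                     "acquisition_day": day, "area_cm2": area})
        return pd.DataFrame(rows)

    def test_report_structure_and_detection(self):
        report = run_full_analysis(self._toy_areas())
        comps = report["comparisons"]
        kinds = set(comps["comparison"])
        assert kinds == {"baseline_area", "end_change", "within_group_roi"}
        end = comps[(comps["comparison"] == "end_change")
                    & (comps["roi_a"] == "muscle")]
        assert (end["p_value"] < 0.05).all()  # -8% vs 0% over 8+8 patients
        assert not report["trajectories"].empty
        u = comps["u_statistic"]
        assert ((0 <= u) & (u <= comps["n_a"] * comps["n_b"])).all()

    def test_requires_two_groups(self):
        df = self._toy_areas()
        with pytest.raises(ValueError):
            run_full_analysis(df[df["group"] == "fast"])
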