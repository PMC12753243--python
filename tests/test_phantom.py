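"""Phantom generator: geometry invariants, programmed atrophy, misalignment,
cohort determinism."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage

from mrbodycomp import phantom as ph
from mrbodycomp.exceptions import (DegenerateAnatomyError, InvalidSpecError,
                                   OutOfFieldError)
from mrbodycomp.registration import RigidTransform2D


class TestMakeAnatomy:
    def test_label_vocabulary_and_partition(self, anatomy96):
        labs = np.unique(anatomy96.labels)
        assert set(labs) <= set(ph.LABEL_NAMES)
        # every declared compartment class is present
        for lab in (ph.MUSCLE, ph.SAT, ph.BONE, ph.BOWEL, ph.GAS, ph.IMAT):
            assert (anatomy96.labels == lab).any()

    def test_sat_ring_encloses_all_muscle(self, anatomy96):
        sat = anatomy96.labels == ph.SAT
        enclosed = ndimage.binary_fill_holes(sat)
        assert enclosed[ph.muscle_mask(anatomy96.labels)].all()

    def test_determinism(self):
        spec = ph.default_spec(96)
        a = ph.make_anatomy(spec, seed=3)
        b = ph.make_anatomy(spec, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_zero_sat_thickness_invalid(self):
        spec = replace(ph.default_spec(96), sat_thickness=0.0)
        with pytest.raises(InvalidSpecError):
            ph.make_anatomy(spec, seed=0)

    def test_imat_fraction_bounds(self):
        spec = replace(ph.default_spec(96), imat_fraction=0.5)
        with pytest.raises(InvalidSpecError):
            ph.make_anatomy(spec, seed=0)

    def test_exact_imat_count(self):
        spec = ph.default_spec(128)
        sl = ph.make_anatomy(spec, seed=5)
        n_muscle = int(ph.muscle_mask(sl.labels).sum())
        n_imat = int((sl.labels == ph.IMAT).sum())
        assert n_imat == round(spec.imat_fraction * n_muscle)


class TestRenderIntensities:
    def test_noiseless_renders_exact_means(self, anatomy96):
        model = ph.IntensityModel(
            sds={k: 0.0 for k in ph.IntensityModel().sds}, noise_sigma=0.0)
        img = ph.render_intensities(anatomy96.labels, model, seed=0)
        muscle_only = anatomy96.labels == ph.MUSCLE
        assert np.allclose(img[muscle_only], model.means["muscle"])
        assert np.allclose(img[anatomy96.labels == ph.IMAT], model.means["sat"])

    def test_default_contrast_ordering(self, rendered96):
        img, lab = rendered96.image, rendered96.labels
        assert (img[lab == ph.SAT].mean() > img[lab == ph.MUSCLE].mean()
                > img[lab == ph.GAS].mean())

    def test_invalid_ordering_rejected(self):
        means = dict(ph.IntensityModel().means)
        means["muscle"] = means["sat"] + 1
        with pytest.raises(InvalidSpecError):
            ph.render_intensities(np.zeros((4, 4), np.uint8),
                                  ph.IntensityModel(means=means), seed=0)


class TestApplyAtrophy:
    def test_zero_rate_is_identity(self, anatomy96):
        out = ph.apply_atrophy(anatomy96, {"muscle": 0, "sat": 0, "imat": 0}, 27)
        assert np.array_equal(out.labels, anatomy96.labels)

    @pytest.mark.parametrize("roi,rate", [
        ("muscle", -1.0 / 27), ("sat", -1.9 / 27), ("imat", -1.8 / 27)])
    def test_programmed_change_within_tolerance(self, roi, rate):
        sl = ph.make_anatomy(ph.default_spec(256), seed=9)
        out = ph.apply_atrophy(sl, {roi: rate * 100 / 100}, 27.0)

        def count(labels, roi):
            if roi == "muscle":
                return ph.muscle_mask(labels).sum()
            if roi == "sat":
                return (labels == ph.SAT).sum()
            return (labels == ph.IMAT).sum()

        realized = 100 * (count(out.labels, roi) / count(sl.labels, roi) - 1)
        assert realized == pytest.approx(rate * 27 * 100 / 100, abs=0.2)

    def test_growth_also_supported(self, anatomy96):
        out = ph.apply_atrophy(anatomy96, {"muscle": 0.2}, 10.0)
        n0 = ph.muscle_mask(anatomy96.labels).sum()
        n1 = ph.muscle_mask(out.labels).sum()
        assert n1 == round(n0 * 1.02)

    def test_emptying_compartment_raises(self, anatomy96):
        with pytest.raises(DegenerateAnatomyError):
            ph.apply_atrophy(anatomy96, {"muscle": -5.0}, 27.0)

    def test_masks_stay_disjoint(self, anatomy96):
        out = ph.apply_atrophy(
            anatomy96, {"muscle": -0.1, "sat": 0.05, "imat": -0.2}, 20.0)
        m = ph.muscle_mask(out.labels)
        s = out.labels == ph.SAT
        assert not (m & s).any()
        assert ((out.labels == ph.IMAT) & ~m).sum() == 0


class TestApplyMisalignment:
    def test_identity_is_bitwise(self, rendered96):
        out = ph.apply_misalignment(rendered96, RigidTransform2D())
        assert np.array_equal(out.labels, rendered96.labels)
        assert np.array_equal(out.image, rendered96.image)

    def test_translation_moves_centroid(self, rendered96):
        t = RigidTransform2D(tx_mm=15.0, ty_mm=0.0)  # 3 px at 5 mm spacing
        out = ph.apply_misalignment(rendered96, t)
        c0 = ndimage.center_of_mass(rendered96.labels != ph.BACKGROUND)
        c1 = ndimage.center_of_mass(out.labels != ph.BACKGROUND)
        dx_mm = (c1[1] - c0[1]) * rendered96.spacing
        assert dx_mm == pytest.approx(15.0, abs=0.5 * rendered96.spacing)
        assert abs(c1[0] - c0[0]) < 0.5

    def test_label_vocabulary_preserved(self, rendered96):
        out = ph.apply_misalignment(rendered96, RigidTransform2D(3.0, -2.0, 2.0))
        assert set(np.unique(out.labels)) <= set(np.unique(rendered96.labels))

    def test_out_of_field_raises(self, rendered96):
        with pytest.raises(OutOfFieldError):
            ph.apply_misalignment(rendered96, RigidTransform2D(tx_mm=400.0))


class TestMakeCohort:
    @staticmethod
    def _small_cohort(seed=1, **group_kw):
        g = ph.group_preset("20adt", n_patients=group_kw.pop("n_patients", 3))
        spec = ph.CohortSpec(groups=(g,), phantom=ph.default_spec(96),
                             seed=seed, **group_kw)
        return ph.make_cohort(spec)

    def test_schedule_structure(self):
        ds = self._small_cohort()
        assert len(ds.patients) == 3
        for p in ds.patients:
            assert len(p.scans) == 5
            days = [s.acquisition_day for s in p.scans]
            assert days[-1] - days[0] == 27
            assert all(len(s.slices) == 3 for s in p.scans)

    def test_determinism_bitwise(self):
        a = self._small_cohort(seed=4)
        b = self._small_cohort(seed=4)
        assert a.truth_log() == b.truth_log()
        for pa, pb in zip(a.patients, b.patients):
            for sa, sb in zip(pa.scans, pb.scans):
                for la, lb in zip(sa.slices, sb.slices):
                    assert np.array_equal(la.labels, lb.labels)
                    assert np.array_equal(la.image, lb.image)

    def test_zero_rates_zero_misalignment_static(self):
        g = ph.GroupSpec("static", 2, (0.0, 2.0, 4.0, 7.0, 10.0),
                         ph.AtrophyModel())
        spec = ph.CohortSpec(
            groups=(g,), phantom=ph.default_spec(96),
            misalignment=ph.MisalignmentModel(0.0, 0.0), seed=2)
        ds = ph.make_cohort(spec)
        for p in ds.patients:
            ref = p.scans[0]
            for scan in p.scans[1:]:
                for a, b in zip(ref.slices, scan.slices):
                    assert np.array_equal(a.labels, b.labels)

    def test_programmed_group_mean_converges(self):
        """Sample mean of programmed end-of-schedule muscle change is within
        2 SEM of the preset mean for n >= 20 patients."""
        g = ph.group_preset("20adt", n_patients=20)
        spec = ph.CohortSpec(groups=(g,), phantom=ph.default_spec(96), seed=6)
        ds = ph.make_cohort(spec)
        changes = [p.rates_pct_per_day["muscle"] * 27 for p in ds.patients]
        mean = np.mean(changes)
        sem = np.std(changes, ddof=1) / np.sqrt(len(changes))
        assert abs(mean - (-1.0)) <= 2 * sem

    def test_truth_log_records_transforms_and_areas(self):
        ds = self._small_cohort()
        log = ds.truth_log()
        p0 = log["patients"][0]
        assert set(p0["rates_pct_per_day"]) == {"muscle", "sat", "imat"}
        assert p0["scans"][0]["transform"] == {"tx_mm": 0.0, "ty_mm": 0.0,
                                               "theta_deg": 0.0}
        assert p0["scans"][1]["transform"] != p0["scans"][0]["transform"]
        assert all(r in p0["scans"][0]["true_area_cm2"]
                   for r in ("muscle", "sat", "imat", "lean_muscle"))
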