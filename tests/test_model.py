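"""Segmentation harness: fold rotation, combined loss values, config
validation, training determinism, prediction contracts, QC flags."""

import numpy as np
import pytest

from mrbodycomp import phantom as ph
from mrbodycomp.exceptions import InvalidConfigError
from mrbodycomp.masks import MaskSet
from mrbodycomp.metrics import dice
from mrbodycomp.model import (TrainConfig, UNetSegmenter, combined_loss,
                              labels_to_classes, make_folds, predict_masks,
                              qc_flags, train_variant)


class TestFolds:
    def test_45_images_five_nines(self):
        folds = make_folds(range(45), k=5, seed=0)
        assert [len(f) for f in folds.folds] == [9] * 5
        all_ids = [i for f in folds.folds for i in f]
        assert sorted(all_ids) == list(range(45))
        evaluated = []
        for r in range(5):
            tr, va, ev = folds.rotation(r)
            assert len(tr) == 27 and len(va) == 9 and len(ev) == 9
            assert set(tr) | set(va) | set(ev) == set(range(45))
            assert not (set(tr) & set(ev)) and not (set(va) & set(ev))
            evaluated.extend(ev)
        assert sorted(evaluated) == list(range(45))  # each image once

    def test_n_equals_k(self):
        folds = make_folds(range(5), k=5, seed=1)
        assert [len(f) for f in folds.folds] == [1] * 5

    def test_too_few_images(self):
        with pytest.raises(ValueError):
            make_folds(range(3), k=5)

    def test_deterministic(self):
        assert make_folds(range(20), seed=7) == make_folds(range(20), seed=7)


class TestCombinedLoss:
    def test_perfect_prediction(self):
        onehot = np.zeros((1, 3, 2, 2), dtype=np.float32)
        onehot[0, 2] = 1.0
        assert combined_loss(onehot, onehot) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_ce_term(self):
        c = 3
        onehot = np.zeros((1, c, 2, 2), dtype=np.float32)
        onehot[0, 0] = 1.0
        uniform = np.full_like(onehot, 1.0 / c)
        got = combined_loss(uniform, onehot, w_ce=1.0, w_dice=0.0)
        assert got == pytest.approx(np.log(c))

    def test_two_class_single_pixel_hand_values(self):
        # p = (0.8, 0.2), target class 0:
        # CE = -ln 0.8; dice_0 = 2*0.8/(0.8+1) = 0.888..., dice_1 ~ 0
        probs = np.array([0.8, 0.2], dtype=np.float32).reshape(1, 2, 1, 1)
        onehot = np.array([1.0, 0.0], dtype=np.float32).reshape(1, 2, 1, 1)
        ce = combined_loss(probs, onehot, w_ce=1.0, w_dice=0.0)
        assert ce == pytest.approx(-np.log(0.8), abs=1e-6)
        dice_term = combined_loss(probs, onehot, w_ce=0.0, w_dice=1.0)
        expected = 1.0 - 0.5 * (2 * 0.8 / 1.8 + 0.0)
        assert dice_term == pytest.approx(expected, abs=1e-4)


class TestTrainConfig:
    def test_indivisible_image_size_rejected(self):
        with pytest.raises(InvalidConfigError):
            TrainConfig(image_size=100).validate()

    def test_bad_lr_and_weights(self):
        with pytest.raises(InvalidConfigError):
            TrainConfig(learning_rate=0.0).validate()
        with pytest.raises(InvalidConfigError):
            TrainConfig(loss_weights=(0.0, 0.0)).validate()

    def test_variant_class_sets(self):
        a = TrainConfig(variant="A")
        b = TrainConfig(variant="B")
        assert set(a.classes) - set(b.classes) == {"bb"}


class TestLabelsToClasses:
    def test_imat_is_muscle_and_bb_present_for_A(self, anatomy96):
        cm = labels_to_classes(anatomy96.labels, "A")
        imat = anatomy96.labels == ph.IMAT
        assert (cm[imat] == 1).all()
        assert set(np.unique(cm)) == {0, 1, 2, 3}
        cm_b = labels_to_classes(anatomy96.labels, "B")
        assert set(np.unique(cm_b)) == {0, 1, 2}
        # interior non-muscle/SAT becomes BB for A, background for B
        viscera = anatomy96.labels == ph.VISCERA
        assert (cm[viscera] == 3).all()
        assert (cm_b[viscera] == 0).all()


@pytest.fixture(scope="module")
def tiny_trained(training_slices):
    """A small but genuinely trained variant-A segmenter (15 slices, one CV
    rotation) used by the behavioural tests below."""
    slices = training_slices[:15]
    cfg = TrainConfig(variant="A", image_size=96, max_epochs=110,
                      early_stop_patience=110, seed=5)
    folds = make_folds(range(15), k=5, seed=5)
    seg = train_variant(slices, cfg, fold=0, folds=folds)
    return seg, slices


class TestTraining:
    def test_zero_epochs_returns_initialized_network(self, training_slices):
        cfg = TrainConfig(variant="B", image_size=96, max_epochs=0, seed=0)
        seg = train_variant(training_slices[:6], cfg, fold=0,
                            folds=make_folds(range(6), k=3, seed=0))
        X = np.stack([s.image for s in training_slices[:2]])
        pred = seg.predict(X)
        assert pred.shape == (2, 96, 96)
        assert set(np.unique(pred)) <= {0, 1, 2}

    def test_inference_deterministic(self, tiny_trained):
        seg, slices = tiny_trained
        X = np.stack([slices[0].image])
        assert np.array_equal(seg.predict(X), seg.predict(X))

    def test_training_learns_anatomy(self, tiny_trained):
        seg, slices = tiny_trained
        assert seg.best_val_dice_ > 0.8
        ev = seg.eval_indices_
        X = np.stack([slices[i].image for i in ev])
        y = np.stack([labels_to_classes(slices[i].labels, "A") for i in ev])
        pred = seg.predict(X)
        muscle = np.mean([dice(pred[i] == 1, y[i] == 1) for i in range(len(ev))])
        assert muscle > 0.8

    def test_flip_equivariance(self, tiny_trained):
        """Horizontally flipping the input flips the predicted compartments
        (IoU >= 0.8 between flip(predict(x)) and predict(flip(x)))."""
        seg, slices = tiny_trained
        x = slices[seg.eval_indices_[0]].image
        pred = seg.predict(x[None])[0]
        pred_of_flipped = seg.predict(x[None, :, ::-1].copy())[0]
        a = pred[:, ::-1] == 1
        b = pred_of_flipped == 1
        iou = (a & b).sum() / max((a | b).sum(), 1)
        assert iou >= 0.8

    def test_fit_determinism(self, training_slices):
        """Two runs with identical config and seed give identical weights and
        validation history."""
        slices = training_slices[:8]
        X = np.stack([s.image for s in slices])
        y = np.stack([labels_to_classes(s.labels, "B") for s in slices])
        runs = []
        for _ in range(2):
            seg = UNetSegmenter(variant="B", image_size=96, max_epochs=3,
                                seed=11)
            seg.fit(X[:6], y[:6], X[6:], y[6:])
            runs.append(seg)
        assert runs[0].history_ == runs[1].history_
        for a, b in zip(runs[0].net_.state_dict(), runs[1].net_.state_dict()):
            assert np.array_equal(a, b)

    def test_sklearn_param_interface(self):
        seg = UNetSegmenter(variant="B", max_epochs=7)
        params = seg.get_params()
        assert params["variant"] == "B" and params["max_epochs"] == 7
        seg.set_params(max_epochs=9)
        assert seg.max_epochs == 9


class TestPredictMasksAndQC:
    def test_predict_masks_variant_classes(self, tiny_trained):
        seg, slices = tiny_trained
        sl = slices[seg.eval_indices_[0]]
        ms = predict_masks(seg, sl.image, spacing=sl.spacing)
        assert ms.bb is not None  # variant A carries a BB mask
        assert not (ms.muscle & ms.sat).any()

    def test_qc_clean_ground_truth(self, rendered96):
        ms = MaskSet(muscle=ph.muscle_mask(rendered96.labels),
                     sat=rendered96.labels == ph.SAT,
                     spacing=rendered96.spacing)
        assert qc_flags(ms) == []

    def test_qc_empty_roi(self, rendered96):
        ms = MaskSet(muscle=np.zeros_like(rendered96.labels, dtype=bool),
                     sat=rendered96.labels == ph.SAT,
                     spacing=rendered96.spacing)
        assert "empty_roi:muscle" in qc_flags(ms)

    def test_qc_relative_change_flag(self, rendered96):
        from mrbodycomp.masks import roi_area
        muscle = ph.muscle_mask(rendered96.labels)
        ms = MaskSet(muscle=muscle, sat=rendered96.labels == ph.SAT,
                     spacing=rendered96.spacing)
        area = roi_area(muscle, rendered96.spacing)
        flags = qc_flags(ms, prior_area_cm2={"muscle": area / 1.11})
        assert any(f.startswith("relative_change_gt_10pct") for f in flags)
        # 10% exactly is not an outlier (strict inequality)
        flags_ok = qc_flags(ms, prior_area_cm2={"muscle": area / 1.0999})
        assert not any(f.startswith("relative_change") for f in flags_ok)

    def test_qc_edge_and_fragmentation(self, rendered96):
        bad = np.zeros_like(rendered96.labels, dtype=bool)
        bad[0, :10] = True  # touches the border
        rng = np.random.default_rng(0)
        speckle = rng.random(bad.shape) < 0.01  # ~90 isolated pixels
        ms = MaskSet(muscle=bad | speckle, sat=np.zeros_like(bad),
                     spacing=rendered96.spacing)
        flags = qc_flags(ms)
        assert "touches_image_edge:muscle" in flags
        assert "fragmented:muscle" in flags
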