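import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hemocascade import (
    BinaryFilterModel,
    ClsTrainConfig,
    FusionModel,
    LabelMask,
    SubtypeLabels,
    build_fusion_input,
    compute_roi,
    crop_and_resize,
    focal_loss,
    predict_subtypes,
    train_binary_filter,
    train_multilabel,
)


class TestFocalLoss:
    def test_gamma_zero_alpha_one_is_cross_entropy_at_half(self):
        assert focal_loss(np.array([0.5]), np.array([1.0]), gamma=0, alpha=1) == (
            pytest.approx(0.6931, abs=1e-4)
        )

    def test_confident_correct_prediction_vanishes(self):
        assert focal_loss(np.array([1.0 - 1e-7]), np.array([1.0])) < 1e-6

    def test_hand_arithmetic_example(self):
        # 0.25 * (1-0.3)^2 * (-ln 0.3) = 0.25 * 0.49 * 1.20397
        val = focal_loss(np.array([0.3]), np.array([1.0]), gamma=2.0, alpha=0.25)
        assert val == pytest.approx(0.25 * 0.49 * -np.log(0.3), abs=1e-6)
        assert val == pytest.approx(0.1475, abs=2e-4)

    def test_out_of_range_probs_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([1.2]), np.array([1.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([0.5, 0.5]), np.array([1.0]))

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        p=hnp.arrays(
            np.float64, (10,), elements=st.floats(1e-6, 1 - 1e-6, allow_nan=False)
        ),
        t=hnp.arrays(np.int8, (10,), elements=st.integers(0, 1)),
    )
    def test_reduces_to_binary_cross_entropy(self, p, t):
        """Oracle: focal(gamma=0, alpha=1) == BCE to 1e-9."""
        t = t.astype(np.float64)
        bce = float(np.mean(-(t * np.log(p) + (1 - t) * np.log(1 - p))))
        assert focal_loss(p, t, gamma=0.0, alpha=1.0) == pytest.approx(bce, abs=1e-9)


def _filter_data(n=24, side=32, seed=0):
    rng = np.random.default_rng(seed)
    data = []
    for i in range(n):
        img = rng.random((side, side)).astype(np.float32) * 0.3
        has = i % 2 == 0
        if has:
            r, c = rng.integers(4, side - 10, size=2)
            img[r : r + 6, c : c + 6] += 0.5
        data.append((img, has))
    return data


class TestBinaryFilter:
    def test_single_class_rejected(self):
        data = [(np.zeros((16, 16), np.float32), True)] * 4
        with pytest.raises(ValueError):
            train_binary_filter(data, ClsTrainConfig(epochs=1))

    def test_smoke_epoch_finite_loss(self):
        model = train_binary_filter(_filter_data(), ClsTrainConfig(epochs=1, seed=0))
        assert np.isfinite(model.loss_history[0])

    def test_deterministic_inference_and_checkpoint(self, tmp_path):
        data = _filter_data()
        model = train_binary_filter(data, ClsTrainConfig(epochs=2, seed=1))
        p1 = model.predict_proba(data[0][0])
        assert p1 == model.predict_proba(data[0][0])
        path = model.save(tmp_path / "f.ckpt")
        back = BinaryFilterModel.load(path)
        assert back.predict_proba(data[0][0]) == p1

    def test_learns_contrast_separation(self):
        data = _filter_data(n=40)
        model = train_binary_filter(
            data, ClsTrainConfig(epochs=15, seed=2, lr=1e-2)
        )
        acc = np.mean([model.predict(x) == y for x, y in data])
        assert acc >= 0.8

    def test_non_tiny_backbone_placeholder(self):
        with pytest.raises(NotImplementedError):
            ClsTrainConfig(backbone="resnet50")


class TestFusionInput:
    def test_empty_mask_no_roi_degenerates_to_global(self):
        slc = np.random.default_rng(0).random((32, 32)).astype(np.float32)
        mask = LabelMask(np.zeros((32, 32), np.uint8))
        fi = build_fusion_input(slc, mask, roi=None)
        np.testing.assert_array_equal(fi.local_view, fi.global_view)
        assert not fi.global_view[1].any()

    def test_global_mask_channel_is_exact_mask(self, rng):
        slc = rng.random((32, 32)).astype(np.float32)
        mask = LabelMask((rng.random((32, 32)) < 0.2).astype(np.uint8))
        roi = compute_roi(mask.binary(), margin=4)
        fi = build_fusion_input(slc, mask, roi)
        np.testing.assert_array_equal(fi.global_view[1], mask.binary().astype(np.float32))

    def test_local_intensity_channel_is_roi_crop(self, rng):
        slc = rng.random((32, 32)).astype(np.float32)
        mask = LabelMask((rng.random((32, 32)) < 0.2).astype(np.uint8))
        roi = compute_roi(mask.binary(), margin=4)
        fi = build_fusion_input(slc, mask, roi, local_side=32)
        np.testing.assert_array_equal(
            fi.local_view[0], crop_and_resize(slc, roi, 32, is_mask=False)
        )

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(ValueError):
            build_fusion_input(
                np.zeros((32, 32)), LabelMask(np.zeros((16, 16), np.uint8)), None
            )


def _fusion_data(n=16, side=32, seed=0):
    rng = np.random.default_rng(seed)
    data = []
    for i in range(n):
        img = rng.random((side, side)).astype(np.float32) * 0.3
        mask = np.zeros((side, side), dtype=np.uint8)
        labels = SubtypeLabels()
        if i % 2 == 0:
            r, c = rng.integers(4, side - 10, size=2)
            mask[r : r + 6, c : c + 6] = 1
            img[mask > 0] += 0.4
            labels = SubtypeLabels(iph=True)
        roi = None if not mask.any() else compute_roi(mask, margin=4)
        data.append((build_fusion_input(img, LabelMask(mask), roi), labels))
    return data


class TestMultilabel:
    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            train_multilabel([], ClsTrainConfig(task="multilabel", epochs=1))

    def test_checkpoint_reload_identical_probabilities(self, tmp_path):
        data = _fusion_data()
        model = train_multilabel(data, ClsTrainConfig(task="multilabel", epochs=2, seed=3))
        probs = model.predict_proba(data[0][0])
        path = model.save(tmp_path / "m.ckpt")
        back = FusionModel.load(path)
        np.testing.assert_array_equal(back.predict_proba(data[0][0]), probs)

    def test_probabilities_valid_and_threshold_zero_all_true(self):
        data = _fusion_data()
        model = train_multilabel(data, ClsTrainConfig(task="multilabel", epochs=1, seed=4))
        labels, probs = predict_subtypes(model, data[0][0], threshold=0.0)
        assert probs.shape == (5,)
        assert (probs >= 0).all() and (probs <= 1).all()
        assert labels.to_array().all()

    def test_deterministic_prediction(self):
        data = _fusion_data()
        model = train_multilabel(data, ClsTrainConfig(task="multilabel", epochs=1, seed=5))
        a = model.predict_proba(data[1][0])
        b = model.predict_proba(data[1][0])
        np.testing.assert_array_equal(a, b)

    def test_global_only_ablation_has_single_backbone(self):
        data = _fusion_data()
        model = train_multilabel(
            data, ClsTrainConfig(task="multilabel", epochs=1, seed=6), global_only=True
        )
        assert len(model.backbones) == 1
        assert model.predict_proba(data[0][0]).shape == (5,)
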