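import numpy as np
import pytest

from hemocascade import (
    AugmentPolicy,
    LabelMask,
    SegModel,
    SegTrainConfig,
    augment,
    cascade_predict,
    dice_loss,
    dice_score,
    train_stage,
    vote,
)
from hemocascade.segmentation import DICE_EPS, draw_augment_params, make_stage2_dataset


def _tiny_data(n=8, side=32, seed=0):
    rng = np.random.default_rng(seed)
    data = []
    for i in range(n):
        img = rng.random((side, side)).astype(np.float32) * 0.3
        mask = np.zeros((side, side), dtype=np.uint8)
        if i % 2 == 0:
            r, c = rng.integers(4, side - 12, size=2)
            mask[r : r + 8, c : c + 8] = 1
            img[mask > 0] += 0.5
        data.append((img, LabelMask(mask)))
    return data


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        t = np.zeros((64, 64))
        t[10:30, 10:30] = 1
        assert dice_loss(t.astype(float), LabelMask(t.astype(np.uint8))) <= 1e-3

    def test_disjoint_near_one(self):
        t = np.zeros((64, 64), dtype=np.uint8)
        t[:32] = 1
        assert dice_loss(1.0 - t.astype(float), LabelMask(t)) >= 0.999

    def test_uniform_half_probability_closed_form(self):
        side = 64
        n = side * side
        t = np.zeros((side, side), dtype=np.uint8)
        t[:32] = 1  # half foreground
        a = int(t.sum())
        probs = np.full((side, side), 0.5)
        expected = 1 - (2 * 0.5 * a + DICE_EPS) / (0.5 * n + a + DICE_EPS)
        assert dice_loss(probs, LabelMask(t)) == pytest.approx(expected)

    def test_equals_one_minus_dice_score_on_binary_inputs(self, rng):
        for _ in range(20):
            a = (rng.random((32, 32)) < 0.3).astype(np.uint8)
            b = (rng.random((32, 32)) < 0.3).astype(np.uint8)
            if not (a.any() or b.any()):
                continue
            loss = dice_loss(a.astype(float), LabelMask(b), eps=0.0)
            assert loss == pytest.approx(1 - dice_score(LabelMask(a), LabelMask(b)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), LabelMask(np.zeros((8, 8), np.uint8)))


class TestAugment:
    def test_forced_double_flip_is_identity(self, rng):
        img = rng.random((32, 32)).astype(np.float32)
        mask = LabelMask((rng.random((32, 32)) < 0.2).astype(np.uint8))
        policy = AugmentPolicy(
            p_apply=1.0, rotation_deg=0.0, zoom=(1.0, 1.0),
            translate_frac=0.0, shear_frac=(0.0, 0.0), flips=True,
        )
        i1, m1 = augment(img, mask, policy, seed=1)
        i2, m2 = augment(i1, m1, policy, seed=2)
        np.testing.assert_allclose(i2, img, atol=1e-6)
        np.testing.assert_array_equal(m2.pixels, mask.pixels)

    def test_rotation_draws_stay_in_range(self):
        policy = AugmentPolicy(p_apply=1.0)
        rng = np.random.default_rng(7)
        draws = [draw_augment_params(policy, rng)["rot_deg"] for _ in range(10_000)]
        assert min(draws) >= -45.0 and max(draws) <= 45.0
        assert min(draws) < -40 and max(draws) > 40  # range actually exercised

    def test_zoom_and_shear_draws_stay_in_range(self):
        policy = AugmentPolicy(p_apply=1.0)
        rng = np.random.default_rng(8)
        params = [draw_augment_params(policy, rng) for _ in range(5000)]
        assert all(0.8 <= p["zoom"] <= 1.2 for p in params)
        assert all(0.0 <= p["shear"] <= 0.1 for p in params)
        assert all(abs(t) <= 0.2 for p in params for t in p["translate"])

    def test_mask_label_set_preserved(self, rng):
        mask = LabelMask(
            rng.integers(0, 6, size=(64, 64)).astype(np.int16), encoding="subtype"
        )
        img = rng.random((64, 64)).astype(np.float32)
        policy = AugmentPolicy(p_apply=1.0)
        for seed in range(5):
            _, m2 = augment(img, mask, policy, seed=seed)
            assert set(np.unique(m2.pixels)) <= set(np.unique(mask.pixels))

    def test_deterministic_under_seed(self, rng):
        img = rng.random((32, 32)).astype(np.float32)
        mask = LabelMask((rng.random((32, 32)) < 0.2).astype(np.uint8))
        policy = AugmentPolicy()
        a = augment(img, mask, policy, seed=5)
        b = augment(img, mask, policy, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1].pixels, b[1].pixels)


class TestTraining:
    def test_one_epoch_smoke_returns_finite_loss(self):
        model = train_stage(_tiny_data(), SegTrainConfig(epochs=1, seed=0))
        assert len(model.loss_history) == 1
        assert np.isfinite(model.loss_history[0])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_stage([], SegTrainConfig(epochs=1))

    def test_loss_decreases_on_synthetic_preset(self):
        model = train_stage(
            _tiny_data(n=16), SegTrainConfig(epochs=12, seed=1, lr=3e-3)
        )
        assert model.loss_history[-1] < model.loss_history[0]

    def test_checkpoint_round_trip_bit_identical(self, tmp_path):
        data = _tiny_data()
        model = train_stage(data, SegTrainConfig(epochs=2, seed=3))
        p = model.save(tmp_path / "seg.ckpt")
        back = SegModel.load(p)
        x = data[0][0]
        np.testing.assert_array_equal(model.predict(x), back.predict(x))

    def test_prediction_deterministic_and_in_range(self):
        data = _tiny_data()
        model = train_stage(data, SegTrainConfig(epochs=1, seed=4))
        p1 = model.predict(data[0][0])
        p2 = model.predict(data[0][0])
        np.testing.assert_array_equal(p1, p2)
        assert p1.min() >= 0.0 and p1.max() <= 1.0

    def test_resolution_mismatch_rejected(self):
        model = train_stage(_tiny_data(side=32), SegTrainConfig(epochs=1, seed=0))
        with pytest.raises(ValueError):
            model.predict(np.zeros((64, 64), dtype=np.float32))

    def test_training_reproducible_under_seed(self):
        data = _tiny_data()
        cfg = SegTrainConfig(epochs=2, seed=9)
        m1 = train_stage(data, cfg)
        m2 = train_stage(data, cfg)
        np.testing.assert_array_equal(m1.predict(data[1][0]), m2.predict(data[1][0]))

    def test_non_tiny_backbones_are_placeholders(self):
        with pytest.raises(NotImplementedError):
            SegTrainConfig(encoder="resnet50")
        with pytest.raises(NotImplementedError):
            SegTrainConfig(architecture="deeplabv3plus")


class TestStage2Dataset:
    def test_empty_slices_are_skipped(self):
        data = _tiny_data(n=8)
        out = make_stage2_dataset([d[0] for d in data], [d[1] for d in data])
        assert len(out) == sum(1 for _, m in data if not m.is_empty())

    def test_crops_are_requested_resolution(self):
        data = _tiny_data(n=4)
        out = make_stage2_dataset(
            [d[0] for d in data], [d[1] for d in data], out_side=32
        )
        for img, msk in out:
            assert img.shape == (32, 32) and msk.shape == (32, 32)


class TestVote:
    def test_mean_rule_example(self):
        a = np.array([[0.9]])
        b = np.array([[0.2]])
        assert vote(a, b, 0.5).pixels[0, 0] == 1  # mean 0.55

    def test_identical_maps_reduce_to_single_thresholding(self, rng):
        p = rng.random((16, 16))
        out = vote(p, p, 0.5)
        np.testing.assert_array_equal(out.pixels, (p >= 0.5).astype(np.uint8))

    def test_union_of_disjoint_maps(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[0, 0] = 0.9
        b[3, 3] = 0.9
        out = vote(a, b, 0.5, strategy="union")
        assert out.pixels[0, 0] == 1 and out.pixels[3, 3] == 1
        assert out.pixels.sum() == 2

    def test_intersection_strategy(self):
        a = np.full((2, 2), 0.9)
        b = np.zeros((2, 2))
        assert vote(a, b, 0.5, strategy="intersection").pixels.sum() == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vote(np.zeros((2, 2)), np.zeros((3, 3)), 0.5)


class TestCascade:
    def test_stage1_negative_gates_stage2(self, monkeypatch):
        data = _tiny_data()
        s1 = train_stage(data, SegTrainConfig(epochs=1, seed=0))
        s2 = train_stage(data, SegTrainConfig(epochs=1, seed=1, stage="II"))

        class Boom:
            input_side = s2.input_side

            def predict(self, x):  # pragma: no cover
                raise AssertionError("Stage II must not run when Stage I is empty")

        # force stage 1 to predict nothing
        monkeypatch.setattr(s1, "predict", lambda x: np.zeros_like(np.asarray(x)))
        mask, roi = cascade_predict(s1, Boom(), data[0][0])
        assert mask.is_empty() and roi is None

    def test_cascade_deterministic(self):
        data = _tiny_data()
        s1 = train_stage(data, SegTrainConfig(epochs=2, seed=0, lr=3e-3))
        s2 = train_stage(data, SegTrainConfig(epochs=2, seed=1, lr=3e-3, stage="II"))
        m1, r1 = cascade_predict(s1, s2, data[0][0])
        m2, r2 = cascade_predict(s1, s2, data[0][0])
        np.testing.assert_array_equal(m1.pixels, m2.pixels)
        assert r1 == r2
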