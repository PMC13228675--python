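"""Autodiff gradients, model construction, augmentation and training."""

import numpy as np
import pytest

from stvseg import nn
from stvseg.nn import autodiff as ad
from stvseg.nn.autodiff import Tensor
from stvseg.nn.layers import BatchNorm2d, Conv2d, ConvBlock


def _numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def _scalar_l2(out: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error as a scalar graph node (for gradient checks)."""
    diff = ad.add(out, Tensor(-target))
    sq = Tensor((diff.data**2).mean(), parents=(diff,))
    sq._backward = lambda g: diff._accum(g * 2 * diff.data / diff.data.size)
    return sq


class TestGradients:
    """Every primitive's analytic gradient vs central finite differences."""

    @pytest.mark.parametrize("op,shape", [
        ("conv", (2, 3, 6, 6)),
        ("relu", (2, 4, 4, 4)),
        ("sigmoid", (2, 2, 4, 4)),
        ("maxpool", (2, 3, 6, 6)),
        ("upsample", (2, 3, 3, 3)),
        ("batchnorm", (3, 4, 5, 5)),
    ])
    def test_primitive_gradients(self, op, shape, rng):
        x = Tensor(rng.standard_normal(shape), requires_grad=True)
        extras: list[Tensor] = []
        if op == "conv":
            w = Tensor(rng.standard_normal((4, shape[1], 3, 3)) * 0.2,
                       requires_grad=True)
            b = Tensor(rng.standard_normal(4) * 0.2, requires_grad=True)
            extras = [w, b]
            fwd = lambda xs: ad.conv2d(xs[0], xs[1], xs[2])
        elif op == "relu":
            fwd = lambda xs: ad.relu(xs[0])
        elif op == "sigmoid":
            fwd = lambda xs: ad.sigmoid(xs[0])
        elif op == "maxpool":
            fwd = lambda xs: ad.maxpool2x2(xs[0])
        elif op == "upsample":
            fwd = lambda xs: ad.upsample2x(xs[0])
        else:  # batchnorm
            gmm = Tensor(rng.uniform(0.5, 1.5, shape[1]), requires_grad=True)
            bt = Tensor(rng.standard_normal(shape[1]) * 0.1, requires_grad=True)
            extras = [gmm, bt]
            rmean = np.zeros(shape[1])
            rvar = np.ones(shape[1])
            fwd = lambda xs: ad.batchnorm2d(
                xs[0], xs[1], xs[2], rmean.copy(), rvar.copy(), training=True)

        tensors = [x] + extras
        probe = fwd(tensors)
        target = rng.random(probe.shape)
        loss = _scalar_l2(fwd(tensors), target)
        loss.backward()

        def value():
            return float(((fwd([Tensor(t.data) for t in tensors]).data
                           - target) ** 2).mean())

        for t in tensors:
            num = _numeric_grad(value, t.data)
            scale = max(np.abs(num).max(), 1e-8)
            assert np.abs(num - t.grad).max() / scale < 1e-5

    @pytest.mark.parametrize("loss_fn", [ad.bce_with_logits_loss,
                                         ad.soft_dice_loss])
    def test_loss_gradients(self, loss_fn, rng):
        z = Tensor(rng.standard_normal((2, 1, 5, 5)), requires_grad=True)
        t = (rng.random((2, 1, 5, 5)) > 0.6).astype(float)
        loss_fn(z, t).backward()

        def value():
            return float(loss_fn(Tensor(z.data), t).data)

        num = _numeric_grad(value, z.data)
        assert np.abs(num - z.grad).max() / max(np.abs(num).max(), 1e-8) < 1e-5

    def test_concat_and_add_gradients(self, rng):
        a = Tensor(rng.standard_normal((1, 2, 4, 4)), requires_grad=True)
        b = Tensor(rng.standard_normal((1, 3, 4, 4)), requires_grad=True)
        cat = ad.concat_channels([a, b])
        target = rng.random(cat.shape)
        _scalar_l2(ad.concat_channels([a, b]), target).backward()
        na = _numeric_grad(
            lambda: float(((ad.concat_channels(
                [Tensor(a.data), Tensor(b.data)]).data - target) ** 2).mean()),
            a.data)
        assert np.abs(na - a.grad).max() < 1e-6


class TestModels:
    def test_forward_probability_range(self):
        cfg = nn.ModelConfig(architecture="unet", depth=2, base_filters=8,
                             input_size=(64, 64))
        model = nn.build_model(cfg)
        p = model.predict_proba(np.zeros((64, 64)))
        assert p.shape == (64, 64)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_unetpp_resnet18_builds(self):
        cfg = nn.ModelConfig(architecture="unetpp", encoder="resnet18",
                             depth=3, base_filters=4, input_size=(32, 32))
        model = nn.build_model(cfg)
        assert model.deep_supervision is False
        p = model.predict_proba(np.zeros((32, 32)))
        assert p.shape == (32, 32)
        assert "resnet18" in model.summary()

    def test_parameter_count_grows_with_base_filters(self):
        small = nn.build_model(nn.ModelConfig(depth=2, base_filters=8,
                                              input_size=(32, 32)))
        large = nn.build_model(nn.ModelConfig(depth=2, base_filters=16,
                                              input_size=(32, 32)))
        assert large.n_parameters() > small.n_parameters()

    def test_input_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            nn.ModelConfig(depth=4, input_size=(60, 60))

    def test_inference_deterministic(self, rng):
        model = nn.build_model(nn.ModelConfig(depth=2, base_filters=4,
                                              input_size=(32, 32)))
        img = rng.random((32, 32))
        np.testing.assert_array_equal(model.predict_proba(img),
                                      model.predict_proba(img))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = nn.build_model(nn.ModelConfig(depth=2, base_filters=4,
                                              input_size=(32, 32)))
        img = rng.random((32, 32))
        before = model.predict_proba(img)
        nn.save_checkpoint(model, str(tmp_path / "m.npz"))
        back = nn.load_checkpoint(str(tmp_path / "m.npz"))
        np.testing.assert_allclose(back.predict_proba(img), before, atol=1e-12)


class TestAugment:
    def test_disabled_is_identity(self, disc_mask, rng):
        img = rng.random(disc_mask.shape)
        out_img, out_msk = nn.augment(img, disc_mask,
                                      nn.AugmentationConfig.disabled(), rng)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_msk, disc_mask)

    def test_flip_twice_is_identity(self, disc_mask, rng):
        class AlwaysFlip:
            def random(self):
                return 0.0

        cfg = nn.AugmentationConfig(
            horizontal_flip=True, vertical_flip=False, max_rotation_deg=0,
            max_translation_frac=0, max_zoom_frac=0)
        img = rng.random(disc_mask.shape)
        once = nn.augment(img, disc_mask, cfg, AlwaysFlip())
        twice = nn.augment(once[0], once[1], cfg, AlwaysFlip())
        np.testing.assert_array_equal(twice[0], img)
        np.testing.assert_array_equal(twice[1], disc_mask)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_rotation_preserves_disc_area(self, disc_mask, seed):
        cfg = nn.AugmentationConfig(
            horizontal_flip=False, vertical_flip=False, max_rotation_deg=20,
            max_translation_frac=0, max_zoom_frac=0)
        _, msk = nn.augment(disc_mask.astype(float), disc_mask, cfg,
                            np.random.default_rng(seed))
        assert int(msk.sum()) == pytest.approx(int(disc_mask.sum()), rel=0.02)

    def test_mask_stays_binary_and_shapes_fixed(self, disc_mask, rng):
        cfg = nn.AugmentationConfig(seed=0)
        img = rng.random(disc_mask.shape)
        for _ in range(10):
            out_img, out_msk = nn.augment(img, disc_mask, cfg, rng)
            assert out_img.shape == img.shape
            assert set(np.unique(out_msk)) <= {0, 1}

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="differ"):
            nn.augment(np.zeros((8, 8)), np.zeros((9, 9)),
                       nn.AugmentationConfig(), rng)


class TestTraining:
    def test_single_batch_loss_decreases(self, crescent_pair):
        from stvseg.volume import reslice, reslice_label

        vol, lab = crescent_pair
        stack = reslice(vol, 10)
        lstack = reslice_label(lab, 10)
        img, msk = stack.images[5], lstack.images[5]
        model = nn.build_model(nn.ModelConfig(depth=2, base_filters=8,
                                              input_size=(64, 64), seed=0))

        def loss_on_pair():
            x = Tensor(img[None, None])
            logits = model.forward(x)
            return float(ad.add(
                ad.bce_with_logits_loss(logits, msk[None, None].astype(float)),
                ad.soft_dice_loss(logits, msk[None, None].astype(float))).data)

        model.set_training(False)
        before = loss_on_pair()
        tcfg = nn.TrainConfig(learning_rate=1e-3, epochs=3, steps_per_epoch=1,
                              batch_size=1, seed=0)
        model, _ = nn.train(model, [(img, msk)], [],
                            tcfg, nn.AugmentationConfig.disabled())
        after = loss_on_pair()
        assert after < before

    def test_steps_beyond_dataset_cycle(self, crescent_pair):
        from stvseg.volume import reslice, reslice_label

        vol, lab = crescent_pair
        pairs = list(zip(reslice(vol, 4).images, reslice_label(lab, 4).images))
        model = nn.build_model(nn.ModelConfig(depth=2, base_filters=2,
                                              input_size=(64, 64)))
        tcfg = nn.TrainConfig(learning_rate=1e-3, epochs=1, steps_per_epoch=3,
                              batch_size=3, seed=0)
        _, hist = nn.train(model, pairs, [], tcfg,
                           nn.AugmentationConfig.disabled())
        assert len(hist["train_loss"]) == 1

    def test_empty_training_set_rejected(self):
        model = nn.build_model(nn.ModelConfig(depth=2, base_filters=2,
                                              input_size=(32, 32)))
        with pytest.raises(ValueError, match="at least one"):
            nn.train(model, [], [], nn.TrainConfig(), nn.AugmentationConfig())


class TestPredict:
    @pytest.fixture(scope="class")
    def model(self):
        return nn.build_model(nn.ModelConfig(depth=2, base_filters=4,
                                             input_size=(64, 64), seed=3))

    def test_threshold_bounds(self, model, rng):
        img = rng.random((64, 64))
        assert nn.predict_slice(model, img, threshold=1.01).sum() == 0
        assert nn.predict_slice(model, img, threshold=0.0).all()

    def test_foreground_monotone_in_threshold(self, model, rng):
        img = rng.random((64, 64))
        counts = [nn.predict_slice(model, img, t).sum()
                  for t in (0.25, 0.5, 0.75)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_stack_prediction_matches_per_slice(self, model, crescent_pair):
        # order is preserved: element i of the stack output equals the
        # independent single-slice prediction of image i
        from stvseg.volume import reslice

        vol, _ = crescent_pair
        stack = reslice(vol, 6)
        masks = nn.predict_stack(model, stack)
        assert len(masks) == 6
        for img, m in zip(stack.images, masks):
            np.testing.assert_array_equal(m, nn.predict_slice(model, img))

    def test_constant_image_predicts_without_error(self, model):
        mask = nn.predict_slice(model, np.zeros((64, 64)))
        assert mask.shape == (64, 64)

    def test_odd_size_input_round_trips(self, model, rng):
        img = rng.random((50, 70))
        mask = nn.predict_slice(model, img)
        assert mask.shape == (50, 70)
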