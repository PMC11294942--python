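"""The compact encoder-decoder: gradients, architecture, Dice loss, training."""

import numpy as np
import pytest

from lungseg.nn import (NetworkSpec, TrainConfig, UNet, build_network,
                        count_layers, dice_loss, load_checkpoint,
                        predict_mask, save_checkpoint, split_dataset, train)
from lungseg.nn import autodiff as ad
from lungseg.nn.unet import _dice_loss_t


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestAutodiffGradients:
    """Every primitive's backward pass against central finite differences."""

    @pytest.mark.parametrize("op_name", ["conv2d", "conv_transpose", "maxpool",
                                         "relu", "sigmoid", "concat", "softmax2"])
    def test_gradients_match_finite_differences(self, op_name, rng):
        x = ad.Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        w = ad.Tensor(rng.normal(size=(2, 3, 3, 3)) * 0.5, requires_grad=True)
        b = ad.Tensor(rng.normal(size=2), requires_grad=True)
        wt = ad.Tensor(rng.normal(size=(3, 2, 2, 2)) * 0.5, requires_grad=True)
        x2 = ad.Tensor(rng.normal(size=(2, 2, 4, 4)), requires_grad=True)
        weights = rng.normal(size=(2, 3, 4, 4))  # fixed linear readout
        weights5 = rng.normal(size=(2, 5, 4, 4))

        def build():
            if op_name == "conv2d":
                return (ad.conv2d(x, w, b) * ad.Tensor(weights[:, :2])).sum()
            if op_name == "conv_transpose":
                return (ad.conv_transpose2x2(x, wt, ad.Tensor(np.zeros(2), requires_grad=True))
                        * ad.Tensor(np.ones((2, 2, 8, 8)))).sum()
            if op_name == "maxpool":
                return (ad.maxpool2x2(x) * ad.Tensor(weights[:, :, :2, :2])).sum()
            if op_name == "relu":
                return (ad.relu(x) * ad.Tensor(weights[:3])).sum()
            if op_name == "sigmoid":
                return (ad.sigmoid(x) * ad.Tensor(weights[:3])).sum()
            if op_name == "concat":
                return (ad.concat([x, x2]) * ad.Tensor(weights5)).sum()
            if op_name == "softmax2":
                return (ad.softmax2(x2) * ad.Tensor(weights[:, :1])).sum()
            raise AssertionError(op_name)

        out = build()
        out.backward()
        for t in (x, w, b, wt, x2):
            if t.grad is None:
                continue
            num = numeric_grad(lambda: build().item(), t.data)
            np.testing.assert_allclose(t.grad, num, atol=1e-5)

    def test_full_network_gradient(self, rng):
        # end-to-end: d(dice loss)/d(weights) of a tiny network
        spec = NetworkSpec(input_size=(8, 8), depth=1, base_filters=2,
                           dropout_rate=0.0)
        net = UNet(spec, seed=0)
        x = rng.random((2, 8, 8))
        t = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)

        def loss_value():
            return _dice_loss_t(net.forward(x), t).item()

        loss = _dice_loss_t(net.forward(x), t)
        loss.backward()
        for name in ("enc0_c1_w", "head_w", "up0_w"):
            p = net.params[name]
            num = numeric_grad(loss_value, p.data)
            np.testing.assert_allclose(p.grad, num, atol=1e-5)


class TestArchitecture:
    def test_output_matches_input_size(self):
        for size in ((32, 32), (16, 32)):
            spec = NetworkSpec(input_size=size, depth=3, base_filters=4)
            net = build_network(spec, seed=0)
            out = net.forward(np.zeros((2, *size)))
            assert out.data.shape == (2, 1, *size)
            assert np.all((out.data >= 0) & (out.data <= 1))

    def test_first_conv_has_base_filters(self):
        net = build_network(NetworkSpec(input_size=(32, 32), depth=3, base_filters=8))
        assert net.params["enc0_c1_w"].data.shape == (8, 1, 3, 3)

    def test_encoder_spatial_sizes_halve_per_level(self):
        # depth-5 at 128x128 walks 128 -> 64 -> 32 -> 16 -> 8 -> 4
        sizes = [128 // 2**i for i in range(6)]
        assert sizes == [128, 64, 32, 16, 8, 4]
        spec = NetworkSpec(input_size=(128, 128), depth=5, base_filters=1)
        net = build_network(spec)
        out = net.forward(np.zeros((1, 128, 128)))
        assert out.data.shape == (1, 1, 128, 128)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkSpec(input_size=(36, 36), depth=3)

    def test_layer_counts(self):
        spec = NetworkSpec(input_size=(128, 128), depth=5)
        counts = count_layers(spec)
        assert counts["encoder_conv"] == 10
        assert counts["pool"] == spec.depth
        assert counts["conv"] == 21  # regression: 10 enc + 10 dec + 1 head
        nested = count_layers(NetworkSpec(input_size=(32, 32), depth=3,
                                          skip_mode="nested"))
        assert nested["conv_transpose"] == 6  # 3+2+1 dense nodes

    def test_parameter_count_is_pure_function_of_spec(self):
        spec = NetworkSpec(input_size=(32, 32), depth=3, base_filters=8)
        assert build_network(spec, 0).parameter_count() == \
            build_network(spec, 99).parameter_count()
        # regression value enumerated from the constructed graph
        assert build_network(spec, 0).parameter_count() == 61161

    def test_nested_mode_forward_shape(self):
        spec = NetworkSpec(input_size=(16, 16), depth=2, base_filters=4,
                           skip_mode="nested")
        out = build_network(spec).forward(np.zeros((1, 16, 16)))
        assert out.data.shape == (1, 1, 16, 16)

    def test_softmax_head_outputs_probabilities(self):
        spec = NetworkSpec(input_size=(16, 16), depth=2, base_filters=4,
                           out_activation="softmax")
        out = build_network(spec).forward(np.zeros((1, 16, 16)))
        assert out.data.shape == (1, 1, 16, 16)
        assert np.all((out.data >= 0) & (out.data <= 1))


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        t = np.ones((8, 8))
        assert dice_loss(t, t) == pytest.approx(0.0, abs=0.01)

    def test_disjoint_masks_near_one(self):
        a = np.zeros((16, 16))
        a[:8] = 1
        b = 1 - a
        assert dice_loss(a, b, eps=1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_half_overlap(self):
        # intersection 1 against sizes 2+2 -> Dice 0.5, loss 0.5
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([1.0, 0.0, 1.0, 0.0])
        assert dice_loss(a, b, eps=1e-12) == pytest.approx(0.5)

    def test_matches_one_minus_dice_metric(self, rng):
        from lungseg.metrics import dice as dice_coef

        a = (rng.random((10, 10)) > 0.5).astype(float)
        b = (rng.random((10, 10)) > 0.5).astype(float)
        assert dice_loss(a, b, eps=1e-12) == pytest.approx(1 - dice_coef(a, b), abs=1e-9)

    def test_in_unit_interval(self, rng):
        a, b = rng.random((6, 6)), (rng.random((6, 6)) > 0.5).astype(float)
        assert 0.0 <= dice_loss(a, b) <= 1.0


class TestSplit:
    def test_70_15_15_sizes(self):
        tr, va, te = split_dataset(list(range(100)), TrainConfig(seed=1))
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_disjoint_exhaustive_deterministic(self):
        cfg = TrainConfig(seed=5)
        items = list(range(37))
        tr, va, te = split_dataset(items, cfg)
        assert sorted(tr + va + te) == list(range(37))
        assert split_dataset(items, cfg) == (tr, va, te)

    def test_tiny_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], TrainConfig())


@pytest.fixture(scope="module")
def tiny_data():
    from lungseg.preprocess import normalize01
    from lungseg.synthetic import PhantomSpec, make_dataset

    spec = PhantomSpec(size=(32, 32), n_nodules=(1, 2), nodule_radius=(2.5, 5.0))
    samples = make_dataset(spec, 8, seed=0)
    return [(normalize01(s.image).pixels, s.nodule_mask.astype(float))
            for s in samples]


class TestTraining:
    def test_learning_reduces_loss(self, tiny_data):
        net = UNet(NetworkSpec(input_size=(32, 32), depth=3, base_filters=8), seed=0)
        images = np.stack([im for im, _ in tiny_data])
        masks = np.stack([mk for _, mk in tiny_data])
        before = dice_loss(net.predict_proba(images), masks)
        report = train(net, tiny_data, TrainConfig(epochs=5, batch_size=8, seed=0))
        assert report.epochs[-1]["train_loss"] < before

    def test_seeded_epoch1_reproducibility(self, tiny_data):
        losses = []
        for _ in range(2):
            net = UNet(NetworkSpec(input_size=(32, 32), depth=3, base_filters=8), seed=3)
            rep = train(net, tiny_data, TrainConfig(epochs=1, batch_size=8, seed=3))
            losses.append(rep.epochs[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_predict_mask_threshold_extremes(self, tiny_data):
        net = UNet(NetworkSpec(input_size=(32, 32), depth=3, base_filters=4), seed=0)
        img = tiny_data[0][0]
        mask0, prob = predict_mask(net, img, threshold=0.0)
        assert mask0.all()
        mask1, _ = predict_mask(net, img, threshold=1.0 + 1e-9)
        assert not mask1.any()
        maskt, prob = predict_mask(net, img, threshold=0.5)
        np.testing.assert_array_equal(maskt, prob >= 0.5)

    def test_checkpoint_round_trip(self, tiny_data, tmp_path):
        net = UNet(NetworkSpec(input_size=(32, 32), depth=3, base_filters=4), seed=0)
        train(net, tiny_data, TrainConfig(epochs=1, batch_size=8, seed=0))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        restored = load_checkpoint(path)
        np.testing.assert_array_equal(
            restored.predict_proba(tiny_data[0][0][None]),
            net.predict_proba(tiny_data[0][0][None]))

    def test_missing_checkpoint_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_checkpoint(tmp_path / "nope.npz")

    def test_empty_dataset_rejected(self):
        net = UNet(NetworkSpec(input_size=(32, 32), depth=3, base_filters=2))
        with pytest.raises(ValueError):
            train(net, [], TrainConfig(epochs=1))
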