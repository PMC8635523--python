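import numpy as np
import pytest

from anaspec.cnn import (ARCHITECTURES, CNNConfig, LayerSpec, _build_network,
                         build_architecture, load_model, output_shape,
                         predict, save_model, train)
from anaspec.dataset import DatasetSplit, LabeledImageSet
from anaspec.spectral import SpectrogramImage


def _toy_split(n_per_class=4, n_test=1, size=32):
    """Linearly separable two-class image problem: bright band top vs bottom."""
    vocab = ("wheeze", "rhonchi")
    train_items, test_items = [], []
    rng = np.random.default_rng(0)
    for label_idx, label in enumerate(vocab):
        for k in range(n_per_class + n_test):
            base = rng.uniform(0, 0.1, (size, size, 3))
            rows = slice(2, 10) if label_idx == 0 else slice(size - 10, size - 2)
            base[rows] += 0.9
            item = (SpectrogramImage(np.clip(base, 0, 1)), label, f"{label}{k}")
            (train_items if k < n_per_class else test_items).append(item)
    return DatasetSplit(LabeledImageSet(train_items, vocab),
                        LabeledImageSet(test_items, vocab))


class TestRegistry:
    def test_alexnet_first_layer_is_96_filters_11x11_stride4(self):
        layers = build_architecture("alexnet_paper")
        assert layers[0] == LayerSpec("conv", filters=96, kernel=(11, 11),
                                      stride=(4, 4), padding="valid")

    def test_alexnet_has_5_conv_and_3_dense(self):
        layers = build_architecture("alexnet_paper")
        assert sum(l.kind == "conv" for l in layers) == 5
        assert sum(l.kind == "dense" for l in layers) == 3
        assert layers[-1].activation == "softmax"

    def test_unknown_architecture_lists_registry(self):
        with pytest.raises(ValueError, match="alexnet_paper"):
            build_architecture("resnet50_full")

    @pytest.mark.parametrize("name", ARCHITECTURES)
    def test_all_registered_architectures_build(self, name):
        layers = build_architecture(name)
        assert layers[-1].units == 7


class TestOutputShape:
    def test_alexnet_shape_chain_on_227(self):
        layers = build_architecture("alexnet_paper")
        shapes = output_shape(layers, (227, 227, 3))
        assert shapes[0] == (55, 55, 96)  # CL1
        assert shapes[1] == (27, 27, 96)  # MP1
        assert shapes[2] == (9, 9, 256)  # CL2
        assert shapes[3] == (4, 4, 256)  # MP2
        assert shapes[7] == (2, 2, 256)  # MP3
        flatten_idx = next(i for i, l in enumerate(layers) if l.kind == "flatten")
        assert shapes[flatten_idx] == (1024,)

    def test_alexnet_not_constructible_below_143(self):
        layers = build_architecture("alexnet_paper")
        with pytest.raises(ValueError):
            output_shape(layers, (96, 96, 3))
        assert output_shape(layers, (143, 143, 3))[-1] == (7,)

    def test_shape_audit_matches_backend_tensors(self):
        # the analytic rules must agree with the real forward pass
        for name, size in (("alexnet_paper", 160), ("lenet5", 96),
                           ("vgg_small", 96)):
            layers = build_architecture(name)
            predicted = output_shape(layers, (size, size, 3))
            net = _build_network(layers, (size, size, 3),
                                 np.random.default_rng(0))
            actual = net.forward_shapes(
                np.zeros((1, size, size, 3), dtype=np.float32))
            assert [tuple(s) for s in predicted] == [tuple(s) for s in actual]


class TestTraining:
    def test_overfits_linearly_separable_toy_set(self):
        split = _toy_split()
        config = CNNConfig(architecture="lenet5", input_size=(32, 32, 3),
                           n_classes=2, epochs=200, optimizer="adam",
                           dropout=0.0, seed=0, early_stop_loss=None,
                           early_stop_patience=10)
        layers = build_architecture("lenet5", config)
        model, history = train(layers, split, config)
        assert history.train_accuracy[-1] == 1.0
        # every training image predicted with its own label
        for image, label, _ in split.train.items:
            token, probs = predict(model, image)
            assert token == label
            assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_history_lengths_equal_epochs_without_early_stop(self):
        split = _toy_split(n_per_class=2)
        config = CNNConfig(architecture="lenet5", input_size=(32, 32, 3),
                           n_classes=2, epochs=5, dropout=0.0, seed=0)
        _, history = train(build_architecture("lenet5", config), split, config)
        assert len(history.train_accuracy) == len(history.val_loss) == 5

    def test_seeded_training_reproducible(self):
        split = _toy_split(n_per_class=2)
        config = CNNConfig(architecture="lenet5", input_size=(32, 32, 3),
                           n_classes=2, epochs=3, seed=11)
        _, h1 = train(build_architecture("lenet5", config), split, config)
        _, h2 = train(build_architecture("lenet5", config), split, config)
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy

    def test_learning_improves_over_epochs(self):
        split = _toy_split()
        config = CNNConfig(architecture="lenet5", input_size=(32, 32, 3),
                           n_classes=2, epochs=40, optimizer="adam",
                           dropout=0.0, seed=1)
        _, history = train(build_architecture("lenet5", config), split, config)
        k = max(1, len(history) // 10)
        assert np.median(history.train_accuracy[-k:]) >= \
            np.median(history.train_accuracy[:k])

    def test_missing_class_in_train_rejected(self):
        split = _toy_split(n_per_class=2)
        truncated = DatasetSplit(
            LabeledImageSet([it for it in split.train.items
                             if it[1] == "wheeze"],
                            split.train.class_vocabulary),
            split.test)
        config = CNNConfig(architecture="lenet5", input_size=(32, 32, 3),
                           n_classes=2, epochs=1)
        with pytest.raises(ValueError, match="rhonchi"):
            train(build_architecture("lenet5", config), truncated, config)

    def test_predict_deterministic(self):
        split = _toy_split(n_per_class=2)
        config = CNNConfig(architecture="lenet5", input_size=(32, 32, 3),
                           n_classes=2, epochs=2, seed=0)
        model, _ = train(build_architecture("lenet5", config), split, config)
        image = split.test.items[0][0]
        _, p1 = predict(model, image)
        _, p2 = predict(model, image)
        assert np.array_equal(p1, p2)


class TestSerialization:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        split = _toy_split(n_per_class=2)
        config = CNNConfig(architecture="lenet5", input_size=(32, 32, 3),
                           n_classes=2, epochs=3, seed=0, dropout=0.5)
        model, _ = train(build_architecture("lenet5", config), split, config)
        path = save_model(model, tmp_path / "model")
        loaded = load_model(path)
        image = split.test.items[0][0]
        t1, p1 = predict(model, image)
        t2, p2 = predict(loaded, image)
        assert t1 == t2
        assert np.allclose(p1, p2, atol=1e-6)

    def test_missing_sidecar_raises(self, tmp_path):
        np.savez(tmp_path / "m.npz", p0=np.zeros(3))
        with pytest.raises(IOError):
            load_model(tmp_path / "m.npz")
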