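import numpy as np
import pytest

from pfv3d.classifier import (ArchitectureSpec, ClassifierConfig, TrainedModel,
                              build_model, load_model, predict, predict_batch,
                              save_model, train)


def separable_pfv_dataset(n_per_class=20, seed=0):
    """Two classes separable by one coordinate: mass on the all-present
    pattern (id 255) vs mass on the all-absent pattern (id 0)."""
    rng = np.random.default_rng(seed)
    data = []
    for label, idx in (("A", 255), ("B", 0)):
        for _ in range(n_per_class):
            f = rng.random(256) * 0.01
            f[idx] += 1.0
            data.append((f, label))
    return data


class TestBuildModel:
    def test_alexnet3d_layer_census(self):
        spec = build_model(ClassifierConfig(head="alexnet3d", n_classes=3))
        assert spec.n_conv_layers == 5
        assert spec.n_dense_layers == 3
        assert spec.pool_windows == [2, 2, 2]
        assert spec.layers[-1].kind == "softmax"
        assert spec.output_width == 3

    def test_alexnet3d_pooling_follows_conv_1_2_5(self):
        spec = build_model(ClassifierConfig(head="alexnet3d", n_classes=2))
        conv_seen = 0
        pools_after = []
        for layer in spec.layers:
            if layer.kind == "conv3d":
                conv_seen += 1
            elif layer.kind == "maxpool3d":
                pools_after.append(conv_seen)
        assert pools_after == [1, 2, 5]

    def test_pfv_mlp_widths(self):
        spec = build_model(ClassifierConfig(head="pfv_mlp", n_classes=2))
        assert spec.input_width == 256
        assert spec.output_width == 2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="n_classes"):
            ClassifierConfig(n_classes=1)

    @pytest.mark.parametrize("field,value", [
        ("learning_rate", 0.0), ("dropout", 1.0), ("validation_split", 0.0),
        ("epochs", 0), ("head", "resnet"),
    ])
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            ClassifierConfig(**{field: value})


class TestTrainMlp:
    def test_separable_toy_set_reaches_full_training_accuracy(self):
        cfg = ClassifierConfig(n_classes=2, seed=3, epochs=65)
        model = train(build_model(cfg), separable_pfv_dataset(), cfg)
        assert model.training_log[-1]["train_accuracy"] == 1.0

    def test_held_out_sample_classified_correctly(self):
        cfg = ClassifierConfig(n_classes=2, seed=3)
        model = train(build_model(cfg), separable_pfv_dataset(), cfg)
        # a fresh draw from the class-A distribution, unseen during training
        held_rng = np.random.default_rng(123)
        held_out = held_rng.random(256) * 0.01
        held_out[255] += 1.0
        probs = predict(model, held_out)
        assert model.class_labels[int(probs.argmax())] == "A"

    def test_single_sample_dataset_runs(self):
        cfg = ClassifierConfig(n_classes=2, seed=1, epochs=2)
        f = np.zeros(256)
        model = train(build_model(cfg), [(f, "A")], cfg)
        assert len(model.training_log) >= 1

    def test_same_seed_gives_identical_weights_and_log(self):
        cfg = ClassifierConfig(n_classes=2, seed=9, epochs=10)
        data = separable_pfv_dataset(seed=5)
        a = train(build_model(cfg), data, cfg)
        b = train(build_model(cfg), data, cfg)
        assert a.training_log == b.training_log
        for pa, pb in zip(a.parameters, b.parameters):
            np.testing.assert_array_equal(pa, pb)

    def test_feature_shape_mismatch_named_in_error(self):
        cfg = ClassifierConfig(n_classes=2)
        with pytest.raises(ValueError, match="256"):
            train(build_model(cfg), [(np.zeros(100), "A"), (np.zeros(100), "B")], cfg)

    def test_early_stopping_flags_the_log(self):
        # perfectly constant data: loss/accuracy freeze almost immediately
        cfg = ClassifierConfig(n_classes=2, seed=0, epochs=65,
                               learning_rate=1e-10, dropout=0.0)
        data = separable_pfv_dataset(n_per_class=10)
        model = train(build_model(cfg), data, cfg)
        assert len(model.training_log) < 65
        assert model.training_log[-1].get("early_stopped")


class TestPredict:
    def test_probabilities_sum_to_one(self, rng):
        cfg = ClassifierConfig(n_classes=2, seed=0, epochs=3)
        model = train(build_model(cfg), separable_pfv_dataset(5), cfg)
        probs = predict_batch(model, [rng.random(256) for _ in range(4)])
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_final_layer_gives_uniform_probabilities(self):
        cfg = ClassifierConfig(n_classes=4, seed=0, epochs=1)
        data = [(np.zeros(256), lab) for lab in "ABCD"]
        model = train(build_model(cfg), data, cfg)
        model.parameters[-2][...] = 0  # final dense weights
        model.parameters[-1][...] = 0  # final dense bias
        probs = predict(model, np.ones(256))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        cfg = ClassifierConfig(n_classes=2, seed=0, epochs=1)
        model = train(build_model(cfg), separable_pfv_dataset(3), cfg)
        with pytest.raises(ValueError, match="shape mismatch"):
            predict(model, np.zeros(10))


class TestAlexnet3d:
    def test_trains_and_predicts_on_tiny_volumes(self):
        cfg = ClassifierConfig(head="alexnet3d", n_classes=2, seed=0,
                               epochs=3, input_shape=(8, 8, 8), batch_size=8)
        rng = np.random.default_rng(0)
        data = []
        for label, level in (("dark", 40), ("bright", 220)):
            for _ in range(6):
                vol = np.clip(rng.normal(level, 10, size=(8, 8, 8)), 0, 255)
                data.append((vol, label))
        model = train(build_model(cfg), data, cfg)
        probs = predict(model, np.full((8, 8, 8), 220.0))
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-6)
        assert len(model.training_log) >= 1

    def test_indivisible_input_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ClassifierConfig(head="alexnet3d", input_shape=(10, 10, 10))


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tmp_path):
        cfg = ClassifierConfig(n_classes=2, seed=4, epochs=5)
        model = train(build_model(cfg), separable_pfv_dataset(10), cfg)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        x = np.linspace(0, 1, 256)
        np.testing.assert_allclose(predict(model, x), predict(loaded, x))
        assert loaded.class_labels == model.class_labels
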