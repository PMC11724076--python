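"""Network correctness (gradients, softmax contract) and training behavior."""

import numpy as np
import pytest

from mrepinsight import (TrainConfig, build_stacks, compute_pixel_map,
                         fit_norm2, predict_probabilities, train)
from mrepinsight.classifier import _pool_stacks
from mrepinsight.mapping import RepresentationSpec
from mrepinsight.network import SmallCNN, softmax


def _fit_blobs_model(blobs_ds, blobs_split, epochs=12, specs=None, seed=0):
    specs = specs or [RepresentationSpec(technique="pca")]
    norm = fit_norm2(blobs_ds.subset(blobs_split.train))
    train_ds = norm.transform(blobs_ds.subset(blobs_split.train))
    val_ds = norm.transform(blobs_ds.subset(blobs_split.validation))
    maps = [compute_pixel_map(train_ds, s, p=12, q=12) for s in specs]
    tr_stacks = build_stacks(train_ds, maps)
    va_stacks = build_stacks(val_ds, maps)
    cfg = TrainConfig(epochs=epochs, learning_rate=0.05, batch_size=16, seed=seed)
    model = train(tr_stacks, train_ds.labels, cfg, va_stacks, val_ds.labels)
    model.normalizer = norm
    return model, tr_stacks, va_stacks, val_ds


class TestNetworkNumerics:
    def test_finite_difference_gradients(self):
        """Backprop gradients match central differences on a tiny network."""
        rng = np.random.default_rng(0)
        net = SmallCNN((6, 6), 3, channels=(2,), hidden=4, seed=1)
        x = rng.uniform(size=(3, 1, 6, 6))
        y = np.array([0, 2, 1])
        net.loss_and_grads(x, y)
        eps = 1e-6
        for lay in net._param_layers():
            for name in ("W", "b"):
                arr = getattr(lay, name)
                analytic = getattr(lay, "d" + name)
                flat_idx = rng.integers(0, arr.size, size=5)
                for k in flat_idx:
                    orig = arr.flat[k]
                    arr.flat[k] = orig + eps
                    lp = _loss_only(net, x, y)
                    arr.flat[k] = orig - eps
                    lm = _loss_only(net, x, y)
                    arr.flat[k] = orig
                    numeric = (lp - lm) / (2 * eps)
                    assert analytic.flat[k] == pytest.approx(numeric, abs=1e-5)

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        probs = softmax(rng.normal(scale=20, size=(40, 5)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert probs.min() >= 0


def _loss_only(net, x, y):
    logits = net.forward(x)
    probs = softmax(logits)
    return -np.log(probs[np.arange(len(y)), y]).mean()


class TestTraining:
    def test_separable_blobs_reach_perfect_validation(self, blobs_ds, blobs_split):
        model, _, _, val_ds = _fit_blobs_model(blobs_ds, blobs_split)
        best_val = max(h["val_accuracy"] for h in model.history)
        assert best_val == 1.0

    def test_small_cnn_can_overfit_training_set(self, blobs_ds, blobs_split):
        model, tr_stacks, _, _ = _fit_blobs_model(blobs_ds, blobs_split)
        images, labels = _pool_stacks(tr_stacks,
                                      blobs_ds.subset(blobs_split.train).labels)
        probs = model.network.predict_proba(images)
        predicted = model.classes[probs.argmax(axis=1)]
        assert (predicted == labels).mean() == 1.0

    def test_checkpoint_best_validation_loss(self, blobs_ds, blobs_split):
        model, _, va_stacks, val_ds = _fit_blobs_model(blobs_ds, blobs_split)
        images, vlabels = _pool_stacks(va_stacks, val_ds.labels)
        idx = np.searchsorted(model.classes, vlabels)
        probs = model.network.predict_proba(images)
        restored = -np.log(np.clip(probs[np.arange(len(idx)), idx], 1e-12, None)).mean()
        assert restored <= model.history[-1]["val_loss"] + 1e-9
        assert restored == pytest.approx(min(h["val_loss"] for h in model.history))

    def test_pooled_image_count_is_n_times_m(self, blobs_ds, blobs_split):
        specs = [RepresentationSpec(technique="pca"),
                 RepresentationSpec(technique="kpca"),
                 RepresentationSpec(technique="pca", seed=1)]
        norm = fit_norm2(blobs_ds.subset(blobs_split.train))
        sub = norm.transform(blobs_ds.subset(blobs_split.train)).subset(np.arange(10))
        maps = [compute_pixel_map(sub, s, p=8, q=8) for s in specs]
        stacks = build_stacks(sub, maps)
        images, labels = _pool_stacks(stacks, sub.labels)
        assert images.shape[0] == 30 and len(labels) == 30

    def test_missing_validation_warns_and_trains(self, blobs_ds, blobs_split):
        norm = fit_norm2(blobs_ds.subset(blobs_split.train))
        train_ds = norm.transform(blobs_ds.subset(blobs_split.train))
        maps = [compute_pixel_map(train_ds, RepresentationSpec(technique="pca"),
                                  p=8, q=8)]
        stacks = build_stacks(train_ds, maps)
        with pytest.warns(UserWarning, match="validation"):
            model = train(stacks, train_ds.labels, TrainConfig(epochs=1, seed=0))
        assert model.history[0]["train_loss"] > 0

    def test_unknown_validation_class_rejected(self, blobs_ds, blobs_split):
        norm = fit_norm2(blobs_ds.subset(blobs_split.train))
        train_ds = norm.transform(blobs_ds.subset(blobs_split.train))
        maps = [compute_pixel_map(train_ds, RepresentationSpec(technique="pca"),
                                  p=8, q=8)]
        stacks = build_stacks(train_ds, maps)
        bad_labels = train_ds.labels.copy()[:4]
        bad_labels[:] = 99
        with pytest.raises(ValueError, match="absent"):
            train(stacks, train_ds.labels, TrainConfig(epochs=1),
                  build_stacks(train_ds.subset(np.arange(4)), maps), bad_labels)

    def test_large_backbones_need_framework(self, blobs_ds, blobs_split):
        with pytest.raises(RuntimeError, match="framework"):
            train([], np.array([]), TrainConfig(backbone="resnet50", pretrained=True))

    def test_training_is_deterministic(self, blobs_ds, blobs_split):
        m1, *_ = _fit_blobs_model(blobs_ds, blobs_split, epochs=2, seed=5)
        m2, *_ = _fit_blobs_model(blobs_ds, blobs_split, epochs=2, seed=5)
        for s1, s2 in zip(m1.network.get_state(), m2.network.get_state()):
            np.testing.assert_array_equal(s1["W"], s2["W"])


@pytest.fixture(scope="module")
def model(blobs_ds, blobs_split):
    return _fit_blobs_model(blobs_ds, blobs_split, epochs=3)[0]


class TestPredictProbabilities:

    def test_sums_to_one(self, model):
        rng = np.random.default_rng(2)
        rho = predict_probabilities(model, rng.uniform(size=model.grid_shape))
        assert rho.shape == (3,)
        assert rho.sum() == pytest.approx(1.0, abs=1e-6)
        assert rho.min() >= 0

    def test_binary_complement(self, blobs_ds):
        # two-class model: second probability is 1 - first
        from mrepinsight import GeneratorConfig, generate_blobs, split_dataset
        ds = generate_blobs(GeneratorConfig(n_samples=40, n_features=6, seed=1,
                                            family="gaussian_blobs"))
        split = split_dataset(ds, fractions=(0.6, 0.2, 0.2), seed=0)
        model, *_ = _fit_blobs_model(ds, split, epochs=2)
        rho = predict_probabilities(model, np.random.default_rng(3).uniform(size=(12, 12)))
        assert rho[1] == pytest.approx(1.0 - rho[0], abs=1e-9)

    def test_inference_deterministic(self, model):
        img = np.random.default_rng(4).uniform(size=model.grid_shape)
        np.testing.assert_array_equal(predict_probabilities(model, img),
                                      predict_probabilities(model, img))

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="shape"):
            predict_probabilities(model, np.zeros((5, 5)))


def test_invalid_train_config():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-1.0)
    with pytest.raises(ValueError):
        TrainConfig(backbone="vgg")
    with pytest.raises(ValueError):
        TrainConfig(pretrained=True)  # small_cnn has no pretrained weights
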