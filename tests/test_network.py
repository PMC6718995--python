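"""Network materialization, the SGD protocol, prediction and checkpoints."""

import numpy as np
import pytest

from dualpathcnn import archspec
from dualpathcnn.archspec import (
    ArchitectureSpec,
    ConvKernelSpec,
    ModuleSpec,
    ShapeTriple,
    SpecStructureError,
)
from dualpathcnn.estimator import DualPathCNNClassifier
from dualpathcnn.network import (
    DivergenceError,
    TrainingConfig,
    build_network,
    evaluate,
    load_checkpoint,
    predict,
    prepare_images,
    save_checkpoint,
    train,
)
from dualpathcnn.nn.layers import softmax, softmax_cross_entropy


def two_class_images(n_per_class=16, size=16, seed=0):
    """Trivially separable fixture: bright left half vs bright right half."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            img = rng.integers(0, 40, size=(size, size, 3), dtype=np.uint8)
            half = slice(None, size // 2) if label == 0 else slice(size // 2, None)
            img[:, half, :] = rng.integers(180, 255, size=(size, size // 2, 3))
            images.append(img)
            labels.append(label)
    return np.stack(images), np.array(labels)


class TestBuildNetwork:
    def test_softmax_rows_sum_to_one(self, specs):
        net = build_network(specs["reductive"], n_classes=5,
                            width_multiplier=0.125, seed=0)
        x = np.random.default_rng(0).random((2, 224, 224, 3), dtype=np.float32)
        probs = net.predict_proba(x)
        assert probs.shape == (2, 5)
        assert probs.min() >= 0
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_original_feature_vector_length(self, specs):
        net = build_network(specs["original"], n_classes=5, seed=0)
        x = np.zeros((1, 64, 64, 3), dtype=np.float32)
        assert net.features(x).shape == (1, 336)

    def test_all_zero_input_gives_finite_outputs(self, tiny_spec):
        net = build_network(tiny_spec, seed=0)
        logits = net.forward(np.zeros((3, 16, 16, 3), dtype=np.float32), train=True)
        assert np.isfinite(logits).all()

    def test_failing_audit_blocks_construction(self, specs):
        spec = specs["reductive"]
        modules = list(spec.modules)
        bad = (ConvKernelSpec(1, 1, 33, 1, 0, 96), ConvKernelSpec(3, 3, 32, 1, 1, 96))
        modules[1] = ModuleSpec("normal_dual", bad,
                                declared_output=modules[1].declared_output)
        broken = ArchitectureSpec("broken", spec.input_shape, tuple(modules))
        with pytest.raises(SpecStructureError):
            build_network(broken)

    def test_runtime_shapes_match_inference(self, specs):
        spec = specs["original"]
        net = build_network(spec, n_classes=5, width_multiplier=1.0, seed=0)
        x = np.random.default_rng(1).random((1, 64, 64, 3), dtype=np.float32)
        net.forward(x, train=False, record_shapes=True)
        assert net.last_shapes == archspec.infer_shapes(spec)


class TestTrain:
    def test_two_class_separable_reaches_perfect_validation(self, tiny_spec):
        images, labels = two_class_images(n_per_class=32)
        net = build_network(tiny_spec, n_classes=2, seed=0)
        cfg = TrainingConfig(epochs=5, batch_size=8, seed=0)
        model = train(net, (images[::2], labels[::2]), (images[1::2], labels[1::2]), cfg)
        assert model.history[-1][2] == 1.0

    def test_zero_epochs_returns_untrained_with_empty_history(self, tiny_spec):
        images, labels = two_class_images(n_per_class=2)
        net = build_network(tiny_spec, n_classes=2, seed=0)
        model = train(net, (images, labels), cfg=TrainingConfig(epochs=0))
        assert model.history == []

    def test_empty_training_set_rejected(self, tiny_spec):
        net = build_network(tiny_spec, n_classes=2, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(net, (np.zeros((0, 16, 16, 3)), np.zeros(0)), cfg=TrainingConfig())

    def test_loss_nonincreasing_on_fixed_tiny_batch(self, tiny_spec):
        images, labels = two_class_images(n_per_class=4)
        x = prepare_images(images, tiny_spec)
        net = build_network(tiny_spec, n_classes=2, seed=1)
        from dualpathcnn.nn import SGDOptimizer

        opt = SGDOptimizer(net, momentum=0.0, weight_decay=0.0)
        losses = []
        for _ in range(5):
            logits = net.forward(x, train=True)
            loss, dlogits = softmax_cross_entropy(logits, labels)
            losses.append(loss)
            net.backward(dlogits)
            opt.step(1e-3)
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_identical_seeds_give_identical_histories(self, tiny_spec):
        images, labels = two_class_images(n_per_class=8)
        order = np.random.default_rng(0).permutation(len(images))
        tr, va = order[:12], order[12:]

        def run():
            net = build_network(tiny_spec, n_classes=2, seed=5)
            cfg = TrainingConfig(epochs=2, batch_size=6, seed=5)
            return train(net, (images[tr], labels[tr]),
                         (images[va], labels[va]), cfg).history

        assert run() == run()

    def test_divergence_aborts_with_diagnostic(self, tiny_spec):
        images, labels = two_class_images(n_per_class=4)
        net = build_network(tiny_spec, n_classes=2, seed=0)
        cfg = TrainingConfig(learning_rate=1e4, epochs=20, batch_size=8, seed=0)
        with pytest.raises((DivergenceError, FloatingPointError)):
            with np.errstate(over="raise", invalid="raise"):
                train(net, (images, labels), cfg=cfg)

    def test_lr_decay_schedule_defaults(self):
        cfg = TrainingConfig(epochs=30)
        assert cfg.decay_epochs() == (15, 23)
        cfg = TrainingConfig(epochs=30, lr_decay_epochs=(10, 20))
        assert cfg.decay_epochs() == (10, 20)


class TestPredict:
    def test_probability_rows_and_order(self, trained_tiny):
        model, images, labels = trained_tiny
        pred, probs = predict(model, images[:7])
        assert pred.shape == (7,)
        assert probs.shape == (7, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        # order-preserving: predicting one-by-one matches the batch
        singles = [predict(model, images[i:i + 1])[0][0] for i in range(7)]
        assert list(pred) == singles

    def test_uniform_logits_tie_break_to_lowest_class(self):
        probs = softmax(np.zeros((1, 5)))
        assert probs.argmax(axis=1)[0] == 0

    def test_shape_mismatch_rejected(self, trained_tiny):
        model, _, _ = trained_tiny
        with pytest.raises(ValueError, match="shape"):
            predict(model, np.zeros((2, 17, 16, 3), dtype=np.uint8))


def test_checkpoint_round_trip(tmp_path, trained_tiny):
    model, images, labels = trained_tiny
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    again = load_checkpoint(path)
    assert again.history == model.history
    assert again.spec == model.spec
    p0, _ = predict(model, images[:5])
    p1, _ = predict(again, images[:5])
    assert (p0 == p1).all()
    a = model.network.predict_proba(prepare_images(images[:5], model.spec))
    b = again.network.predict_proba(prepare_images(images[:5], model.spec))
    assert np.allclose(a, b)


class TestEstimator:
    def test_fit_predict_on_separable_data(self, tiny_spec):
        images, labels = two_class_images(n_per_class=32)
        clf = DualPathCNNClassifier(arch=tiny_spec, epochs=5, batch_size=8,
                                    random_state=0)
        clf.fit(images[::2], labels[::2], X_val=images[1::2], y_val=labels[1::2])
        assert clf.history_[-1][2] == 1.0
        assert set(clf.predict(images)) <= {0, 1}
        assert clf.score(images[1::2], labels[1::2]) == 1.0

    def test_class_relabeling(self, tiny_spec):
        images, labels = two_class_images(n_per_class=6)
        shifted = np.where(labels == 0, 3, 9)  # arbitrary non-contiguous labels
        clf = DualPathCNNClassifier(arch=tiny_spec, epochs=3, batch_size=8,
                                    random_state=0)
        clf.fit(images, shifted)
        assert set(clf.classes_) == {3, 9}
        assert set(clf.predict(images[:4])) <= {3, 9}

    def test_get_set_params(self):
        clf = DualPathCNNClassifier(epochs=7)
        assert clf.get_params()["epochs"] == 7
        clf.set_params(width_multiplier=0.5)
        assert clf.width_multiplier == 0.5
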