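"""The window classifier: architecture contract, gradients, training."""

import numpy as np
import pytest

from epievents.errors import FormatError, InvalidInputError, SpecError
from epievents.io import RunConfig
from epievents.nn.layers import softmax_cross_entropy
from epievents.nn.model import (
    NetworkSpec,
    build_network,
    load_network,
    normalize_windows,
    predict_window,
    save_network,
    train_network,
)
from epievents.scaling import CLASS_ORDER, EventClass
from epievents.windows import WindowSequence, split_train_validation


class TestArchitectureContract:
    def test_dimension_chain_for_default_window(self):
        spec = NetworkSpec()
        assert spec.spatial_sides() == (45, 22, 11, 5)

    def test_filter_doubling(self):
        spec = NetworkSpec()
        assert spec.filters == (8, 16, 32, 64)
        assert spec.feature_dim == 64

    def test_feature_vector_length_is_64(self):
        net = build_network(NetworkSpec(), seed=0)
        x = normalize_windows(np.random.default_rng(0).random((2, 10, 45, 45)))
        b, t = 2, 10
        z = x.reshape(b * t, 45, 45, 1)
        for conv, bn, relu, pool in net.blocks:
            z = relu.forward(bn.forward(conv.forward(z, False), False), False)
            if pool is not None:
                z = pool.forward(z, False)
        assert z.shape == (b * t, 5, 5, 64)
        assert net.global_pool.forward(z, False).shape == (b * t, 64)

    def test_window_too_small_is_spec_error(self):
        with pytest.raises(SpecError):
            build_network(NetworkSpec(window_shape=(10, 7, 7)))

    def test_class_order_truncation(self):
        assert NetworkSpec(n_classes=2).class_order == CLASS_ORDER[:2]
        assert NetworkSpec(n_classes=4).class_order == CLASS_ORDER
        with pytest.raises(SpecError):
            NetworkSpec(n_classes=1).validate()


class TestPrediction:
    @pytest.fixture(scope="class")
    def tiny_net(self):
        return build_network(
            NetworkSpec(base_filters=2, n_classes=3, window_shape=(4, 16, 16),
                        dense_sizes=(8,)), seed=3)

    def test_softmax_normalisation(self, tiny_net, rng):
        x = normalize_windows(rng.random((16, 4, 16, 16)))
        p = tiny_net.predict_proba(x)
        assert p.shape == (16, 3)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic(self, tiny_net, rng):
        w = WindowSequence(rng.random((4, 16, 16)).astype(np.float32))
        p1 = predict_window(tiny_net, w)
        p2 = predict_window(tiny_net, w)
        np.testing.assert_array_equal(p1, p2)

    def test_shape_mismatch_rejected(self, tiny_net, rng):
        w = WindowSequence(rng.random((4, 18, 18)).astype(np.float32))
        with pytest.raises(InvalidInputError):
            predict_window(tiny_net, w)


class TestGradients:
    """Finite-difference checks of every layer's backward pass."""

    @staticmethod
    def _check_layer(layer, x, rng, n_coords=5):
        y = layer.forward(x, True)
        w = rng.normal(size=y.shape).astype(np.float32)
        for p in getattr(layer, "params", []):
            p.zero_grad()
        dx = layer.backward(w)

        def loss():
            return float((layer.forward(x, True) * w).sum())

        flat, dflat = x.reshape(-1), dx.reshape(-1)
        for i in rng.choice(flat.size, n_coords, replace=False):
            eps, orig = 1e-3, flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            assert dflat[i] == pytest.approx((lp - lm) / (2 * eps),
                                             rel=5e-2, abs=5e-3)
        for p in getattr(layer, "params", []):
            pf, gf = p.value.reshape(-1), p.grad.reshape(-1)
            for i in rng.choice(pf.size, min(3, pf.size), replace=False):
                eps, orig = 1e-3, pf[i]
                pf[i] = orig + eps
                lp = loss()
                pf[i] = orig - eps
                lm = loss()
                pf[i] = orig
                assert gf[i] == pytest.approx((lp - lm) / (2 * eps),
                                              rel=5e-2, abs=5e-3), p.name

    def test_conv_backward(self, rng):
        from epievents.nn.layers import Conv2DSame
        self._check_layer(Conv2DSame(2, 3, rng),
                          rng.random((2, 6, 6, 2)).astype(np.float32), rng)

    def test_batchnorm_backward(self, rng):
        from epievents.nn.layers import BatchNorm
        self._check_layer(BatchNorm(2),
                          rng.random((2, 6, 6, 2)).astype(np.float32), rng)

    def test_maxpool_backward(self, rng):
        from epievents.nn.layers import MaxPool2x2
        self._check_layer(MaxPool2x2(),
                          rng.random((2, 7, 7, 2)).astype(np.float32), rng)

    def test_global_pool_backward(self, rng):
        from epievents.nn.layers import GlobalMaxPool
        self._check_layer(GlobalMaxPool(),
                          rng.random((3, 5, 5, 4)).astype(np.float32), rng)

    def test_gru_backward(self, rng):
        from epievents.nn.layers import GRU
        self._check_layer(GRU(3, 4, rng),
                          rng.random((2, 5, 3)).astype(np.float32), rng)

    def test_dense_backward(self, rng):
        from epievents.nn.layers import Dense
        self._check_layer(Dense(4, 3, rng),
                          rng.random((5, 4)).astype(np.float32), rng)

    def test_full_network_gradient_descends(self, rng):
        """A step along the analytic gradient decreases the composite loss."""
        spec = NetworkSpec(n_conv_blocks=2, base_filters=2,
                           window_shape=(3, 12, 12), dense_sizes=(4,),
                           dropout_rate=0.0, n_classes=2)
        net = build_network(spec, seed=1)
        x = rng.random((8, 3, 12, 12)).astype(np.float32)
        y = np.array([0, 1] * 4)
        logits = net.forward(x, train=True)
        loss0, dlogits, _ = softmax_cross_entropy(logits, y)
        for p in net.params:
            p.zero_grad()
        net.backward(dlogits)
        for p in net.params:
            p.value -= 0.05 * p.grad
        loss1, _, _ = softmax_cross_entropy(net.forward(x, train=True), y)
        assert loss1 < loss0


def _toy_training_set(rng, n_per_class=24, shape=(4, 16, 16)):
    """Separable fixture: centred bright blob vs pure noise (pattern-coded,
    so per-window normalisation cannot erase the signal)."""
    windows = []
    yy, xx = np.mgrid[0 : shape[1], 0 : shape[2]]
    blob = np.exp(-((yy - shape[1] / 2) ** 2 + (xx - shape[2] / 2) ** 2) / 10)
    for _ in range(n_per_class):
        vox = rng.random(shape).astype(np.float32)
        windows.append(WindowSequence(vox, EventClass.NONE))
        vox2 = rng.random(shape).astype(np.float32) + 6 * blob
        windows.append(WindowSequence(vox2.astype(np.float32),
                                      EventClass.EXTRUSION))
    return windows


class TestTraining:
    @pytest.fixture(scope="class")
    def toy_result(self):
        rng = np.random.default_rng(0)
        windows = _toy_training_set(rng)
        ts = split_train_validation(windows, 0.25, rng)
        spec = NetworkSpec(base_filters=2, n_classes=2,
                           window_shape=(4, 16, 16), dense_sizes=(8,),
                           dropout_rate=0.0)
        net = build_network(spec, seed=0)
        # no occluder-patch augmentation: a random square can cover the
        # discriminative blob on a 16-px toy window
        cfg = RunConfig(epochs=10, batch_size=8, augmentation_factor=1)
        net, history = train_network(net, ts, cfg, rng_seed=0)
        return net, history, ts

    def test_converges_on_separable_fixture(self, toy_result):
        _, history, _ = toy_result
        assert max(history["accuracy"]) > 0.95

    def test_history_length_and_finite_loss(self, toy_result):
        _, history, _ = toy_result
        assert len(history["loss"]) == 10
        assert len(history["val_loss"]) == 10
        assert np.all(np.isfinite(history["loss"]))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_validation_loss_improves(self, seed):
        rng = np.random.default_rng(seed)
        windows = _toy_training_set(rng, n_per_class=16)
        ts = split_train_validation(windows, 0.25, rng)
        spec = NetworkSpec(base_filters=2, n_classes=2,
                           window_shape=(4, 16, 16), dense_sizes=(8,),
                           dropout_rate=0.0)
        net = build_network(spec, seed=seed)
        cfg = RunConfig(epochs=6, batch_size=8)
        _, history = train_network(net, ts, cfg, rng_seed=seed)
        assert min(history["val_loss"]) < history["val_loss"][0]

    def test_single_class_rejected(self, rng):
        windows = [WindowSequence(rng.random((4, 16, 16)).astype(np.float32),
                                  EventClass.NONE) for _ in range(8)]
        ts = split_train_validation(windows, 0.25, rng)
        net = build_network(NetworkSpec(base_filters=2, n_classes=2,
                                        window_shape=(4, 16, 16)))
        with pytest.raises(InvalidInputError):
            train_network(net, ts, RunConfig(epochs=1))


class TestPersistence:
    def test_save_load_prediction_identity(self, tmp_path, toy_net=None):
        rng = np.random.default_rng(7)
        spec = NetworkSpec(base_filters=2, n_classes=2,
                           window_shape=(4, 16, 16), dense_sizes=(8,))
        net = build_network(spec, seed=7)
        save_network(net, tmp_path / "model")
        back = load_network(tmp_path / "model")
        x = normalize_windows(rng.random((10, 4, 16, 16)))
        np.testing.assert_array_equal(net.predict_proba(x),
                                      back.predict_proba(x))

    def test_sidecar_carries_class_order(self, tmp_path):
        net = build_network(NetworkSpec(base_filters=2, n_classes=3,
                                        window_shape=(4, 16, 16)))
        save_network(net, tmp_path / "m")
        text = (tmp_path / "m" / "network.cfg").read_text()
        assert "classes=none,extrusion,sop" in text
        assert load_network(tmp_path / "m").spec.n_classes == 3

    def test_weights_spec_mismatch_errors(self, tmp_path):
        net = build_network(NetworkSpec(base_filters=2, n_classes=2,
                                        window_shape=(4, 16, 16)))
        save_network(net, tmp_path / "m")
        cfg = (tmp_path / "m" / "network.cfg").read_text()
        (tmp_path / "m" / "network.cfg").write_text(
            cfg.replace("base_filters=2", "base_filters=4")
        )
        with pytest.raises(FormatError):
            load_network(tmp_path / "m")

    def test_not_a_model_dir(self, tmp_path):
        with pytest.raises(FormatError):
            load_network(tmp_path)
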