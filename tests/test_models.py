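"""FIR baseline (truncated-SVD least squares) and DNN construction/training."""

import numpy as np
import pytest

from emgtorque.models import (
    DnnSpec,
    DnnTorque,
    FirTorque,
    TrainConfig,
    build_network,
    cnn_shape_trace,
    fit_fir,
    predict_fir,
    train_network,
)
from emgtorque.synth import sample_ground_truth, synthesize_identification_data


class TestFirFitting:
    @pytest.mark.parametrize("seed", range(5))
    def test_parameter_recovery_noiseless(self, seed):
        # exact linear system with independent broadband excitation: the
        # untruncated solution recovers the generating kernels
        rng = np.random.default_rng(seed)
        kernels = rng.standard_normal((3, 16))
        amps, torque = synthesize_identification_data(kernels, 800, seed=seed + 100)
        res = fit_fir(amps, torque, order=15, sv_tolerance=0.0)
        assert np.max(np.abs(res.coefficients - kernels)) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_zero_tolerance_equals_normal_equations(self, seed):
        rng = np.random.default_rng(seed + 50)
        kernels = rng.standard_normal((2, 16))
        amps, torque = synthesize_identification_data(
            kernels, 500, seed=seed, noise_sd=0.3
        )
        res = fit_fir(amps, torque, order=15, sv_tolerance=0.0)
        # independent oracle: solve A'A theta = A'y directly
        n, c = amps.shape
        cols = [amps[15 - lag : n - lag, ch] for ch in range(c) for lag in range(16)]
        A = np.stack(cols, axis=1)
        theta = np.linalg.solve(A.T @ A, A.T @ torque[15:])
        assert np.max(np.abs(res.coefficients.ravel() - theta)) < 1e-8

    def test_zero_targets_zero_coefficients(self):
        amps = np.random.default_rng(0).random((100, 2))
        res = fit_fir(amps, np.zeros(100))
        assert not np.any(res.coefficients)

    def test_truncation_reduces_rank(self):
        # strongly collinear channels: relative tolerance must drop modes
        base = np.random.default_rng(1).random(300)
        amps = np.stack([base, base * 1.0001], axis=1)
        res = fit_fir(amps, base, order=15, sv_tolerance=0.005)
        assert res.rank < len(res.singular_values)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            FirTorque(np.zeros((10, 2)), np.zeros(10), order=15)

    def test_underdetermined_warns(self):
        with pytest.warns(UserWarning):
            FirTorque(np.random.default_rng(0).random((20, 2)), np.zeros(20), order=15)


class TestFirPrediction:
    def test_zero_envelope_zero_estimate(self):
        amps = np.random.default_rng(0).random((100, 2))
        res = fit_fir(amps, np.random.default_rng(1).random(100))
        assert not np.any(res.predict(np.zeros((50, 2))))

    def test_linearity(self):
        amps = np.random.default_rng(0).random((100, 2))
        res = fit_fir(amps, np.random.default_rng(1).random(100))
        x = np.random.default_rng(2).random((60, 2))
        assert np.allclose(res.predict(2.5 * x), 2.5 * res.predict(x))

    def test_matches_convolution_sum_oracle(self):
        amps = np.random.default_rng(0).random((100, 2))
        res = fit_fir(amps, np.random.default_rng(1).random(100))
        x = np.random.default_rng(3).random((50, 2))
        pred = predict_fir(res, x)
        # explicit double sum over channels and lags, zero-padded history
        expect = np.zeros(50)
        for t in range(50):
            for c in range(2):
                for lag in range(16):
                    if t - lag >= 0:
                        expect[t] += res.coefficients[c, lag] * x[t - lag, c]
        assert np.allclose(pred, expect, atol=1e-10)

    def test_memory_span(self):
        amps = np.random.default_rng(0).random((100, 1))
        res = fit_fir(amps, np.zeros(100), order=15)
        assert res.memory_span_s == pytest.approx(16 / 40.96)


MLP_SUMMARY = (
    "mlp (input (256,))\n"
    "  fc1: Dense(W[256, 128], b[128])\n"
    "  fc2: Dense(W[128, 128], b[128])\n"
    "  fc2_relu: ReLU()\n"
    "  fc3: Dense(W[128, 64], b[64])\n"
    "  fc3_relu: ReLU()\n"
    "  out: Dense(W[64, 1], b[1])\n"
    "  total parameters: 57729"
)

LSTM_SUMMARY = (
    "lstm (input (16, 16))\n"
    "  fc1: Dense(W[16, 128], b[128])\n"
    "  lstm: LSTM(Wx[128, 400], Wh[100, 400], b[400])\n"
    "  fc2: Dense(W[100, 64], b[64])\n"
    "  fc2_relu: ReLU()\n"
    "  out: Dense(W[64, 1], b[1])\n"
    "  total parameters: 100305"
)


class TestArchitectures:
    def test_mlp_layer_sizes(self):
        net = build_network(DnnSpec("mlp", (256,)))
        assert net["fc1"].params["W"].shape == (256, 128)
        assert net["fc2"].params["W"].shape == (128, 128)
        assert net["fc3"].params["W"].shape == (128, 64)
        assert net["out"].params["W"].shape == (64, 1)

    def test_mlp_summary_frozen(self):
        assert build_network(DnnSpec("mlp", (256,))).summary() == MLP_SUMMARY

    def test_lstm_summary_frozen(self):
        assert build_network(DnnSpec("lstm", (16, 16))).summary() == LSTM_SUMMARY

    def test_cnn_filter_counts_and_kernel_size(self):
        net = build_network(DnnSpec("cnn", (800, 16)))
        for b, (cin, cout) in enumerate([(1, 64), (64, 128), (128, 128), (128, 64)],
                                        start=1):
            conv = net[f"conv{b}"]
            assert conv.k == 3
            assert conv.params["W"].shape == (9 * cin, cout)
        # batch norm on blocks 1-3 only
        assert "bn3" in net.layer_names() and "bn4" not in net.layer_names()

    def test_cnn_flatten_width_target_domain(self):
        assert cnn_shape_trace(800, 16)[-1] == (50, 1, 64)
        net = build_network(DnnSpec("cnn", (800, 16)))
        assert net["fc1"].params["W"].shape == (3200, 128)

    def test_clstm_lstm_feature_width_domain_invariant(self):
        # shape trace through 4 pooling stages collapses the channel axis
        # for both domains, so the LSTM input width (64) transfers
        assert cnn_shape_trace(1600, 8)[-1] == (100, 1, 64)
        assert cnn_shape_trace(800, 16)[-1] == (50, 1, 64)
        for shape in ((1600, 8), (800, 16)):
            net = build_network(DnnSpec("clstm", shape))
            assert net["lstm"].params["Wx"].shape == (64, 2000)

    def test_same_seed_identical_initialisation(self):
        a = build_network(DnnSpec("mlp", (64,)), seed=3)
        b = build_network(DnnSpec("mlp", (64,)), seed=3)
        for (ka, va), (kb, vb) in zip(a.parameters(), b.parameters()):
            assert ka == kb and np.array_equal(va, vb)

    def test_incompatible_shape_rejected(self):
        with pytest.raises(ValueError):
            DnnSpec("mlp", (16, 16))
        with pytest.raises(ValueError):
            DnnSpec("cnn", (800,))
        with pytest.raises(ValueError):
            DnnSpec("resnet", (10,))

    def test_forward_shapes(self):
        x = np.random.default_rng(0).standard_normal((2, 800, 16, 1)).astype(np.float32)
        net = build_network(DnnSpec("cnn", (800, 16)))
        assert net.forward(x).shape == (2, 1)


class TestTraining:
    def _toy(self, n=200, f=12):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((n, f)).astype(np.float32)
        w = rng.standard_normal(f).astype(np.float32)
        y = X @ w + 0.1 * rng.standard_normal(n).astype(np.float32)
        return X, y

    def test_loss_decreases(self):
        X, y = self._toy()
        net = build_network(DnnSpec("mlp", (12,)), seed=0)
        hist = train_network(net, X, y, TrainConfig(n_epochs=10, batch_size=32))
        assert hist[-1] < hist[0]

    def test_zero_lr_noop(self):
        X, y = self._toy()
        net = build_network(DnnSpec("mlp", (12,)), seed=0)
        before = net.get_weights()
        train_network(net, X, y, TrainConfig(lr=0.0, n_epochs=3))
        for k, v in net.get_weights().items():
            if not k.endswith("running_mean") and not k.endswith("running_var"):
                assert np.array_equal(v, before[k]), k

    def test_epoch_11_learning_rate(self):
        assert TrainConfig().lr_at_epoch(10) == pytest.approx(2e-4)

    def test_deterministic_given_seed(self):
        X, y = self._toy()
        nets = []
        for _ in range(2):
            net = build_network(DnnSpec("mlp", (12,)), seed=4)
            train_network(net, X, y, TrainConfig(n_epochs=3, seed=9))
            nets.append(net.get_weights())
        for k in nets[0]:
            assert np.array_equal(nets[0][k], nets[1][k]), k

    def test_empty_training_rejected(self):
        net = build_network(DnnSpec("mlp", (12,)))
        with pytest.raises(ValueError):
            train_network(net, np.zeros((0, 12), dtype=np.float32), np.zeros(0),
                          TrainConfig())

    def test_model_results_round_trip(self):
        X, y = self._toy()
        res = DnnTorque(X, y, DnnSpec("mlp", (12,))).fit(TrainConfig(n_epochs=2))
        pred = res.predict(X)
        assert pred.shape == (200,)
        assert "trained 2 epochs" in res.summary()
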