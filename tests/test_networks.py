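"""Architectures and losses: shapes, stability contracts, hand-checked values."""

import math

import numpy as np
import pytest

from dpomics.networks import (
    AutoencoderSpec,
    ClassifierSpec,
    LayerSpec,
    NetworkParams,
    RegressorSpec,
    apply_dropout,
    corrupt_input,
    cross_entropy_loss,
    encode,
    forward_autoencoder,
    forward_classifier,
    forward_regressor,
    init_params,
    reconstruction_loss,
    regression_loss,
    relu,
    softmax,
    spec_from_record,
    spec_record,
)


class TestElementwise:
    def test_relu_values_and_idempotence(self, rng):
        assert np.array_equal(relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0])
        assert np.array_equal(relu(np.array([-3.0, -1e-9])), [0.0, 0.0])
        x = rng.normal(size=(20, 7))
        assert np.array_equal(relu(relu(x)), relu(x))

    def test_dropout_identity_cases(self, rng):
        x = rng.normal(size=(5, 4))
        assert np.array_equal(apply_dropout(x, 0.0, "train", 0), x)
        assert np.array_equal(apply_dropout(x, 0.7, "infer", 0), x)

    def test_dropout_is_unbiased(self):
        x = np.ones(100_000)
        out = apply_dropout(x, 0.5, "train", 99)
        # inverted dropout: E[out]=1, var = rate/(1-rate) = 1 -> 3 SE band
        assert abs(out.mean() - 1.0) < 3.0 / math.sqrt(x.size)

    def test_dropout_rate_domain(self):
        with pytest.raises(ValueError):
            apply_dropout(np.ones(3), 1.0, "train", 0)

    def test_corruption_law(self):
        X = np.zeros((400, 250))
        assert corrupt_input(X, 0.0, 0) is not None
        assert np.array_equal(corrupt_input(X, 0.0, 0), X)
        noisy = corrupt_input(X, 0.1, 5)
        se = 0.1 / math.sqrt(2 * (X.size - 1))
        assert abs(noisy.std() - 0.1) < 3 * se
        assert np.array_equal(corrupt_input(X, 0.1, 5), noisy)  # seeded
        with pytest.raises(ValueError):
            corrupt_input(X, -0.1, 0)

    def test_softmax_stability(self):
        assert np.allclose(softmax(np.array([[0.0, 0.0]])), [[0.5, 0.5]])
        big = softmax(np.array([[1000.0, 0.0]]))
        assert np.isfinite(big).all()
        assert big[0, 0] == pytest.approx(1.0, abs=1e-12)


class TestLosses:
    def test_reconstruction_loss(self, rng):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        B = np.array([[1.0, 2.0], [3.0, 6.0]])
        assert reconstruction_loss(A, A) == 0.0
        assert reconstruction_loss(B, A) == pytest.approx(1.0)
        # brute-force elementwise oracle
        X, Y = rng.normal(size=(6, 5)), rng.normal(size=(6, 5))
        manual = sum(
            (X[i, j] - Y[i, j]) ** 2 for i in range(6) for j in range(5)
        ) / 30.0
        assert reconstruction_loss(X, Y) == pytest.approx(manual, rel=1e-12)
        with pytest.raises(ValueError):
            reconstruction_loss(X, Y[:, :3])

    def test_cross_entropy_values(self):
        uniform = np.full((4, 2), 0.5)
        assert cross_entropy_loss(uniform, np.array([0, 1, 0, 1])) == pytest.approx(
            math.log(2), abs=1e-12
        )
        perfect = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(perfect, np.array([0, 1])) <= 1e-10
        hand = np.array([[0.8, 0.2], [0.6, 0.4]])
        expected = -(math.log(0.8) + math.log(0.4)) / 2
        assert cross_entropy_loss(hand, np.array([0, 1])) == pytest.approx(expected, abs=1e-9)
        with pytest.raises(ValueError):
            cross_entropy_loss(uniform, np.array([0, 1, 2, 1]))

    def test_regression_loss(self):
        assert regression_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert regression_loss(np.array([1.0, 3.0]), np.array([0.0, 0.0])) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            regression_loss(np.ones(3), np.ones(4))


class TestSpecs:
    def test_decoder_must_mirror_encoder(self):
        spec = AutoencoderSpec(input_dim=30, encoder_widths=(16, 8))
        assert spec.decoder_widths == (16, 30)
        assert spec.code_dim == 8
        with pytest.raises(ValueError):
            AutoencoderSpec(input_dim=30, encoder_widths=(16, 8), decoder_widths=(8, 30))

    def test_softmax_only_final(self):
        with pytest.raises(ValueError):
            LayerSpec(4, "sigmoid")
        spec = ClassifierSpec(input_dim=8)
        assert spec.layer_specs()[-1].activation == "softmax"
        assert spec.layer_specs()[-1].width == 2

    def test_regressor_single_output(self):
        assert RegressorSpec(input_dim=8).layer_specs()[-1].width == 1

    @pytest.mark.parametrize(
        "spec",
        [
            AutoencoderSpec(input_dim=12, encoder_widths=(6, 3)),
            ClassifierSpec(input_dim=5, hidden_width=4),
            RegressorSpec(input_dim=5, hidden_widths=(4, 3)),
        ],
    )
    def test_record_round_trip(self, spec):
        assert spec_from_record(spec_record(spec)) == spec


class TestForward:
    def test_autoencoder_shapes_and_zero_params(self):
        spec = AutoencoderSpec(input_dim=10, encoder_widths=(6, 4), dropout_rate=0.0)
        params = init_params(spec, 0)
        for W in params.weights:
            W[:] = 0.0
        X = np.random.default_rng(0).normal(size=(7, 10))
        recon, code = forward_autoencoder(params, spec, X)
        assert recon.shape == (7, 10) and code.shape == (7, 4)
        assert np.all(recon == 0.0) and np.all(code == 0.0)

    def test_code_dim_matches_bottleneck(self):
        spec = AutoencoderSpec(input_dim=10, encoder_widths=(8, 5))
        params = init_params(spec, 1)
        X = np.random.default_rng(1).normal(size=(4, 10))
        assert encode(params, spec, X).shape[1] == spec.code_dim == 5

    def test_infer_mode_is_deterministic(self):
        spec = AutoencoderSpec(input_dim=10, encoder_widths=(6, 4), dropout_rate=0.5)
        params = init_params(spec, 2)
        X = np.random.default_rng(3).normal(size=(5, 10))
        r1, c1 = forward_autoencoder(params, spec, X, mode="infer")
        r2, c2 = forward_autoencoder(params, spec, X, mode="infer")
        assert np.array_equal(r1, r2) and np.array_equal(c1, c2)

    def test_classifier_rows_are_probabilities(self):
        spec = ClassifierSpec(input_dim=6, dropout_rate=0.0)
        params = init_params(spec, 4)
        codes = np.random.default_rng(5).normal(size=(9, 6))
        probs = forward_classifier(params, spec, codes)
        assert probs.shape == (9, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_regressor_matches_matrix_product(self):
        # single linear layer: prediction = codes @ w + b
        spec = RegressorSpec(input_dim=3, hidden_widths=())
        params = init_params(spec, 6)
        params.weights[0][:] = np.array([[1.0], [2.0], [-1.0]])
        params.biases[0][:] = 0.5
        codes = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 0.0]])
        assert np.allclose(forward_regressor(params, spec, codes), [-0.5, 2.5])

    def test_zero_weights_regressor_predicts_bias(self):
        spec = RegressorSpec(input_dim=4, hidden_widths=(3,), dropout_rate=0.0)
        params = init_params(spec, 7)
        for W in params.weights:
            W[:] = 0.0
        params.biases[-1][:] = 1.25
        preds = forward_regressor(params, spec, np.ones((5, 4)))
        assert np.allclose(preds, 1.25)

    def test_shape_mismatch_rejected(self):
        spec = ClassifierSpec(input_dim=6)
        params = init_params(spec, 8)
        with pytest.raises(ValueError):
            forward_classifier(params, spec, np.ones((3, 5)))


class TestInit:
    def test_deterministic_and_zero_biases(self):
        spec = ClassifierSpec(input_dim=20, hidden_width=10)
        p1, p2 = init_params(spec, 42), init_params(spec, 42)
        for W1, W2 in zip(p1.weights, p2.weights):
            assert np.array_equal(W1, W2)
        for b in p1.biases:
            assert np.all(b == 0.0)

    def test_he_variance(self):
        spec = AutoencoderSpec(input_dim=400, encoder_widths=(300,), dropout_rate=0.0)
        params = init_params(spec, 9)
        W = params.weights[0]  # fan_in 400
        assert W.var() == pytest.approx(2.0 / 400, rel=0.05)

    def test_shape_chaining_enforced(self):
        with pytest.raises(ValueError):
            NetworkParams(
                weights=[np.ones((3, 4)), np.ones((5, 2))],
                biases=[np.zeros(4), np.zeros(2)],
            )
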