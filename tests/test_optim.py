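"""DP-SGD machinery: clipping, the noise law, per-example gradients, accountant charging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dpomics.networks import ClassifierSpec, RegressorSpec, init_params
from dpomics.optim import (
    ClipSpec,
    SGDConfig,
    clip_per_example,
    dp_sgd_step,
    iterate_minibatches,
    noisy_aggregate,
    per_example_gradients,
    per_example_losses_and_gradients,
)
from dpomics.privacy import BudgetExhaustedError, RDPParams, plan_schedule

from .oracles import batch_gradients


class TestClipping:
    def test_rescaling_preserves_direction(self):
        out = clip_per_example(np.array([3.0, 4.0]), ClipSpec(1.0))
        assert np.allclose(out, [0.6, 0.8])

    def test_within_bound_unchanged(self):
        g = np.array([0.3, 0.4])
        assert np.array_equal(clip_per_example(g, ClipSpec(1.0)), g)

    def test_zero_is_fixed_point(self):
        assert np.array_equal(clip_per_example(np.zeros(4), ClipSpec(0.5)), np.zeros(4))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            clip_per_example(np.array([np.inf, 1.0]), ClipSpec(1.0))

    @settings(derandomize=True, max_examples=100)
    @given(
        g=arrays(float, st.integers(1, 20), elements=st.floats(-1e6, 1e6)),
        clip=st.floats(0.01, 100.0),
    )
    def test_clipped_norm_never_exceeds_bound(self, g, clip):
        out = clip_per_example(g, ClipSpec(clip))
        assert np.linalg.norm(out) <= clip * (1 + 1e-12)


class TestNoisyAggregate:
    def test_sigma_zero_is_clipped_mean(self):
        batch = np.array([[2.0, 0.0], [0.0, 2.0]])
        out = noisy_aggregate(batch, ClipSpec(10.0), 0.0, 0)
        assert np.allclose(out, [1.0, 1.0])

    def test_seeded_determinism(self):
        batch = np.zeros((4, 3))
        a = noisy_aggregate(batch, ClipSpec(1.0), 1.0, 123)
        b = noisy_aggregate(batch, ClipSpec(1.0), 1.0, 123)
        assert np.array_equal(a, b)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            noisy_aggregate(np.empty((0, 3)), ClipSpec(1.0), 0.0, 0)

    def test_noise_scale(self):
        # sigma=1, C=1, B=4: per-coordinate std of the mean is sigma*C/B
        rng = np.random.default_rng(7)
        draws = np.array(
            [noisy_aggregate(np.zeros((4, 3)), ClipSpec(1.0), 1.0, rng) for _ in range(20_000)]
        )
        target = 0.25
        se = target / math.sqrt(2 * (draws.size - 1))
        assert abs(draws.std() - target) < 4 * se


class TestPerExampleGradients:
    def test_linear_model_hand_value(self):
        # f(x) = w x, loss (f - y)^2, w=1, sample (x=2, y=1): dL/dw = 2x(wx-y) = 4
        spec = RegressorSpec(input_dim=1, hidden_widths=())
        params = init_params(spec, 0)
        params.weights[0][:] = 1.0
        grads = per_example_gradients(
            params, spec.layer_specs(), np.array([[2.0]]), np.array([[1.0]]), "mse"
        )
        assert grads.shape == (1, 2)  # w then b
        assert grads[0, 0] == pytest.approx(4.0)
        assert grads[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("loss,spec", [
        ("mse", RegressorSpec(input_dim=6, hidden_widths=(5,), dropout_rate=0.0)),
        ("xent", ClassifierSpec(input_dim=6, hidden_width=5, dropout_rate=0.0)),
    ])
    def test_mean_equals_batch_gradient(self, loss, spec, rng):
        """Mean of per-example gradients = analytic full-batch gradient of the mean loss."""
        params = init_params(spec, 3)
        X = rng.normal(size=(11, 6))
        if loss == "mse":
            targets = rng.normal(size=(11, 1))
        else:
            targets = rng.integers(0, 2, size=11)
        grads = per_example_gradients(params, spec.layer_specs(), X, targets, loss, mode="infer")
        acts = [ls.activation for ls in spec.layer_specs()]
        dWs, dbs = batch_gradients(params.weights, params.biases, acts, X, targets, loss)
        flat = np.concatenate([np.concatenate([W.ravel(), b]) for W, b in zip(dWs, dbs)])
        assert np.allclose(grads.mean(axis=0), flat, atol=1e-8)

    def test_finite_difference_agreement(self, rng):
        """Central finite differences confirm the backprop on a 2-layer toy net."""
        spec = ClassifierSpec(input_dim=4, hidden_width=3, dropout_rate=0.0)
        params = init_params(spec, 5)
        X = rng.normal(size=(3, 4))
        y = np.array([0, 1, 1])
        losses, grads = per_example_losses_and_gradients(
            params, spec.layer_specs(), X, y, "xent", mode="infer"
        )
        vec = params.to_vector()
        h = 1e-5
        for j in range(len(vec)):
            for sign, store in ((1, "hi"), (-1, "lo")):
                shifted = params.copy()
                delta = np.zeros_like(vec)
                delta[j] = sign * h
                shifted.add_vector_(delta)
                l, _ = per_example_losses_and_gradients(
                    shifted, spec.layer_specs(), X, y, "xent", mode="infer"
                )
                if sign == 1:
                    hi = l
                else:
                    lo = l
            numeric = (hi - lo) / (2 * h)
            assert np.allclose(grads[:, j], numeric, rtol=1e-4, atol=1e-7)

    def test_mismatched_counts_rejected(self):
        spec = ClassifierSpec(input_dim=4, hidden_width=3)
        params = init_params(spec, 0)
        with pytest.raises(ValueError):
            per_example_gradients(
                params, spec.layer_specs(), np.ones((3, 4)), np.array([0, 1]), "xent"
            )


class TestDpSgdStep:
    def _setup(self, rng):
        spec = RegressorSpec(input_dim=5, hidden_widths=(4,), dropout_rate=0.0)
        params = init_params(spec, 2)
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=(8, 1))
        return spec, params, X, y

    def test_noise_free_equals_textbook_sgd(self, rng):
        """sigma=0 with a non-binding clip bound reproduces plain mini-batch SGD."""
        spec, params, X, y = self._setup(rng)
        reference = params.copy()
        config = SGDConfig(learning_rate=0.1, batch_size=8, epochs=1)
        dp_sgd_step(params, spec.layer_specs(), X, y, "mse", config, ClipSpec(1e9))
        acts = [ls.activation for ls in spec.layer_specs()]
        dWs, dbs = batch_gradients(reference.weights, reference.biases, acts, X, y, "mse")
        for W, dW, Wn in zip(reference.weights, dWs, params.weights):
            assert np.allclose(W - 0.1 * dW, Wn, atol=1e-10)
        for b, db, bn in zip(reference.biases, dbs, params.biases):
            assert np.allclose(b - 0.1 * db, bn, atol=1e-10)

    def test_single_step_schedule_fully_spent(self, rng):
        spec, params, X, y = self._setup(rng)
        state = plan_schedule(RDPParams(2.0, 1.0), clip_norm=1.0, planned_steps=1)
        config = SGDConfig(learning_rate=0.1, batch_size=8, epochs=1)
        dp_sgd_step(params, spec.layer_specs(), X, y, "mse", config, ClipSpec(1.0),
                    accountant=state, sigma=state.sigma, noise_rng=0)
        assert state.spent() == pytest.approx(state.total_epsilon, abs=1e-9)
        with pytest.raises(BudgetExhaustedError):
            dp_sgd_step(params, spec.layer_specs(), X, y, "mse", config, ClipSpec(1.0),
                        accountant=state, sigma=state.sigma, noise_rng=0)

    def test_zero_learning_rate_still_charges_budget(self, rng):
        spec, params, X, y = self._setup(rng)
        before = params.to_vector()
        state = plan_schedule(RDPParams(2.0, 1.0), clip_norm=1.0, planned_steps=3)
        config = SGDConfig(learning_rate=0.0, batch_size=8, epochs=1)
        dp_sgd_step(params, spec.layer_specs(), X, y, "mse", config, ClipSpec(1.0),
                    accountant=state, sigma=state.sigma, noise_rng=1)
        assert np.array_equal(params.to_vector(), before)
        assert state.steps_taken == 1


def test_iterate_minibatches_drops_last():
    batches = iterate_minibatches(10, 3, 0)
    assert len(batches) == 3
    assert sorted(len(b) for b in batches) == [3, 3, 3]
    with pytest.raises(ValueError):
        iterate_minibatches(2, 3, 0)
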