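"""DP-SGD: per-example gradient clipping, Gaussian noise, accountant-charged updates.

One noisy parameter update is the Gaussian mechanism applied to the SUM of
per-example gradients, each clipped to l2 norm at most ``C``:

    g_tilde = ( sum_i clip(g_i, C) + Normal(0, sigma^2 C^2 I) ) / B

Removing any single example changes the clipped sum by at most ``C`` in l2
norm, so the mechanism's sensitivity is exactly the clip norm and the noise
scale ``sigma`` produced by :func:`dpomics.privacy.plan_schedule` carries the
advertised per-step RDP cost.  Every update charges the accountant exactly
once; the budget-exhausted error aborts training rather than overspending.

Per-example gradients are computed by manual backprop through the dense
stacks of :mod:`dpomics.networks` (losses: reconstruction/regression MSE and
softmax cross-entropy).  Gradient vectors follow the fixed flattening order of
:class:`~dpomics.networks.NetworkParams` (layer-major, weights before biases).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .networks import LayerSpec, NetworkParams, as_generator, forward
from .privacy import AccountantState, record_step

LOSSES = ("mse", "xent")


@dataclass(frozen=True)
class ClipSpec:
    """Per-example l2 clipping bound C > 0; this IS the mechanism sensitivity."""

    clip_norm: float

    def __post_init__(self) -> None:
        if not self.clip_norm > 0:
            raise ValueError(f"clip_norm must be positive, got {self.clip_norm}")


@dataclass(frozen=True)
class SGDConfig:
    """Plain (momentum-free) mini-batch SGD settings; the seed fixes every random draw."""

    learning_rate: float
    batch_size: int
    epochs: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.learning_rate >= 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


def clip_per_example(grad: np.ndarray, clip: ClipSpec) -> np.ndarray:
    """Rescale one flat gradient to l2 norm at most C: ``g * min(1, C/||g||)``.

    Direction is preserved; vectors already within the bound pass unchanged.
    """
    grad = np.asarray(grad, dtype=float)
    if not np.isfinite(grad).all():
        raise ValueError("gradient has non-finite entries")
    norm = np.linalg.norm(grad)
    if norm <= clip.clip_norm or norm == 0.0:
        return grad
    return grad * (clip.clip_norm / norm)


def clip_batch(per_example: np.ndarray, clip: ClipSpec) -> np.ndarray:
    """Row-wise clipping of an (n, P) per-example gradient matrix."""
    per_example = np.asarray(per_example, dtype=float)
    if not np.isfinite(per_example).all():
        raise ValueError("gradient batch has non-finite entries")
    norms = np.linalg.norm(per_example, axis=1, keepdims=True)
    factors = np.ones_like(norms)
    np.divide(clip.clip_norm, norms, out=factors, where=norms > clip.clip_norm)
    return per_example * factors


def noisy_aggregate(per_example: np.ndarray, clip: ClipSpec, sigma: float, rng_seed) -> np.ndarray:
    """Clipped-sum Gaussian mechanism, averaged over the batch.

    Returns ``(sum_i clip(g_i, C) + z) / B`` with ``z ~ Normal(0, sigma^2 C^2 I)``.
    Deterministic given the seed; ``sigma = 0`` reduces exactly to the clipped
    mean (no random draw is made).
    """
    per_example = np.atleast_2d(np.asarray(per_example, dtype=float))
    if per_example.shape[0] == 0:
        raise ValueError("cannot aggregate an empty gradient batch")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    batch_size = per_example.shape[0]
    total = clip_batch(per_example, clip).sum(axis=0)
    if sigma > 0:
        rng = as_generator(rng_seed)
        total = total + rng.normal(0.0, sigma * clip.clip_norm, size=total.shape)
    return total / batch_size


# ---------------------------------------------------------------------------
# per-example gradients (manual backprop)
# ---------------------------------------------------------------------------

def _loss_output_grad(output: np.ndarray, targets: np.ndarray, loss: str):
    """Per-example losses and dL_i/d(final layer output) for the supported losses.

    mse:  L_i = mean_j (out_ij - t_ij)^2           -> dL/dout = 2 (out - t) / D
    xent: L_i = -log p_i[y_i] (softmax final layer) -> dL/dlogits = p - onehot
    """
    if loss == "mse":
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        if targets.shape != output.shape:
            raise ValueError(f"target shape {targets.shape} != output shape {output.shape}")
        diff = output - targets
        losses = np.mean(diff**2, axis=1)
        return losses, 2.0 * diff / output.shape[1]
    if loss == "xent":
        labels = np.asarray(targets).astype(int).ravel()
        if labels.shape[0] != output.shape[0]:
            raise ValueError("label count does not match batch size")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        p_true = output[np.arange(len(labels)), labels]
        losses = -np.log(np.maximum(p_true, 1e-12))
        delta = output.copy()
        delta[np.arange(len(labels)), labels] -= 1.0
        return losses, delta
    raise ValueError(f"unknown loss {loss!r}; expected one of {LOSSES}")


def per_example_losses_and_gradients(
    params: NetworkParams,
    layers: Sequence[LayerSpec],
    inputs: np.ndarray,
    targets: np.ndarray,
    loss: str,
    mode: str = "train",
    rng=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Backprop yielding one flat gradient per example.

    Returns ``(losses, G)`` where ``losses`` has shape (n,) and ``G`` has shape
    (n, n_params).  The mean of the rows of ``G`` equals the gradient of the
    mean loss.  For the cross-entropy, the final layer must be the softmax
    layer; the softmax Jacobian and the log-loss collapse to ``p - onehot``.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    n = inputs.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    if loss == "xent" and np.asarray(targets).ravel().shape[0] != n:
        raise ValueError("mismatched sample counts between inputs and targets")
    cache: dict = {}
    output = forward(params, layers, inputs, mode=mode, rng=rng, cache=cache)
    if loss == "xent" and layers[-1].activation != "softmax":
        raise ValueError("cross-entropy requires a softmax final layer")
    losses, delta = _loss_output_grad(output, targets, loss)

    grads = np.empty((n, params.n_params))
    # per-layer slice offsets in the flat vector (layer-major, W before b)
    offsets = []
    off = 0
    for W, b in zip(params.weights, params.biases):
        offsets.append((off, off + W.size, off + W.size + b.size))
        off += W.size + b.size

    for li in range(len(layers) - 1, -1, -1):
        ls = layers[li]
        mask = cache["masks"][li]
        if mask is not None:
            delta = delta * mask
        if ls.activation == "relu":
            delta = delta * (cache["pre"][li] > 0)
        # softmax/identity: delta already w.r.t. pre-activation
        a_prev = cache["inputs"][li]
        w_lo, b_lo, b_hi = offsets[li]
        dW = np.einsum("ni,nj->nij", a_prev, delta)
        grads[:, w_lo:b_lo] = dW.reshape(n, -1)
        grads[:, b_lo:b_hi] = delta
        if li > 0:
            delta = delta @ params.weights[li].T
    return losses, grads


def per_example_gradients(
    params: NetworkParams,
    layers: Sequence[LayerSpec],
    inputs: np.ndarray,
    targets: np.ndarray,
    loss: str,
    mode: str = "train",
    rng=None,
) -> np.ndarray:
    """One flat gradient vector per sample (see :func:`per_example_losses_and_gradients`)."""
    _, grads = per_example_losses_and_gradients(params, layers, inputs, targets, loss, mode, rng)
    return grads


# ---------------------------------------------------------------------------
# the DP-SGD step
# ---------------------------------------------------------------------------

def dp_sgd_step(
    params: NetworkParams,
    layers: Sequence[LayerSpec],
    inputs: np.ndarray,
    targets: np.ndarray,
    loss: str,
    config: SGDConfig,
    clip: ClipSpec,
    accountant: AccountantState | None = None,
    sigma: float = 0.0,
    grad_rng=None,
    noise_rng=None,
) -> float:
    """One noisy parameter update, in place; returns the batch loss before the update.

    ``sigma`` is the noise MULTIPLIER relative to the clip norm (the noise
    added to the clipped gradient sum has scale ``sigma * C``), matching
    :func:`noisy_aggregate`; the accountant's calibrated scale is absolute, so
    callers pass ``accountant.sigma / C``.  The accountant (if any) is charged
    exactly once, BEFORE the update, so an exhausted budget aborts without
    touching the parameters.  With ``sigma = 0`` the step is bit-identical to
    a plain clipped-SGD step; with a non-binding clip bound it reduces to
    textbook mini-batch SGD.  A zero learning rate still charges the
    accountant: the noisy gradient was released whether or not it moved the
    model.
    """
    if accountant is not None:
        record_step(accountant)
    losses, grads = per_example_losses_and_gradients(
        params, layers, inputs, targets, loss, mode="train", rng=grad_rng
    )
    update = noisy_aggregate(grads, clip, sigma, noise_rng)
    params.add_vector_(update, scale=-config.learning_rate)
    return float(losses.mean())


def iterate_minibatches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    """One epoch's batch index sets: a seeded shuffle split into full batches.

    The incomplete final batch is dropped so every mechanism invocation has
    identical batch size (and hence identical per-step budget).
    """
    if n < batch_size:
        raise ValueError(f"need at least one full batch: n={n} < batch_size={batch_size}")
    perm = as_generator(rng).permutation(n)
    n_batches = n // batch_size
    return [perm[i * batch_size : (i + 1) * batch_size] for i in range(n_batches)]
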