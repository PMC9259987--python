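"""Independent reference implementations used only as test oracles.

Deliberately naive: full-batch-mean backprop with per-layer loops, no
per-example machinery, no clipping, no noise.  These re-derive the training
trajectory that DP-SGD must reproduce exactly when its privacy machinery is
switched off (sigma = 0, no corruption, no dropout, non-binding clip bound).

They share only the documented conventions of the package (He init from
substream 0, epoch shuffles from substream 1 of SeedSequence(seed).spawn(6),
drop-last batching, plain SGD update) — the numerics are written from
scratch.
"""

from __future__ import annotations

import numpy as np


def _he_init(widths, rng):
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _softmax(z):
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _forward_cached(weights, biases, activations, X):
    pre, post = [], [X]
    a = X
    for W, b, act in zip(weights, biases, activations):
        z = a @ W + b
        pre.append(z)
        if act == "relu":
            a = np.maximum(z, 0.0)
        elif act == "softmax":
            a = _softmax(z)
        else:
            a = z
        post.append(a)
    return pre, post


def batch_gradients(weights, biases, activations, X, targets, loss):
    """Gradient of the MEAN loss over the batch, one (dW, db) pair per layer."""
    n = X.shape[0]
    pre, post = _forward_cached(weights, biases, activations, X)
    out = post[-1]
    if loss == "mse":
        delta = 2.0 * (out - targets) / targets.shape[1] / n
    elif loss == "xent":
        onehot = np.zeros_like(out)
        onehot[np.arange(n), np.asarray(targets, dtype=int)] = 1.0
        delta = (out - onehot) / n
    else:
        raise ValueError(loss)
    dWs, dbs = [None] * len(weights), [None] * len(weights)
    for li in range(len(weights) - 1, -1, -1):
        if activations[li] == "relu":
            delta = delta * (pre[li] > 0)
        dWs[li] = post[li].T @ delta
        dbs[li] = delta.sum(axis=0)
        if li > 0:
            delta = delta @ weights[li].T
    return dWs, dbs


def plain_sgd_train(X, targets, widths, activations, loss, learning_rate, batch_size, epochs, seed):
    """Reference trajectory: plain mini-batch SGD with the package's seeding conventions.

    Returns the final (weights, biases).
    """
    X = np.asarray(X, dtype=float)
    streams = np.random.SeedSequence(seed).spawn(6)
    init_rng = np.random.default_rng(streams[0])
    shuffle_rng = np.random.default_rng(streams[1])
    weights, biases = _he_init(widths, init_rng)
    n = X.shape[0]
    n_batches = n // batch_size
    for _ in range(epochs):
        perm = shuffle_rng.permutation(n)
        for b in range(n_batches):
            idx = perm[b * batch_size : (b + 1) * batch_size]
            tgt = targets[idx]
            dWs, dbs = batch_gradients(weights, biases, activations, X[idx], tgt, loss)
            for W, bb, dW, db in zip(weights, biases, dWs, dbs):
                W -= learning_rate * dW
                bb -= learning_rate * db
    return weights, biases


def brute_force_auc(scores, labels):
    """AUC by enumeration of every positive-negative pair (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    wins = 0.0
    pairs = 0
    for sp in scores[labels == 1]:
        for sn in scores[labels == 0]:
            pairs += 1
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / pairs


def spearman_d2(predicted, truth):
    """Tie-free Spearman via the classical d^2 formula: 1 - 6 sum d^2 / (n(n^2-1))."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    n = len(truth)
    r1 = np.argsort(np.argsort(predicted)) + 1
    r2 = np.argsort(np.argsort(truth)) + 1
    d2 = np.sum((r1 - r2) ** 2)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))
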