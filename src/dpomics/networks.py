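"""Architectures and losses: denoising autoencoder, softmax classifier, scalar regressor.

Everything here is a pure forward/loss computation on explicit parameter
containers; the DP-SGD machinery in :mod:`dpomics.optim` owns gradients and
updates.  All three model families are plain fully-connected stacks:

* dpAE — denoising autoencoder.  The clean input is corrupted with elementwise
  Gaussian noise, encoded through relu+dropout dense layers to a bottleneck
  code, decoded through the mirrored widths back to the input dimension, and
  scored by mean-squared reconstruction error against the CLEAN input.
* dpClassM — one relu+dropout hidden layer on autoencoder codes, a 2-unit
  output layer with a row softmax, cross-entropy loss.
* dpRegM — relu+dropout hidden layers on codes, a single linear output unit,
  mean-squared-error loss.

Numerical contracts: softmax subtracts the row max before exponentiating;
cross-entropy clamps probabilities at 1e-12; dropout is "inverted" (survivors
scaled by 1/(1-rate)) so inference mode is the exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

_ACTIVATIONS = ("relu", "identity", "softmax")

#: floor applied to probabilities inside the cross-entropy
PROB_CLAMP = 1e-12


def as_generator(rng) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or a Generator; return a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One dense layer: ``width`` output units, activation, inverted-dropout rate."""

    width: int
    activation: str = "relu"
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError(f"layer width must be positive, got {self.width}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {self.dropout_rate}")


def _check_softmax_position(layers: Sequence[LayerSpec]) -> None:
    for ls in layers[:-1]:
        if ls.activation == "softmax":
            raise ValueError("softmax is only valid as the final classifier activation")


@dataclass(frozen=True)
class AutoencoderSpec:
    """Denoising autoencoder architecture.

    The default widths (64, 32, 16) are a desk-scale profile; the full-scale
    profile (8000, 4000, 2000), sized for transcriptome-width inputs, runs
    through the identical code path via :meth:`full_scale`.  The decoder must
    mirror the encoder: reversed hidden widths, final width = ``input_dim``.
    ``corruption_std`` is the elementwise Gaussian noise added to the input
    during training only (0.1 default; reconstruction always targets the clean
    input).
    """

    input_dim: int
    encoder_widths: tuple[int, ...] = (64, 32, 16)
    decoder_widths: tuple[int, ...] | None = None
    corruption_std: float = 0.1
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if len(self.encoder_widths) < 1:
            raise ValueError("encoder needs at least one layer")
        enc = tuple(int(w) for w in self.encoder_widths)
        object.__setattr__(self, "encoder_widths", enc)
        mirror = tuple(reversed(enc[:-1])) + (self.input_dim,)
        if self.decoder_widths is None:
            object.__setattr__(self, "decoder_widths", mirror)
        else:
            dec = tuple(int(w) for w in self.decoder_widths)
            if dec != mirror:
                raise ValueError(
                    f"decoder widths {dec} must mirror the encoder: expected {mirror}"
                )
            object.__setattr__(self, "decoder_widths", dec)
        if self.corruption_std < 0:
            raise ValueError("corruption_std must be non-negative")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def full_scale(cls, input_dim: int, **kw) -> "AutoencoderSpec":
        """The 8000/4000/2000 width profile for transcriptome-width inputs."""
        return cls(input_dim=input_dim, encoder_widths=(8000, 4000, 2000), **kw)

    @property
    def code_dim(self) -> int:
        return self.encoder_widths[-1]

    @property
    def n_encoder_layers(self) -> int:
        return len(self.encoder_widths)

    def layer_specs(self) -> list[LayerSpec]:
        layers = [LayerSpec(w, "relu", self.dropout_rate) for w in self.encoder_widths]
        layers += [LayerSpec(w, "relu", self.dropout_rate) for w in self.decoder_widths[:-1]]
        layers.append(LayerSpec(self.decoder_widths[-1], "identity", 0.0))
        return layers


@dataclass(frozen=True)
class ClassifierSpec:
    """Binary softmax head on autoencoder codes: dense+relu+dropout, then a 2-unit softmax layer."""

    input_dim: int
    hidden_width: int = 16
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_width < 1:
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def layer_specs(self) -> list[LayerSpec]:
        return [
            LayerSpec(self.hidden_width, "relu", self.dropout_rate),
            LayerSpec(2, "softmax", 0.0),
        ]


@dataclass(frozen=True)
class RegressorSpec:
    """Scalar regression head on autoencoder codes: relu+dropout hiddens, one linear output."""

    input_dim: int
    hidden_widths: tuple[int, ...] = (16,)
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        object.__setattr__(self, "hidden_widths", tuple(int(w) for w in self.hidden_widths))
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def layer_specs(self) -> list[LayerSpec]:
        layers = [LayerSpec(w, "relu", self.dropout_rate) for w in self.hidden_widths]
        layers.append(LayerSpec(1, "identity", 0.0))
        return layers


ModelSpec = AutoencoderSpec | ClassifierSpec | RegressorSpec


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class NetworkParams:
    """Ordered dense-layer parameters: weight matrices (fan_in x fan_out) and bias vectors.

    Flattening order is fixed and documented — layer-major, each layer's weight
    matrix (C order) before its bias — so serialized states and gradient
    vectors are portable.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must pair up")
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.ndim != 2 or b.ndim != 1 or W.shape[1] != b.shape[0]:
                raise ValueError(f"layer {i}: weight {W.shape} and bias {b.shape} do not chain")
            if i > 0 and self.weights[i - 1].shape[1] != W.shape[0]:
                raise ValueError(f"layer {i}: fan-in {W.shape[0]} does not chain")
            if not (np.isfinite(W).all() and np.isfinite(b).all()):
                raise ValueError(f"layer {i}: non-finite parameter entries")

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    def copy(self) -> "NetworkParams":
        return NetworkParams([W.copy() for W in self.weights], [b.copy() for b in self.biases])

    def to_vector(self) -> np.ndarray:
        parts = []
        for W, b in zip(self.weights, self.biases):
            parts.append(W.ravel())
            parts.append(b)
        return np.concatenate(parts)

    def add_vector_(self, vec: np.ndarray, scale: float = 1.0) -> None:
        """In-place ``params += scale * vec`` following the fixed flattening order."""
        if vec.shape != (self.n_params,):
            raise ValueError(f"update vector has shape {vec.shape}, expected ({self.n_params},)")
        off = 0
        for W, b in zip(self.weights, self.biases):
            W += scale * vec[off : off + W.size].reshape(W.shape)
            off += W.size
            b += scale * vec[off : off + b.size]
            off += b.size


def init_params(spec: ModelSpec, rng_seed) -> NetworkParams:
    """He-style initialization: W ~ Normal(0, 2/fan_in), biases zero; deterministic per seed."""
    rng = as_generator(rng_seed)
    widths = [spec.input_dim] + [ls.width for ls in spec.layer_specs()]
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkParams(weights, biases)


# ---------------------------------------------------------------------------
# elementwise pieces
# ---------------------------------------------------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    x = np.asarray(x)
    if not np.isfinite(x).all():
        raise ValueError("relu input must be finite")
    return np.maximum(0.0, x)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row softmax with max-subtraction for overflow safety."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def corrupt_input(X: np.ndarray, s: float, rng_seed) -> np.ndarray:
    """Denoising corruption: add elementwise Normal(0, s^2) noise; s=0 is the identity."""
    if s < 0:
        raise ValueError(f"corruption std must be non-negative, got {s}")
    X = np.asarray(X, dtype=float)
    if s == 0:
        return X
    rng = as_generator(rng_seed)
    return X + rng.normal(0.0, s, size=X.shape)


def apply_dropout(x: np.ndarray, rate: float, mode: str, rng_seed) -> np.ndarray:
    """Inverted dropout: zero units w.p. ``rate`` and scale survivors by 1/(1-rate) in train
    mode; exact identity in infer mode."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if mode not in ("train", "infer"):
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    x = np.asarray(x, dtype=float)
    if mode == "infer" or rate == 0.0:
        return x
    rng = as_generator(rng_seed)
    mask = rng.random(x.shape) >= rate
    return x * mask / (1.0 - rate)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def forward(
    params: NetworkParams,
    layers: Sequence[LayerSpec],
    X: np.ndarray,
    mode: str = "infer",
    rng=None,
    cache: dict | None = None,
):
    """Run the dense stack; optionally record the per-layer caches backprop needs.

    ``cache`` (if a dict is passed) is filled with ``inputs`` (activations
    entering each layer), ``pre`` (pre-activations) and ``masks`` (dropout
    keep-masks already scaled, or None).  Dropout draws come from ``rng`` and
    are only made in train mode with a positive rate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(layers) != params.n_layers:
        raise ValueError(f"{len(layers)} layer specs but {params.n_layers} parameter layers")
    if X.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {params.weights[0].shape[0]}"
        )
    _check_softmax_position(layers)
    if mode not in ("train", "infer"):
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    if cache is not None:
        cache["inputs"], cache["pre"], cache["masks"] = [], [], []
    a = X
    gen = as_generator(rng) if rng is not None else None
    for ls, W, b in zip(layers, params.weights, params.biases):
        z = a @ W + b
        if ls.activation == "relu":
            h = np.maximum(0.0, z)
        elif ls.activation == "softmax":
            h = softmax(z)
        else:
            h = z
        mask = None
        if ls.dropout_rate > 0.0 and mode == "train":
            if gen is None:
                gen = np.random.default_rng()
            mask = (gen.random(h.shape) >= ls.dropout_rate) / (1.0 - ls.dropout_rate)
            h = h * mask
        if cache is not None:
            cache["inputs"].append(a)
            cache["pre"].append(z)
            cache["masks"].append(mask)
        a = h
    return a


def forward_autoencoder(
    params: NetworkParams,
    spec: AutoencoderSpec,
    X_corrupt: np.ndarray,
    mode: str = "infer",
    rng=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full pass through encoder and decoder; returns (reconstruction, code).

    The caller supplies the (possibly corrupted) input; the bottleneck code is
    the activation leaving the last encoder layer.
    """
    layers = spec.layer_specs()
    cache: dict = {}
    recon = forward(params, layers, X_corrupt, mode=mode, rng=rng, cache=cache)
    k = spec.n_encoder_layers
    # activation entering decoder layer k = output of encoder layer k-1
    code = cache["inputs"][k]
    return recon, code


def encode(params: NetworkParams, spec: AutoencoderSpec, X: np.ndarray) -> np.ndarray:
    """Deterministic inference-mode encoder pass on clean input (the transfer map)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k = spec.n_encoder_layers
    enc_params = NetworkParams(params.weights[:k], params.biases[:k])
    enc_layers = [LayerSpec(w, "relu", 0.0) for w in spec.encoder_widths]
    return forward(enc_params, enc_layers, X, mode="infer")


def forward_classifier(
    params: NetworkParams,
    spec: ClassifierSpec,
    codes: np.ndarray,
    mode: str = "infer",
    rng=None,
) -> np.ndarray:
    """Class-probability matrix [n x 2]; rows sum to 1."""
    return forward(params, spec.layer_specs(), codes, mode=mode, rng=rng)


def forward_regressor(
    params: NetworkParams,
    spec: RegressorSpec,
    codes: np.ndarray,
    mode: str = "infer",
    rng=None,
) -> np.ndarray:
    """One real prediction per sample."""
    out = forward(params, spec.layer_specs(), codes, mode=mode, rng=rng)
    return out[:, 0]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def reconstruction_loss(reconstruction: np.ndarray, original: np.ndarray) -> float:
    """Mean squared error over all matrix entries; 0 iff identical."""
    reconstruction = np.asarray(reconstruction, dtype=float)
    original = np.asarray(original, dtype=float)
    if reconstruction.shape != original.shape:
        raise ValueError(f"shape mismatch: {reconstruction.shape} vs {original.shape}")
    return float(np.mean((reconstruction - original) ** 2))


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean of -log p(true class), natural log, probabilities clamped at 1e-12."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if probabilities.ndim != 2 or probabilities.shape[0] != labels.shape[0]:
        raise ValueError("probabilities and labels are misaligned")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    p_true = probabilities[np.arange(len(labels)), labels.astype(int)]
    return float(np.mean(-np.log(np.maximum(p_true, PROB_CLAMP))))


def regression_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error between prediction and target vectors."""
    predictions = np.asarray(predictions, dtype=float).ravel()
    targets = np.asarray(targets, dtype=float).ravel()
    if predictions.shape != targets.shape:
        raise ValueError(f"length mismatch: {predictions.shape} vs {targets.shape}")
    return float(np.mean((predictions - targets) ** 2))


def spec_record(spec: ModelSpec) -> dict:
    """JSON-serializable architecture record for manifests."""
    rec = asdict(spec)
    rec["kind"] = type(spec).__name__
    return rec


def spec_from_record(rec: dict) -> ModelSpec:
    rec = dict(rec)
    kind = rec.pop("kind")
    classes = {c.__name__: c for c in (AutoencoderSpec, ClassifierSpec, RegressorSpec)}
    if kind not in classes:
        raise ValueError(f"unknown architecture kind {kind!r}")
    for key in ("encoder_widths", "decoder_widths", "hidden_widths"):
        if key in rec and rec[key] is not None:
            rec[key] = tuple(rec[key])
    return classes[kind](**rec)
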