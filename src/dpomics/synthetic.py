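"""Synthetic omics-like fixtures with the structure the DP pipeline assumes.

A linear-Gaussian latent factor model generates everything, so a
low-dimensional code is provably sufficient for both downstream tasks and
pipeline utility can be measured against a known oracle:

* expression: ``X = Z W + noise`` with ``Z ~ N(0,1)`` of shape (n, k) and
  ``W ~ N(0,1)`` of shape (k, d) — an expression-like continuous matrix;
* copy-number calls: columnwise quantile thresholding of such a matrix into
  {-1 (loss), 0 (diploid), +1 (gain)};
* binary status labels: a logistic rule on the first latent factor, with the
  intercept solved so the positive fraction matches a configurable imbalance
  (default 0.8, the ~794:197 positive:negative profile of ER status cohorts);
* per-drug responses: drug-specific linear combinations of the latent factors
  plus noise, masked completely at random so only a subset of samples is
  usable per drug (IC50-style tables).

Defaults are desk-scale (1000 samples x 200 features, 10 latent factors);
cohort-scale shapes are reachable through the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters; (config, seed) fully determines every artifact."""

    n_samples: int = 1000
    n_features: int = 200
    latent_dim: int = 10
    noise_std: float = 1.0
    class_effect: float = 3.0
    class_ratio: float = 0.8
    n_drugs: int = 5
    drug_noise_std: float = 1.0
    missing_rate: float = 0.3
    cna_loss_quantile: float = 0.15
    cna_gain_quantile: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim >= self.n_features:
            raise ValueError("latent_dim must be smaller than n_features")
        if self.n_samples < 1 or self.latent_dim < 1:
            raise ValueError("sample and latent counts must be positive")
        if self.noise_std < 0 or self.drug_noise_std < 0:
            raise ValueError("noise levels must be non-negative")
        if not 0 < self.class_ratio < 1:
            raise ValueError("class_ratio must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for q in (self.cna_loss_quantile, self.cna_gain_quantile):
            if not 0 <= q < 0.5:
                raise ValueError("CNA quantiles must lie in [0, 0.5)")
        if self.cna_loss_quantile + self.cna_gain_quantile >= 1:
            raise ValueError("CNA quantiles must sum to less than 1")


@dataclass
class SyntheticBundle:
    """A generated dataset plus the latent truth needed by recovery tests."""

    X: pd.DataFrame
    Z: np.ndarray
    labels: pd.Series | None
    responses: pd.DataFrame | None
    config: SyntheticConfig

    def truth_record(self) -> dict:
        return {"config": asdict(self.config)}


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def gen_expression(config: SyntheticConfig) -> SyntheticBundle:
    """Continuous expression-like matrix from the latent factor model."""
    rng = np.random.default_rng(config.seed)
    Z = rng.normal(size=(config.n_samples, config.latent_dim))
    W = rng.normal(size=(config.latent_dim, config.n_features))
    X = Z @ W
    if config.noise_std > 0:
        X = X + rng.normal(0.0, config.noise_std, size=X.shape)
    frame = pd.DataFrame(
        X, index=_ids("s", config.n_samples), columns=_ids("g", config.n_features)
    )
    frame.index.name = "sample_id"
    return SyntheticBundle(X=frame, Z=Z, labels=None, responses=None, config=config)


def gen_cna(config: SyntheticConfig) -> pd.DataFrame:
    """Discrete copy-number calls in {-1, 0, 1} by columnwise quantile thresholding."""
    bundle = gen_expression(config)
    values = bundle.X.to_numpy()
    calls = np.zeros_like(values, dtype=int)
    if config.cna_loss_quantile > 0:
        lo = np.quantile(values, config.cna_loss_quantile, axis=0)
        calls[values < lo] = -1
    if config.cna_gain_quantile > 0:
        hi = np.quantile(values, 1.0 - config.cna_gain_quantile, axis=0)
        calls[values > hi] = 1
    return pd.DataFrame(calls, index=bundle.X.index, columns=bundle.X.columns)


def gen_labels(config: SyntheticConfig, Z: np.ndarray) -> pd.Series:
    """Imbalanced binary labels: p(y=1|z) = logistic(effect * z1 + offset).

    The offset is solved (on the realized z1) so the expected positive fraction
    equals ``class_ratio``; draws are seeded independently of the expression
    noise.
    """
    Z = np.asarray(Z)
    z1 = Z[:, 0]
    target = config.class_ratio

    def excess(offset: float) -> float:
        return float(np.mean(expit(config.class_effect * z1 + offset)) - target)

    offset = brentq(excess, -50.0, 50.0)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    y = (rng.random(len(z1)) < expit(config.class_effect * z1 + offset)).astype(int)
    return pd.Series(y, index=_ids("s", len(z1)), name="label")


def gen_drug_response(config: SyntheticConfig, Z: np.ndarray) -> pd.DataFrame:
    """Drugs-by-samples response table with completely-at-random missingness.

    Each drug's response is a fixed linear combination of the latent factors
    plus Gaussian noise; entries are masked to NA independently with
    probability ``missing_rate``.
    """
    Z = np.asarray(Z)
    n, k = Z.shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    betas = rng.normal(size=(config.n_drugs, k))
    Y = betas @ Z.T
    if config.drug_noise_std > 0:
        Y = Y + rng.normal(0.0, config.drug_noise_std, size=Y.shape)
    if config.missing_rate > 0:
        mask = rng.random(Y.shape) < config.missing_rate
        Y = np.where(mask, np.nan, Y)
    return pd.DataFrame(Y, index=_ids("d", config.n_drugs), columns=_ids("s", n))


def gen_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Expression matrix, labels and drug responses from one latent draw."""
    bundle = gen_expression(config)
    bundle.labels = gen_labels(config, bundle.Z)
    bundle.responses = gen_drug_response(config, bundle.Z)
    return bundle
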