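"""Metrics and experiment scaffolding.

Accuracy, ROC AUC (Mann-Whitney form, ties counted one half), Spearman rank
correlation, stratified k-fold assignment, generic cross-validation, and
repeated-run summaries.  The AUC deliberately uses the rank-statistic
formulation — the probability that a random positive outscores a random
negative — because it is exact, tie-aware and directly checkable against
brute-force pair enumeration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger("dpomics")


@dataclass
class MetricSummary:
    """Per-fold (or per-repeat) metric values with their mean and standard deviation.

    The sample standard deviation (ddof=1) is reported; a single value has
    std 0 by convention.
    """

    values: np.ndarray
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("MetricSummary needs at least one value")
        self.mean = float(self.values.mean())
        self.std = float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0


@dataclass
class FoldAssignment:
    """A partition of samples into k folds (fold index per sample)."""

    k: int
    fold_index: np.ndarray
    seed: int
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def accuracy(predicted_labels: Sequence, true_labels: Sequence) -> float:
    """Fraction of exact label matches."""
    predicted = np.asarray(predicted_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if predicted.shape != true.shape or predicted.size == 0:
        raise ValueError("label vectors must be non-empty and equal length")
    return float(np.mean(predicted == true))


def roc_auc(scores: Sequence[float], true_labels: Sequence) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties count 1/2."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(true_labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be equal length")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC requires both classes to be present")
    ranks = stats.rankdata(scores)  # average ranks on ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def spearman(predicted: Sequence[float], truth: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average-ranked values."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if predicted.shape != truth.shape or predicted.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(predicted) == 0 or np.ptp(truth) == 0:
        raise ValueError("rank correlation is undefined for constant input")
    rho = stats.spearmanr(predicted, truth).statistic
    return float(rho)


def stratified_kfold(labels: Sequence, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Seeded stratified partition into k folds (per-fold class ratio within +-1 sample).

    Falls back to plain (unstratified) folds with a warning when some class has
    fewer than k members.
    """
    labels = np.asarray(labels).ravel()
    n = len(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    _, counts = np.unique(labels, return_counts=True)
    stratified = bool(counts.min() >= k)
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            f"smallest class has {counts.min()} < k={k} members; using unstratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), labels)):
        fold_index[test_idx] = fold
    return FoldAssignment(k=k, fold_index=fold_index, seed=seed, stratified=stratified)


class FoldError(RuntimeError):
    """A trainer failure annotated with the fold it occurred in."""


def cross_validate(
    trainer: Callable,
    data: np.ndarray,
    targets: Sequence,
    metrics: Mapping[str, Callable[[np.ndarray, np.ndarray], float]],
    k: int = 10,
    seed: int = 0,
    stratify: bool = True,
) -> dict[str, MetricSummary]:
    """k-fold cross-validation of a trainer.

    ``trainer(train_data, train_targets, seed)`` must return a callable mapping
    held-out data to scores; each metric is called as ``metric(truth, scores)``
    on the held-out fold only.  Returns one :class:`MetricSummary` per metric.
    """
    data = np.asarray(data)
    targets = np.asarray(targets)
    if data.shape[0] != targets.shape[0]:
        raise ValueError("data and targets are misaligned")
    if stratify:
        folds = stratified_kfold(targets, k=k, seed=seed)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            folds = stratified_kfold(np.zeros(len(targets)), k=k, seed=seed)
    per_metric: dict[str, list[float]] = {name: [] for name in metrics}
    for fold in range(k):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        try:
            predict = trainer(data[tr], targets[tr], seed + fold)
            scores = np.asarray(predict(data[te]))
        except Exception as exc:  # annotate, do not swallow
            raise FoldError(f"trainer failed on fold {fold}: {exc}") from exc
        for name, fn in metrics.items():
            per_metric[name].append(float(fn(targets[te], scores)))
        logger.info(
            "event=cv_fold fold=%d %s",
            fold,
            " ".join(f"{name}={per_metric[name][-1]:.4f}" for name in metrics),
        )
    return {name: MetricSummary(vals) for name, vals in per_metric.items()}


def repeat_experiment(
    experiment: Callable[[int], float], n_repeats: int = 10, base_seed: int = 0
) -> MetricSummary:
    """Run ``experiment(seed)`` with seeds base_seed .. base_seed+n-1; summarize."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    values = [float(experiment(base_seed + i)) for i in range(n_repeats)]
    return MetricSummary(values)
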