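"""Accuracy metrics, holdout splitting, repeated k-fold CV, and tuning grids.

The protocol: 2/3 of the seeds (stratified by variety) train the model; the
remaining 1/3 is held out for a single final validation.  Model parameters
(predictors per subspace, learners in the ensemble) are chosen on the
training partition with repeated stratified 10-fold cross-validation.

Error rate and accuracy are the plain mismatch/match fractions,
``E = (1/n) sum 1[f(x_i) != y_i]`` and ``A = 1 - E``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io_formats import SeedspecError, SpectraTable
from .rsld import fit_ld, fit_rsld, predict_ld, predict_rsld

__all__ = [
    "SplitPlan",
    "CVReport",
    "error_and_accuracy",
    "make_split",
    "repeated_kfold_error",
    "tune_grid",
    "ld_trainer",
    "rsld_trainer",
]

# A trainer maps (X_train, y_train, seed) to a predict callable.
Trainer = Callable[[np.ndarray, np.ndarray, int], Callable[[np.ndarray], np.ndarray]]


def ld_trainer(shrinkage: float = 1e-4) -> Trainer:
    """Trainer factory for the plain (single) linear discriminant."""

    def train(X: np.ndarray, y: np.ndarray, seed: int) -> Callable:
        model = fit_ld(X, y, shrinkage=shrinkage)
        return lambda Xt: predict_ld(model, Xt)

    return train


def rsld_trainer(
    n_predictors: int = 30, n_learners: int = 25, shrinkage: float = 1e-4
) -> Trainer:
    """Trainer factory for the random-subspace LD ensemble."""

    def train(X: np.ndarray, y: np.ndarray, seed: int) -> Callable:
        model = fit_rsld(
            X,
            y,
            n_predictors=min(n_predictors, X.shape[1]),
            n_learners=n_learners,
            shrinkage=shrinkage,
            rng_seed=seed,
        )
        return lambda Xt: predict_rsld(model, Xt)

    return train


def error_and_accuracy(
    predicted: Sequence, truth: Sequence
) -> tuple[float, float]:
    """Error rate E (mismatch fraction) and accuracy A = 1 - E."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.ndim != 1:
        raise ValueError("predicted and truth must be 1-D of equal length")
    if len(truth) < 1:
        raise ValueError("need at least one prediction")
    E = float(np.mean(predicted != truth))
    return E, 1.0 - E


@dataclass
class SplitPlan:
    """A train/test partition of sample indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    stratified: bool
    rng_seed: int

    def __post_init__(self) -> None:
        tr = set(self.train_indices.tolist())
        te = set(self.test_indices.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")


def make_split(
    labels: Sequence,
    fraction: float = 2 / 3,
    stratified: bool = True,
    rng_seed: int = 0,
) -> SplitPlan:
    """Random train/test split; stratified keeps each class's train share
    within one sample of ``fraction``.

    Every sample lands in exactly one side; the test side is never empty.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(rng_seed)
    train: list[int] = []
    test: list[int] = []
    if stratified:
        for lab in dict.fromkeys(labels.tolist()):
            idx = np.flatnonzero(labels == lab)
            if len(idx) < 2:
                raise SeedspecError(
                    f"class {lab!r} has a single sample; cannot stratify"
                )
            idx = rng.permutation(idx)
            n_tr = int(round(fraction * len(idx)))
            n_tr = min(max(n_tr, 1), len(idx) - 1)  # both sides nonempty
            train.extend(idx[:n_tr].tolist())
            test.extend(idx[n_tr:].tolist())
    else:
        idx = rng.permutation(n)
        n_tr = min(max(int(round(fraction * n)), 1), n - 1)
        train = idx[:n_tr].tolist()
        test = idx[n_tr:].tolist()
    return SplitPlan(
        np.array(sorted(train)), np.array(sorted(test)), fraction, stratified, rng_seed
    )


@dataclass
class CVReport:
    """Result of repeated stratified k-fold cross-validation.

    ``fold_errors`` holds one error rate per fold per repeat.
    ``mean_error`` is the pooled mismatch fraction over every prediction
    made (equivalently the fold-size-weighted mean of fold error rates), so
    it equals the error recomputed from the confusion matrix exactly;
    ``mean_accuracy = 1 - mean_error``.
    """

    fold_errors: list[float]
    mean_error: float
    mean_accuracy: float
    confusion: np.ndarray  # (C, C), rows = truth, cols = predicted
    class_labels: list
    k: int
    repeats: int
    rng_seed: int

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=pd.Index(self.class_labels, name="truth"),
            columns=pd.Index(self.class_labels, name="predicted"),
        )


def repeated_kfold_error(
    table: SpectraTable,
    trainer: Trainer,
    k: int = 10,
    repeats: int = 10,
    rng_seed: int = 0,
    feature_indices: np.ndarray | None = None,
) -> CVReport:
    """Repeated stratified k-fold CV of a trainer on a spectra table.

    Each repeat reshuffles and re-partitions the samples into k stratified
    folds; every sample is predicted exactly once per repeat.  If the
    smallest class holds fewer than ``k`` samples the fold count is
    downgraded (with a warning) to stay feasible.
    """
    X = table.spectra
    if feature_indices is not None:
        X = X[:, np.asarray(feature_indices)]
    y = table.labels
    n = len(y)
    if n < k:
        raise ValueError(f"{n} samples cannot fill {k} folds")
    class_labels = table.label_set
    min_class = min(int(np.sum(y == lab)) for lab in class_labels)
    if min_class < k:
        warnings.warn(
            f"smallest class has {min_class} samples; downgrading folds "
            f"{k} -> {min_class}",
            stacklevel=2,
        )
        k = max(2, min_class)
    seeds = np.random.SeedSequence(rng_seed).generate_state(2 * repeats)
    pos = {lab: i for i, lab in enumerate(class_labels)}
    confusion = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    fold_errors: list[float] = []
    mismatches = 0
    total = 0
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(seeds[2 * rep] % (2**31))
        )
        fit_seed = int(seeds[2 * rep + 1] % (2**31))
        for tr_idx, te_idx in skf.split(X, y):
            predict = trainer(X[tr_idx], y[tr_idx], fit_seed)
            pred = np.asarray(predict(X[te_idx]))
            truth = y[te_idx]
            E, _ = error_and_accuracy(pred, truth)
            fold_errors.append(E)
            mismatches += int(np.sum(pred != truth))
            total += len(truth)
            for t, p in zip(truth, pred):
                confusion[pos[t], pos[p]] += 1
    mean_error = mismatches / total
    return CVReport(
        fold_errors=fold_errors,
        mean_error=mean_error,
        mean_accuracy=1.0 - mean_error,
        confusion=confusion,
        class_labels=class_labels,
        k=k,
        repeats=repeats,
        rng_seed=rng_seed,
    )


def tune_grid(
    table: SpectraTable,
    predictors_grid: Sequence[int],
    learners_grid: Sequence[int],
    k: int = 10,
    repeats: int = 10,
    rng_seed: int = 0,
    shrinkage: float = 1e-4,
    feature_indices: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean CV error for every (predictors, learners) pair.

    Returns a DataFrame with columns ``predictors``, ``learners``,
    ``mean_error``; deterministic given ``rng_seed``.
    """
    if len(predictors_grid) == 0 or len(learners_grid) == 0:
        raise ValueError("grids must be nonempty")
    rows = []
    for m in predictors_grid:
        for k_learners in learners_grid:
            report = repeated_kfold_error(
                table,
                rsld_trainer(m, k_learners, shrinkage),
                k=k,
                repeats=repeats,
                rng_seed=rng_seed,
                feature_indices=feature_indices,
            )
            rows.append(
                {"predictors": m, "learners": k_learners, "mean_error": report.mean_error}
            )
    return pd.DataFrame(rows)
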