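"""Linear discriminant learner and the random-subspace ensemble (RSLD).

The base learner is a linear discriminant classifier with a pooled
within-class covariance: class ``c`` scores

    delta_c(x) = x' S^-1 mu_c - 1/2 mu_c' S^-1 mu_c + log pi_c

where ``mu_c`` is the class mean, ``pi_c`` the class prior and ``S`` the
pooled covariance, optionally ridge-regularized as
``S + lambda * mean(diag(S)) * I`` so that high-dimensional fits on few
samples stay well-posed.

The ensemble draws ``k`` random feature subspaces of ``m`` predictors each
(uniformly without replacement within a learner, independently across
learners), trains one LD learner per subspace, and combines the ``k``
predicted labels by majority vote.  Ties are broken by the largest summed
posterior over the tied labels, then by label order, so prediction is fully
deterministic.  With hundreds of mutually redundant spectral bands and only
a few dozen training seeds per variety, a single full-dimensional LD fit
overfits its covariance estimate; restricting each learner to a small
random subspace regularizes the ensemble while the vote recovers accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import FormatError, SeedspecError

__all__ = [
    "LDModel",
    "RSLDModel",
    "SingularCovarianceError",
    "fit_ld",
    "predict_ld",
    "draw_subspaces",
    "fit_rsld",
    "predict_rsld",
    "save_rsld",
    "load_rsld",
]


class SingularCovarianceError(SeedspecError):
    """Pooled covariance is singular; shrinkage > 0 is required."""


@dataclass
class LDModel:
    """One fitted linear discriminant: class means, pooled covariance, priors."""

    class_labels: list
    class_means: np.ndarray  # (C, d)
    pooled_cov: np.ndarray  # (d, d), regularized
    priors: np.ndarray  # (C,)
    shrinkage: float = 0.0
    # cached Cholesky factor of pooled_cov, lazily computed
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def cholesky(self) -> np.ndarray:
        if self._chol is None:
            try:
                self._chol = np.linalg.cholesky(self.pooled_cov)
            except np.linalg.LinAlgError as exc:
                raise SingularCovarianceError(
                    "pooled covariance is not positive definite; "
                    "increase shrinkage"
                ) from exc
        return self._chol


def fit_ld(X: np.ndarray, y: np.ndarray, shrinkage: float = 1e-4) -> LDModel:
    """Fit a pooled-covariance linear discriminant.

    Parameters
    ----------
    X, y
        Training matrix (n x d) and labels (length n).  Every class needs
        at least 2 samples unless ``shrinkage > 0``, and ``n`` must exceed
        the class count.
    shrinkage
        Ridge coefficient lambda; the pooled covariance becomes
        ``S + lambda * mean(diag(S)) * I``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = X.shape
    if len(y) != n:
        raise ValueError("X and y lengths differ")
    if shrinkage < 0:
        raise ValueError("shrinkage must be >= 0")
    labels = list(dict.fromkeys(y.tolist()))  # first-appearance order
    C = len(labels)
    if n < C + 1:
        raise ValueError(f"need at least {C + 1} samples for {C} classes, got {n}")
    means = np.empty((C, d))
    priors = np.empty(C)
    scatter = np.zeros((d, d))
    for ci, lab in enumerate(labels):
        mask = y == lab
        nc = int(mask.sum())
        if nc < 2 and shrinkage == 0:
            raise SingularCovarianceError(
                f"class {lab!r} has {nc} sample(s); covariance is degenerate — "
                "use shrinkage > 0"
            )
        Xc = X[mask]
        means[ci] = Xc.mean(axis=0)
        priors[ci] = nc / n
        dev = Xc - means[ci]
        scatter += dev.T @ dev
    cov = scatter / (n - C)
    if shrinkage > 0:
        cov = cov + shrinkage * float(np.mean(np.diag(cov))) * np.eye(d)
    return LDModel(labels, means, cov, priors, shrinkage)


def _ld_scores(model: LDModel, X: np.ndarray) -> np.ndarray:
    """Discriminant scores delta_c(x) for every sample and class, (n, C)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {model.n_features}"
        )
    L = model.cholesky()
    # S^-1 mu_c via two triangular solves
    A = np.linalg.solve(L, model.class_means.T)  # (d, C)
    inv_mu = np.linalg.solve(L.T, A)  # S^-1 mu_c, (d, C)
    lin = X @ inv_mu  # (n, C)
    quad = 0.5 * np.sum(model.class_means.T * inv_mu, axis=0)  # (C,)
    return lin - quad + np.log(model.priors)


def predict_ld(
    model: LDModel, X: np.ndarray, return_posterior: bool = False
):
    """Predict labels by the largest discriminant score.

    Ties go to the earliest label in ``class_labels`` order.  With
    ``return_posterior=True`` a softmax of the scores is returned as well.
    """
    scores = _ld_scores(model, X)
    # argmax takes the first maximum -> earliest label wins ties
    idx = np.argmax(scores, axis=1)
    labels = np.array([model.class_labels[i] for i in idx])
    if not return_posterior:
        return labels
    shifted = scores - scores.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    posterior = expd / expd.sum(axis=1, keepdims=True)
    return labels, posterior


# ---------------------------------------------------------------------------
# Random-subspace ensemble
# ---------------------------------------------------------------------------

def draw_subspaces(
    feature_count: int, n_predictors: int, n_learners: int, rng_seed: int
) -> list[np.ndarray]:
    """Draw ``n_learners`` feature subsets of size ``n_predictors``.

    Each subset is sampled uniformly without replacement from the feature
    indices; draws are independent across learners (the same subspace may
    recur).  Fully reproducible given ``rng_seed``.
    """
    if not 1 <= n_predictors <= feature_count:
        raise ValueError(
            f"n_predictors must be in [1, {feature_count}], got {n_predictors}"
        )
    rng = np.random.default_rng(rng_seed)
    return [
        np.sort(rng.choice(feature_count, size=n_predictors, replace=False))
        for _ in range(n_learners)
    ]


@dataclass
class RSLDModel:
    """Random-subspace LD ensemble: (subspace, learner) pairs plus the vote."""

    learners: list[tuple[np.ndarray, LDModel]]
    n_predictors: int
    n_learners: int
    rng_seed: int
    class_labels: list

    def __post_init__(self) -> None:
        if len(self.learners) != self.n_learners:
            raise ValueError("learner count disagrees with n_learners")
        for sub, _ in self.learners:
            if len(np.unique(sub)) != self.n_predictors:
                raise ValueError("every subspace must hold n_predictors distinct indices")


def fit_rsld(
    X: np.ndarray,
    y: np.ndarray,
    n_predictors: int = 30,
    n_learners: int = 25,
    shrinkage: float = 1e-4,
    rng_seed: int = 0,
) -> RSLDModel:
    """Train the random-subspace LD ensemble.

    Defaults follow the operating point where cross-validated error levels
    off for seed-variety spectra: 30 predictors per learner, 25 learners.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subspaces = draw_subspaces(X.shape[1], n_predictors, n_learners, rng_seed)
    learners: list[tuple[np.ndarray, LDModel]] = []
    for i, sub in enumerate(subspaces):
        try:
            model = fit_ld(X[:, sub], y, shrinkage=shrinkage)
        except SeedspecError as exc:
            raise type(exc)(f"learner {i}: {exc}") from exc
        learners.append((sub, model))
    labels = list(dict.fromkeys(y.tolist()))
    return RSLDModel(learners, n_predictors, n_learners, rng_seed, labels)


def predict_rsld(model: RSLDModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over the ensemble's per-learner predictions.

    A tied vote is resolved by the largest sum of per-learner posteriors
    over the tied labels; any remaining tie by earliest label order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    C = len(model.class_labels)
    label_pos = {lab: i for i, lab in enumerate(model.class_labels)}
    votes = np.zeros((n, C), dtype=int)
    post_sum = np.zeros((n, C), dtype=float)
    for sub, ld in model.learners:
        if sub.max() >= X.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} features but a subspace references "
                f"feature {int(sub.max())}"
            )
        pred, post = predict_ld(ld, X[:, sub], return_posterior=True)
        for j, lab in enumerate(ld.class_labels):
            post_sum[:, label_pos[lab]] += post[:, j]
        for i, lab in enumerate(pred):
            votes[i, label_pos[lab]] += 1
    out = np.empty(n, dtype=object)
    for i in range(n):
        top = votes[i].max()
        tied = np.flatnonzero(votes[i] == top)
        if len(tied) > 1:
            best = tied[np.argmax(post_sum[i, tied])]  # argmax -> earliest on tie
        else:
            best = tied[0]
        out[i] = model.class_labels[best]
    return np.array(out.tolist())


# ---------------------------------------------------------------------------
# Serialization (portable structured text)
# ---------------------------------------------------------------------------

def save_rsld(model: RSLDModel, path: str | Path) -> None:
    """Write the ensemble to a JSON text file, losslessly (float repr)."""
    doc = {
        "format": "seedspec-rsld",
        "version": 1,
        "n_predictors": model.n_predictors,
        "n_learners": model.n_learners,
        "rng_seed": model.rng_seed,
        "class_labels": [str(l) for l in model.class_labels],
        "learners": [
            {
                "subspace_bands_1based": (sub + 1).tolist(),
                "class_labels": [str(l) for l in ld.class_labels],
                "class_means": ld.class_means.tolist(),
                "pooled_cov": ld.pooled_cov.tolist(),
                "priors": ld.priors.tolist(),
                "shrinkage": ld.shrinkage,
            }
            for sub, ld in model.learners
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_rsld(path: str | Path) -> RSLDModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "seedspec-rsld":
        raise FormatError(f"not a seedspec RSLD model file: {path}")
    learners = []
    for rec in doc["learners"]:
        ld = LDModel(
            class_labels=list(rec["class_labels"]),
            class_means=np.array(rec["class_means"], dtype=float),
            pooled_cov=np.array(rec["pooled_cov"], dtype=float),
            priors=np.array(rec["priors"], dtype=float),
            shrinkage=float(rec["shrinkage"]),
        )
        sub = np.array(rec["subspace_bands_1based"], dtype=int) - 1
        learners.append((sub, ld))
    return RSLDModel(
        learners=learners,
        n_predictors=int(doc["n_predictors"]),
        n_learners=int(doc["n_learners"]),
        rng_seed=int(doc["rng_seed"]),
        class_labels=list(doc["class_labels"]),
    )
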