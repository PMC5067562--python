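"""Cross-cohort multi-class classification of subgroup membership.

Subgroups identified independently in two cohorts are matched by rank order
of mean total score ("homologous" labels). A boosted ensemble is trained on
one cohort's item responses and rank labels and evaluated on the other; the
observed accuracy is compared against a null distribution obtained by
refitting the whole model under randomly permuted training labels.

The booster is AdaBoost.M2: it maintains a weight distribution over
(example, incorrect-label) pairs, fits a weak learner per round, and scores a
round by its *pseudo-loss*

    eps_t = 1/2 * sum_{i, y != y_i} D_t(i, y) * (1 - h_t(x_i, y_i) + h_t(x_i, y))

where h_t(x, y) in [0, 1] is the learner's plausibility for class y. With
beta_t = eps_t / (1 - eps_t), the weights update as

    D_{t+1}(i, y) = D_t(i, y) * beta_t ** (1/2 * (1 + h_t(x_i, y_i) - h_t(x_i, y)))

(renormalized), and the final score of class y is sum_t ln(1/beta_t) h_t(x, y).

The weak learner is a weighted linear discriminant with pooled covariance
plus a small ridge (binary item features make the pooled covariance
singular); its plausibilities are the normalized class posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ValidationError

_BETA_FLOOR = 1e-10
_EPS_CEIL = 0.5 - 1e-7


@dataclass
class _DiscriminantLearner:
    """Weighted LDA with ridge-regularized pooled covariance."""

    classes: np.ndarray
    coef: np.ndarray  # (C, d)
    intercept: np.ndarray  # (C,)

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, w: np.ndarray, classes: np.ndarray,
            ridge_scale: float = 1e-3) -> "_DiscriminantLearner":
        n, d = X.shape
        w = w / w.sum()
        means = np.empty((len(classes), d))
        priors = np.empty(len(classes))
        cov = np.zeros((d, d))
        for c, label in enumerate(classes):
            mask = y == label
            wc = w[mask]
            total = wc.sum()
            priors[c] = total
            if total <= 0:
                # class absent under this weighting: neutral mean
                means[c] = (w[:, None] * X).sum(axis=0)
                continue
            means[c] = (wc[:, None] * X[mask]).sum(axis=0) / total
            xc = X[mask] - means[c]
            cov += (wc[:, None] * xc).T @ xc
        ridge = ridge_scale * (np.trace(cov) / d if np.trace(cov) > 0 else 1.0)
        cov += ridge * np.eye(d)
        priors = np.clip(priors, 1e-12, None)
        priors /= priors.sum()
        inv = np.linalg.inv(cov)
        coef = means @ inv
        intercept = -0.5 * np.einsum("cd,cd->c", coef, means) + np.log(priors)
        return cls(classes=classes, coef=coef, intercept=intercept)

    def plausibilities(self, X: np.ndarray) -> np.ndarray:
        """Class posteriors in [0, 1], one row per example."""
        scores = X @ self.coef.T + self.intercept
        scores -= scores.max(axis=1, keepdims=True)
        expd = np.exp(scores)
        return expd / expd.sum(axis=1, keepdims=True)


@dataclass
class BoostedEnsemble:
    """AdaBoost.M2 ensemble of discriminant weak learners."""

    classes: np.ndarray
    learners: list[_DiscriminantLearner]
    betas: list[float]
    item_ids: tuple[str, ...] | None
    rounds: int
    seed: int | None = None
    degenerate: bool = False  # single-class training labels
    pseudo_losses: list[float] = field(default_factory=list)

    @property
    def learner_weights(self) -> np.ndarray:
        return np.log(1.0 / np.asarray(self.betas))

    def class_scores(self, X: np.ndarray) -> np.ndarray:
        if self.degenerate:
            scores = np.zeros((len(X), len(self.classes)))
            scores[:, 0] = 1.0
            return scores
        total = np.zeros((len(X), len(self.classes)))
        for learner, beta in zip(self.learners, self.betas):
            total += np.log(1.0 / beta) * learner.plausibilities(X)
        return total


def train_adaboost_m2(
    features: np.ndarray,
    labels: np.ndarray,
    rounds: int = 20,
    seed: int | None = None,
    item_ids=None,
) -> BoostedEnsemble:
    """Train an AdaBoost.M2 ensemble on item responses and subgroup labels.

    Boosting stops early when the pseudo-loss reaches 0 (perfect round) or
    0.5 (no better than random plausibilities); beta is floored by a small
    constant so learner weights stay finite. Training is deterministic; the
    seed is recorded for provenance.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, d) aligned with labels")
    if len(X) == 0:
        raise ValueError("empty feature matrix")
    classes = np.unique(y)
    item_ids = tuple(item_ids) if item_ids is not None else None
    if len(classes) < 2:
        return BoostedEnsemble(
            classes=classes, learners=[], betas=[], item_ids=item_ids,
            rounds=rounds, seed=seed, degenerate=True,
        )
    n, c = len(X), len(classes)
    class_index = {label: i for i, label in enumerate(classes)}
    yi = np.array([class_index[v] for v in y])

    # D over (example, incorrect label) pairs; D[i, y_i] fixed at 0
    D = np.full((n, c), 1.0 / (n * (c - 1)))
    D[np.arange(n), yi] = 0.0

    learners: list[_DiscriminantLearner] = []
    betas: list[float] = []
    losses: list[float] = []
    for _ in range(rounds):
        w = D.sum(axis=1)
        learner = _DiscriminantLearner.fit(X, y, w, classes)
        h = learner.plausibilities(X)
        h_true = h[np.arange(n), yi]
        eps = 0.5 * float((D * (1.0 - h_true[:, None] + h)).sum())
        if eps >= 0.5 and learners:
            break
        eps_c = float(np.clip(eps, _BETA_FLOOR, _EPS_CEIL))
        beta = eps_c / (1.0 - eps_c)
        learners.append(learner)
        betas.append(beta)
        losses.append(eps)
        if eps <= _BETA_FLOOR or eps >= 0.5:
            break
        exponent = 0.5 * (1.0 + h_true[:, None] - h)
        D = D * beta ** exponent
        D[np.arange(n), yi] = 0.0
        D /= D.sum()
    return BoostedEnsemble(
        classes=classes, learners=learners, betas=betas, item_ids=item_ids,
        rounds=rounds, seed=seed, pseudo_losses=losses,
    )


def predict_subgroups(model: BoostedEnsemble, features, item_ids=None) -> np.ndarray:
    """Predict labels by argmax of ensemble class scores (lowest index on ties)."""
    X = np.asarray(features, dtype=float)
    if model.item_ids is not None and item_ids is not None:
        if tuple(item_ids) != model.item_ids:
            raise ValidationError("feature item IDs do not match training")
    if model.item_ids is not None and X.shape[1] != len(model.item_ids):
        raise ValidationError("feature dimension does not match training")
    scores = model.class_scores(X)
    return model.classes[np.argmax(scores, axis=1)]


def evaluate_predictions(
    truth,
    predicted,
    class_labels=None,
    merges: list[list[set]] | None = None,
) -> dict:
    """Accuracy, confusion counts (rows = actual) and merged-group accuracies.

    Each merge spec is a list of disjoint label sets (e.g. ``[{1, 2},
    {3, 4, 5}]``); both vectors are mapped through the merge before the
    coarse accuracy is computed, so correct fine predictions stay correct.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predictions must be aligned")
    if class_labels is None:
        class_labels = np.unique(np.concatenate([truth, predicted]))
    class_labels = np.asarray(class_labels)
    known = set(class_labels.tolist())
    for v in np.concatenate([truth, predicted]):
        if v not in known:
            raise ValidationError(f"label {v!r} outside the declared class set")
    index = {label: i for i, label in enumerate(class_labels)}
    k = len(class_labels)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predicted):
        confusion[index[t], index[p]] += 1
    accuracy = float((truth == predicted).mean())
    merged = []
    for spec in merges or []:
        mapping = {}
        for gi, group in enumerate(spec):
            for label in group:
                mapping[label] = gi
        mt = np.array([mapping[v] for v in truth])
        mp = np.array([mapping[v] for v in predicted])
        merged.append(
            {"merge": [sorted(g) for g in spec], "accuracy": float((mt == mp).mean())}
        )
    return {
        "accuracy": accuracy,
        "confusion": confusion,
        "class_labels": class_labels,
        "merged": merged,
    }


@dataclass(frozen=True)
class PermutationResult:
    """Observed accuracy against a label-permutation null distribution."""

    observed_accuracy: float
    null_accuracies: np.ndarray
    n_permutations: int
    p_value: float  # add-one estimator, never exactly 0
    p_raw: float  # plain proportion of null >= observed
    seed: int

    def __post_init__(self) -> None:
        if len(self.null_accuracies) != self.n_permutations:
            raise ValueError("null vector length must equal permutation count")


def permutation_null_test(
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    rounds: int = 20,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of cross-cohort accuracy.

    The ensemble is refit from scratch for every permutation of the training
    labels (not merely rescored), and the test accuracy recorded. The
    reported p-value is the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_perm)``; the raw proportion is also
    kept. The permutation stream is fully determined by ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xtr, ytr = np.asarray(train[0], float), np.asarray(train[1])
    Xte, yte = np.asarray(test[0], float), np.asarray(test[1])
    model = train_adaboost_m2(Xtr, ytr, rounds=rounds, seed=seed)
    observed = float((predict_subgroups(model, Xte) == yte).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(ytr)
        pm = train_adaboost_m2(Xtr, perm, rounds=rounds)
        null[b] = float((predict_subgroups(pm, Xte) == yte).mean())
    k = int((null >= observed).sum())
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=null,
        n_permutations=n_perm,
        p_value=(k + 1) / (n_perm + 1),
        p_raw=k / n_perm,
        seed=seed,
    )
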