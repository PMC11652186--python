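"""Confident learning and co-teaching for the three-class refinement.

The chart-assigned three-class labels still contain mistakes. The final
stage treats them as noisy labels and (1) estimates the joint
distribution of observed and true labels from cross-validated predicted
probabilities via per-class confidence thresholds, (2) prunes the
samples counted off-diagonal (likely mislabeled), (3) reweights classes
by inverse retained frequency, and (4) trains two peer networks by
co-teaching: each epoch every model selects its small-loss (likely
clean) fraction and the *peer* updates on that selection, which keeps a
single model from confirming its own label errors. Final predictions
average the two models' class probabilities (ties break to the lowest
class index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import ClassifierConfig, TinyNet, keep_rate

__all__ = [
    "ConfidentJoint",
    "CoTeachModels",
    "estimate_confident_joint",
    "cross_val_probs",
    "prune_and_reweight",
    "coteach_train",
    "predict_final",
]


@dataclass
class ConfidentJoint:
    """Confident-joint counts: rows = observed label, columns =
    confidently predicted label; plus per-class thresholds and the
    per-sample assignments used for pruning."""

    counts: np.ndarray  # (k, k)
    thresholds: np.ndarray  # (k,)
    assigned_idx: np.ndarray  # indices of samples counted in the joint
    assigned_pred: np.ndarray  # their confident predicted class

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def noise_estimate(self) -> float:
        """Fraction of confidently assigned samples counted off-diagonal."""
        total = self.counts.sum()
        if total == 0:
            return 0.0
        return float((total - np.trace(self.counts)) / total)


def estimate_confident_joint(
    probs: np.ndarray,
    labels: np.ndarray,
    n_classes: int | None = None,
) -> ConfidentJoint:
    """Count samples into (observed, confidently predicted) cells.

    The class-j threshold t_j is the mean predicted probability of class
    j among samples observed as j (its self-confidence). A sample is
    assigned to the class of highest probability among classes whose
    probability reaches their threshold; samples reaching none are
    omitted from the joint.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.ndim != 2 or probs.shape[0] != labels.size:
        raise ValueError("probs must be n x k aligned with labels")
    if not np.isfinite(probs).all():
        raise ValueError("predicted probabilities contain NaN/inf")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of probs must sum to 1")
    k = n_classes or probs.shape[1]

    thresholds = np.full(k, np.inf)
    for j in range(k):
        mask = labels == j
        if mask.any():
            thresholds[j] = probs[mask, j].mean()

    # small slack guards against float accumulation in the class means
    eligible = probs >= thresholds - 1e-9  # broadcast over rows
    masked = np.where(eligible, probs, -np.inf)
    has_any = eligible.any(axis=1)
    pred = masked.argmax(axis=1)

    counts = np.zeros((k, k), dtype=np.int64)
    idx = np.flatnonzero(has_any)
    np.add.at(counts, (labels[idx], pred[idx]), 1)
    return ConfidentJoint(counts=counts, thresholds=thresholds,
                          assigned_idx=idx, assigned_pred=pred[idx])


def cross_val_probs(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    config: ClassifierConfig | None = None,
    n_folds: int = 5,
    seed: int | None = None,
) -> np.ndarray:
    """Out-of-fold predicted probabilities from the compact softmax
    network, so the confident joint is not estimated from
    self-confirmed in-sample fits."""
    config = config or ClassifierConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, n_folds)
    probs = np.full((len(y), n_classes), np.nan)
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        net = _fit_softmax(X[train_idx], y[train_idx], n_classes, config,
                           seed=int(rng.integers(2**31)))
        mu, sd = X[train_idx].mean(0), X[train_idx].std(0)
        sd = np.where(sd > 0, sd, 1.0)
        probs[test_idx] = net.predict_proba((X[test_idx] - mu) / sd)
    return probs


def _fit_softmax(X: np.ndarray, y: np.ndarray, n_classes: int,
                 config: ClassifierConfig, seed: int,
                 sample_weight: np.ndarray | None = None) -> TinyNet:
    mu, sd = X.mean(0), X.std(0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    net = TinyNet(Z.shape[1], n_out=n_classes, hidden=config.hidden,
                  lr=config.learning_rate, weight_decay=config.weight_decay,
                  seed=seed)
    rng = np.random.default_rng(seed)
    for _ in range(config.epochs):
        order = rng.permutation(len(Z))
        for lo in range(0, len(Z), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            w = None if sample_weight is None else sample_weight[idx]
            net.step(Z[idx], y[idx], sample_weight=w)
    return net


def prune_and_reweight(
    X: np.ndarray,
    labels: np.ndarray,
    joint: ConfidentJoint,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop samples the joint counts off-diagonal and compute class
    weights proportional to inverse retained class frequency
    (normalized to mean 1 over classes).

    Returns ``(keep_mask, class_weights)``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    keep = np.ones(labels.size, dtype=bool)
    off = joint.assigned_idx[joint.assigned_pred != labels[joint.assigned_idx]]
    keep[off] = False

    k = joint.n_classes
    counts = np.bincount(labels[keep], minlength=k)
    if np.any(counts[np.unique(labels)] == 0):
        raise ValueError("pruning would remove an entire class")
    with np.errstate(divide="ignore"):
        w = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    nz = w > 0
    w[nz] = w[nz] / w[nz].mean()
    return keep, w


@dataclass
class CoTeachModels:
    """Two peer-trained softmax networks with averaged predictions."""

    model_a: TinyNet
    model_b: TinyNet
    x_mean: np.ndarray
    x_scale: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(np.asarray(X, float)) - self.x_mean) / self.x_scale
        return 0.5 * (self.model_a.predict_proba(Z) + self.model_b.predict_proba(Z))


def coteach_train(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig | None = None,
    seed: int | None = None,
    class_weights: np.ndarray | None = None,
    noise_estimate: float | None = None,
    n_classes: int = 3,
) -> CoTeachModels:
    """Co-teaching on the (pruned) three-class data.

    Each epoch, each model ranks its per-sample losses and keeps the
    ``keep_rate`` smallest; the *peer* takes its Adam step on that
    subset. During warm-up the keep rate is 1.
    """
    config = config or ClassifierConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=np.int64)
    present = np.unique(y)
    if present.size < 2:
        raise ValueError("co-teaching needs more than one class present")
    noise = config.assumed_noise if noise_estimate is None else noise_estimate

    rng = np.random.default_rng(seed)
    mu, sd = X.mean(0), X.std(0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    sw = None
    if class_weights is not None:
        sw = np.asarray(class_weights, float)[y]

    nets = [
        TinyNet(Z.shape[1], n_out=n_classes, hidden=config.hidden,
                lr=config.learning_rate, weight_decay=config.weight_decay,
                seed=int(rng.integers(2**31)))
        for _ in range(2)
    ]
    n = len(Z)
    for epoch in range(config.epochs):
        r = keep_rate(epoch, config.warmup_epochs, noise)
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            selections = []
            for net in nets:
                losses = net.per_sample_loss(Z[idx], y[idx])
                k = max(int(np.ceil(r * idx.size)), 2)
                selections.append(idx[np.argsort(losses, kind="stable")[:k]])
            # each model updates on its peer's small-loss selection
            for net, sel in zip(nets, reversed(selections)):
                net.step(Z[sel], y[sel],
                         sample_weight=None if sw is None else sw[sel])

    return CoTeachModels(model_a=nets[0], model_b=nets[1], x_mean=mu, x_scale=sd)


def predict_final(models: CoTeachModels, X: np.ndarray) -> np.ndarray:
    """Averaged-probability argmax of the two peers; ties break to the
    lowest class index."""
    return models.predict_proba(X).argmax(axis=1).astype(np.int64)
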