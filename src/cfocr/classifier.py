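"""Noise-tolerant classifiers producing the probability pC.

The sensitized chart consumes a single number per query sample: the
probability pC = sigmoid(theta) that the sample is open chromatin,
where theta is the raw score of the model's linear output unit. The
classifier behind it is a contract — anything exposing ``train`` and
``prob`` semantics can back the chart — and this module provides a
compact, fully deterministic implementation: a linear (logistic) model
or a one-hidden-layer network trained with Adam.

Noise tolerance comes from small-loss sample selection: label noise is
learned late, so after a warm-up phase each epoch keeps only the
fraction of samples with the smallest current loss, ramping the keep
rate down to ``1 - min(assumed_noise, 0.3)``. The same schedule drives
the three-class co-teaching models in :mod:`cfocr.confident`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassifierConfig",
    "ProbOutput",
    "TinyNet",
    "NoiseTolerantClassifier",
    "train_classifier",
    "prob_classifier",
    "keep_rate",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Training hyper-parameters.

    Defaults follow standard noise-tolerant training practice for this
    problem (Adam, lr 1e-4, batch 128, 150 epochs with a 10-epoch
    warm-up, metrics averaged over 5 seeds); the compact linear model
    used by the fast pipeline overrides the learning rate upward.
    """

    hidden: int = 0  # 0 = logistic regression; >0 = one hidden tanh layer
    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 150
    warmup_epochs: int = 10
    n_seeds: int = 5
    weight_decay: float = 1e-3
    assumed_noise: float = 0.2
    small_loss: bool = True
    feature_kind: str = "extended"

    def __post_init__(self) -> None:
        if not self.epochs >= self.warmup_epochs >= 0:
            raise ValueError("need epochs >= warmup_epochs >= 0")
        if not 0.0 <= self.assumed_noise < 0.5:
            raise ValueError("assumed_noise must lie in [0, 0.5)")


@dataclass(frozen=True)
class ProbOutput:
    """Raw linear-unit score and its sigmoid probability."""

    theta: float
    pc: float


def keep_rate(epoch: int, warmup: int, noise: float, ramp: int = 10) -> float:
    """Small-loss keep-rate schedule: 1 during warm-up, then ramping
    linearly down to ``1 - min(noise, 0.3)`` over ``ramp`` epochs."""
    if epoch < warmup:
        return 1.0
    return 1.0 - min(noise, 0.3) * min(1.0, (epoch - warmup + 1) / ramp)


class TinyNet:
    """Minimal feed-forward network (0 or 1 tanh hidden layer) with an
    Adam optimizer, per-sample losses, and deterministic seeding.

    ``n_out=1`` gives a sigmoid binary head whose pre-activation is
    theta; ``n_out>1`` a softmax head.
    """

    def __init__(self, n_in: int, n_out: int = 1, hidden: int = 0,
                 lr: float = 1e-2, weight_decay: float = 0.0,
                 seed: int | None = None) -> None:
        rng = np.random.default_rng(seed)
        self.hidden = hidden
        self.lr = lr
        self.weight_decay = weight_decay
        dims = [n_in, hidden, n_out] if hidden else [n_in, n_out]
        self.W = [rng.normal(0.0, 1.0 / np.sqrt(a), size=(a, b))
                  for a, b in zip(dims[:-1], dims[1:])]
        self.b = [np.zeros(b) for b in dims[1:]]
        self._m = [np.zeros_like(w) for w in self.W + self.b]
        self._v = [np.zeros_like(w) for w in self.W + self.b]
        self._t = 0

    # -- forward ---------------------------------------------------------
    def scores(self, X: np.ndarray) -> np.ndarray:
        """Pre-activation outputs (theta for the binary head)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.W[0].shape[0]:
            raise ValueError("feature dimension mismatch")
        if self.hidden:
            h = np.tanh(X @ self.W[0] + self.b[0])
            return h @ self.W[1] + self.b[1]
        return X @ self.W[0] + self.b[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = self.scores(X)
        if s.shape[1] == 1:
            p1 = 1.0 / (1.0 + np.exp(-s[:, 0]))
            return np.stack([1.0 - p1, p1], axis=1)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def per_sample_loss(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return -np.log(np.clip(p[np.arange(len(p)), y], 1e-12, None))

    # -- backward --------------------------------------------------------
    def _grads(self, X: np.ndarray, y: np.ndarray,
               sample_weight: np.ndarray | None) -> list[np.ndarray]:
        X = np.atleast_2d(X)
        n = len(X)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        w = w / w.sum()
        p = self.predict_proba(X)
        n_out = self.W[-1].shape[1]
        if n_out == 1:
            delta = (p[:, 1] - (y == 1)).reshape(-1, 1)
        else:
            delta = p.copy()
            delta[np.arange(n), y] -= 1.0
        delta = delta * w[:, None]
        if self.hidden:
            h = np.tanh(X @ self.W[0] + self.b[0])
            gW1 = h.T @ delta + self.weight_decay * self.W[1]
            gb1 = delta.sum(axis=0)
            dh = (delta @ self.W[1].T) * (1.0 - h * h)
            gW0 = X.T @ dh + self.weight_decay * self.W[0]
            gb0 = dh.sum(axis=0)
            return [gW0, gW1, gb0, gb1]
        gW = X.T @ delta + self.weight_decay * self.W[0]
        gb = delta.sum(axis=0)
        return [gW, gb]

    def step(self, X: np.ndarray, y: np.ndarray,
             sample_weight: np.ndarray | None = None) -> None:
        """One Adam update on the given (sub)batch."""
        grads = self._grads(X, y, sample_weight)
        params = self.W + self.b
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (prm, g) in enumerate(zip(params, grads)):
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mh = self._m[i] / (1 - b1 ** self._t)
            vh = self._v[i] / (1 - b2 ** self._t)
            prm -= self.lr * mh / (np.sqrt(vh) + eps)


@dataclass
class NoiseTolerantClassifier:
    """Trained binary classifier exposing the pC probability contract."""

    net: TinyNet
    x_mean: np.ndarray
    x_scale: np.ndarray
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) / self.x_scale

    def theta(self, X: np.ndarray) -> np.ndarray:
        return self.net.scores(self._standardize(X))[:, 0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._standardize(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(np.int64)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig | None = None,
    seed: int | None = None,
) -> NoiseTolerantClassifier:
    """Train the binary pC model with minibatch Adam and (optionally)
    small-loss sample selection after the warm-up epochs. Deterministic
    given ``seed``."""
    config = config or ClassifierConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=np.int64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present in the training data")
    if not np.isin(classes, [0, 1]).all():
        raise ValueError("binary labels must be 0/1")

    rng = np.random.default_rng(seed)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=0)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    Z = (X - x_mean) / x_scale

    net = TinyNet(Z.shape[1], n_out=1, hidden=config.hidden,
                  lr=config.learning_rate, weight_decay=config.weight_decay,
                  seed=int(rng.integers(2**31)))
    n = len(Z)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        if config.small_loss:
            r = keep_rate(epoch, config.warmup_epochs, config.assumed_noise)
        else:
            r = 1.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            if r < 1.0:
                losses = net.per_sample_loss(Z[idx], y[idx])
                k = max(int(np.ceil(r * idx.size)), 2)
                idx = idx[np.argsort(losses, kind="stable")[:k]]
            net.step(Z[idx], y[idx])

    return NoiseTolerantClassifier(net=net, x_mean=x_mean, x_scale=x_scale,
                                   config=config)


def prob_classifier(model: NoiseTolerantClassifier, x: np.ndarray) -> ProbOutput:
    """pC for one query sample: theta from the linear output unit and
    pc = sigmoid(theta)."""
    theta = float(model.theta(np.atleast_2d(x))[0])
    return ProbOutput(theta=theta, pc=float(1.0 / (1.0 + np.exp(-theta))))
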