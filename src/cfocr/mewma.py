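"""Multivariate EWMA chart and its bootstrap probability transform.

The second-stage chart monitors the per-sample summary vector (sd of
windowed WPS, sd of windowed coverage) with the MEWMA recursion

    Z_i = lam * (X_i - mu) + (1 - lam) * Z_{i-1},     Z_0 = 0,
    T²_i = Z_i' S_Z^{-1} Z_i,   S_Z = lam / (2 - lam) * S,

where mu and S are the in-control (closed chromatin) mean and
covariance. The raw T² is mapped to an open-state probability through a
sigmoid anchored at a bootstrap control value BD — the mean over B
bootstrap resamples of the (1 - alpha) quantile of in-control T²:

    pT²(x) = sigmoid((T² - BD) / BD),

so pT² = 0.5 exactly at the control value and increases with T².

Each query sample is monitored independently by default (a single
recursion step from Z_0 = 0, i.e. Z = lam * (x - mu)); a sequence mode
over ordered windows is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["MEWMAModel", "fit_mewma", "mewma_t2", "bootstrap_bd", "prob_t2"]


@dataclass
class MEWMAModel:
    lam: float
    mu: np.ndarray
    S: np.ndarray
    bd: float | None = None
    alpha: float = 0.05
    B: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must lie in (0, 1]")
        self.mu = np.asarray(self.mu, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if np.linalg.eigvalsh(self.SZ).min() <= 0:
            raise ValueError("S_Z must be positive definite")

    @property
    def p(self) -> int:
        return self.mu.size

    @property
    def SZ(self) -> np.ndarray:
        return self.lam / (2.0 - self.lam) * self.S


def fit_mewma(ic_X: np.ndarray, lam: float = 0.2, alpha: float = 0.05,
              B: int = 1000) -> MEWMAModel:
    """Estimate the in-control mean and covariance from IC observations."""
    ic_X = np.asarray(ic_X, dtype=float)
    if ic_X.ndim != 2 or ic_X.shape[0] <= ic_X.shape[1]:
        raise ValueError("need an n x p IC matrix with n > p")
    return MEWMAModel(lam=lam, mu=ic_X.mean(axis=0),
                      S=np.cov(ic_X, rowvar=False, ddof=1), alpha=alpha, B=B)


def mewma_t2(
    x_seq: np.ndarray,
    model: MEWMAModel,
    sequence: bool = False,
) -> np.ndarray:
    """MEWMA T² statistics for query observations.

    ``sequence=False`` (default) treats each row as an independent query
    sample: one recursion step from Z_0 = 0. ``sequence=True`` runs the
    full recursion along the rows in order.
    """
    X = np.atleast_2d(np.asarray(x_seq, dtype=float))
    if X.shape[1] != model.p:
        raise ValueError("dimension mismatch with the fitted model")
    D = X - model.mu
    cf = cho_factor(model.SZ)
    if not sequence:
        Z = model.lam * D
        return np.einsum("ij,ij->i", Z, cho_solve(cf, Z.T).T)
    t2 = np.empty(X.shape[0])
    z = np.zeros(model.p)
    for i, d in enumerate(D):
        z = model.lam * d + (1.0 - model.lam) * z
        t2[i] = z @ cho_solve(cf, z)
    return t2


def bootstrap_bd(
    ic_t2: np.ndarray,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap control value BD: the mean over B resamples of the
    empirical 100(1 - alpha)-th percentile of in-control T² values."""
    ic_t2 = np.asarray(ic_t2, dtype=float).ravel()
    if ic_t2.size < 50:
        raise ValueError("need at least 50 in-control statistics")
    if B < 1:
        raise ValueError("B must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ic_t2.size, size=(B, ic_t2.size))
    return float(np.quantile(ic_t2[idx], 1.0 - alpha, axis=1).mean())


def prob_t2(t2: float | np.ndarray, bd: float) -> float | np.ndarray:
    """Open-state probability from the chart: sigmoid((T² - BD) / BD)."""
    if bd <= 0:
        raise ValueError("BD must be positive")
    z = (np.asarray(t2, dtype=float) - bd) / bd
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if np.isscalar(t2) else out
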