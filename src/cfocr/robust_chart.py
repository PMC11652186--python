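"""Robust Hotelling T² control chart with MRCD scatter and run rules.

The first stage of the classifier treats the windows x 4 feature matrix
of a monitored genome segment as multivariate process observations:
closed chromatin is the in-control state, open chromatin the
out-of-control state. Because the monitored data themselves contain open
windows (outliers), the in-control location and scatter are estimated
with the minimum regularized covariance determinant (MRCD): the
h-subset of observations whose regularized covariance has minimal
determinant, found by C-step descent from several deterministic starts
after median/Qn standardization, with an identity target matrix and a
regularization weight rho chosen as the smallest grid value keeping the
condition number bounded.

The T² control limit comes from a Monte-Carlo moment-matched scaled-F
distribution: out-of-sample T² values from clean Gaussian replicates are
pooled and their mean m and variance v are matched to

    E[T²]   = d q / (q - 2)
    Var[T²] = 2 d² q² (p + q - 2) / (p (q - 4) (q - 2)²),

the moments of ``d * F(p, q)``; the upper control limit is
``UCL = d_hat * F_{1-alpha}(p, q_hat)``.

Three run rules upgrade single-window alarms to open-region calls:
(1) three or more consecutive exceedances; (2) an exceedance at the
first or last window of a segment, called as a three-window (600 bp at
the default width) boundary region; (3) two exceedance runs separated by
fewer than three in-control windows are merged into one call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from statsmodels.robust.scale import qn_scale

__all__ = [
    "MRCDModel",
    "ChartCalibration",
    "RunRuleCall",
    "fit_mrcd",
    "fit_classical",
    "t2_statistic",
    "calibrate_limits",
    "apply_run_rules",
    "filter_training_set",
]

#: rho grid searched for the smallest regularization keeping cond <= COND_MAX
RHO_GRID = (0.0, 0.001, 0.005, 0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
            0.6, 0.7, 0.8, 0.9, 1.0)
COND_MAX = 50.0
N_STARTS = 6
MAX_CSTEPS = 60


@dataclass
class MRCDModel:
    """Robust location/scatter estimate backing the T² statistic."""

    location: np.ndarray
    scatter: np.ndarray
    rho: float
    h: int
    p: int
    n: int
    support: np.ndarray = field(default=None, repr=False)  # h-subset indices

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.scatter = np.asarray(self.scatter, dtype=float)
        if not np.allclose(self.scatter, self.scatter.T):
            raise ValueError("scatter must be symmetric")
        if np.linalg.eigvalsh(self.scatter).min() <= 0:
            raise ValueError("scatter must be positive definite")
        if self.h > self.n:
            raise ValueError("h cannot exceed n")


#: qn_scale's pairwise machinery overflows 32-bit counts for larger n;
#: above this an evenly strided subsample of the order statistics is used
_QN_MAX_N = 20_000


def _qn_scale_large(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    if n <= _QN_MAX_N:
        return np.asarray(qn_scale(X, axis=0), dtype=float)
    idx = np.linspace(0, n - 1, _QN_MAX_N).round().astype(np.int64)
    sub = np.sort(X, axis=0)[idx]
    return np.asarray(qn_scale(sub, axis=0), dtype=float)


def _consistency_factor(gamma: float, p: int) -> float:
    """Fisher-consistency factor for the gamma-subset ML covariance
    under the Gaussian model."""
    if gamma >= 1.0:
        return 1.0
    q = stats.chi2.ppf(gamma, p)
    return gamma / stats.chi2.cdf(q, p + 2)


def _initial_scatters(Z: np.ndarray) -> list[np.ndarray]:
    """Deterministic starting scatter guesses on standardized data
    (DetMCD-style): rank/transform correlations plus simple covariances."""
    n, p = Z.shape
    out: list[np.ndarray] = [np.eye(p)]

    with np.errstate(invalid="ignore"):
        out.append(np.corrcoef(np.tanh(Z), rowvar=False))
        ranks = np.argsort(np.argsort(Z, axis=0), axis=0) + 1.0
        out.append(np.corrcoef(ranks, rowvar=False))
        scores = stats.norm.ppf(ranks / (n + 1.0))
        out.append(np.corrcoef(scores, rowvar=False))
    out.append(Z.T @ Z / n)
    norms = np.linalg.norm(Z, axis=1)
    half = np.argsort(norms, kind="stable")[: max((n + 1) // 2, p + 1)]
    Zh = Z[half]
    out.append((Zh - Zh.mean(0)).T @ (Zh - Zh.mean(0)) / len(half))

    fixed = []
    for S in out[:N_STARTS]:
        S = np.where(np.isfinite(S), S, np.eye(p))
        S = (S + S.T) / 2.0
        lo = np.linalg.eigvalsh(S).min()
        if lo <= 1e-10:
            S = S + (1e-8 - min(lo, 0.0)) * np.eye(p)
        fixed.append(S)
    return fixed


def _reg_scatter(Zh: np.ndarray, rho: float, c: float) -> tuple[np.ndarray, np.ndarray]:
    mu = Zh.mean(axis=0)
    D = Zh - mu
    S = rho * np.eye(Zh.shape[1]) + (1.0 - rho) * c * (D.T @ D / len(Zh))
    return mu, S


def _csteps(Z: np.ndarray, subset: np.ndarray, h: int, rho: float, c: float
            ) -> tuple[np.ndarray, float]:
    for _ in range(MAX_CSTEPS):
        mu, S = _reg_scatter(Z[subset], rho, c)
        d2 = _mahalanobis_sq(Z, mu, S)
        new = np.argsort(d2, kind="stable")[:h]
        if np.array_equal(np.sort(new), np.sort(subset)):
            break
        subset = new
    _, S = _reg_scatter(Z[subset], rho, c)
    sign, logdet = np.linalg.slogdet(S)
    return subset, logdet if sign > 0 else np.inf


def _mahalanobis_sq(X: np.ndarray, mu: np.ndarray, S: np.ndarray) -> np.ndarray:
    D = X - mu
    try:
        cf = cho_factor(S)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise ValueError("singular scatter matrix") from exc
    return np.einsum("ij,ij->i", D, cho_solve(cf, D.T).T)


def fit_mrcd(
    X: np.ndarray,
    alpha_trim: float = 0.25,
    rho: float | None = None,
) -> MRCDModel:
    """Fit the MRCD location and scatter.

    ``h = ceil(n * (1 - alpha_trim))`` observations are retained; the
    scatter is ``rho * I + (1 - rho) * c * S_h`` on median/Qn
    standardized data (consistency factor c), back-transformed to the
    original scale. With ``alpha_trim=0`` and ``rho=0`` the estimate
    reduces to the classical mean and ML covariance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array")
    n, p = X.shape
    if p < 2 or n <= p:
        raise ValueError("need n > p >= 2 observations")
    if not 0.0 <= alpha_trim < 1.0:
        raise ValueError("alpha_trim must lie in [0, 1)")

    med = np.median(X, axis=0)
    scale = _qn_scale_large(X)
    if np.any(scale <= 0):
        # fall back to MAD, then to plain sd, before declaring degeneracy
        mad = stats.median_abs_deviation(X, axis=0, scale="normal")
        scale = np.where(scale > 0, scale, mad)
        scale = np.where(scale > 0, scale, X.std(axis=0, ddof=1))
        if np.any(scale <= 0):
            raise ValueError("degenerate data: a variable has zero spread")
    Z = (X - med) / scale

    h = int(np.ceil(n * (1.0 - alpha_trim)))
    h = min(max(h, p + 1), n)
    c = _consistency_factor(h / n, p)

    starts = _initial_scatters(Z)
    subsets = []
    for S0 in starts:
        d2 = _mahalanobis_sq(Z, np.zeros(p), S0)
        subsets.append(np.argsort(d2, kind="stable")[:h])

    if rho is None:
        rho = 0.0
        for cand in RHO_GRID:
            ok = True
            for sub in subsets:
                _, S = _reg_scatter(Z[sub], cand, c)
                ev = np.linalg.eigvalsh(S)
                if ev.min() <= 0 or ev.max() / ev.min() > COND_MAX:
                    ok = False
                    break
            if ok:
                rho = cand
                break
        else:  # pragma: no cover - identity target is always well conditioned
            rho = 1.0
    elif not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")

    best, best_obj = None, np.inf
    for sub in subsets:
        sub, obj = _csteps(Z, sub, h, rho, c)
        if obj < best_obj:
            best, best_obj = sub, obj
    if best is None:  # pragma: no cover
        raise ValueError("MRCD subset search failed")

    mu_z, S_z = _reg_scatter(Z[best], rho, c)
    location = med + scale * mu_z
    scatter = S_z * np.outer(scale, scale)
    return MRCDModel(location, scatter, rho=float(rho), h=h, p=p, n=n,
                     support=np.sort(best))


def fit_classical(X: np.ndarray, ddof: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Classical (non-robust) mean and covariance for the T² statistic.

    ``ddof=0`` matches the ML normalization used inside the MRCD fit, so
    the two charts agree exactly when trimming and regularization vanish.
    """
    X = np.asarray(X, dtype=float)
    return X.mean(axis=0), np.cov(X, rowvar=False, ddof=ddof)


def t2_statistic(
    model: MRCDModel | tuple[np.ndarray, np.ndarray],
    x: np.ndarray,
) -> float | np.ndarray:
    """Hotelling T² of ``x`` (vector or rows of a matrix) against a
    fitted location/scatter: ``(x - m)' S^{-1} (x - m)``."""
    if isinstance(model, MRCDModel):
        mu, S = model.location, model.scatter
    else:
        mu, S = model
        mu = np.asarray(mu, dtype=float)
        S = np.asarray(S, dtype=float)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != mu.size:
        raise ValueError(f"dimension mismatch: x has {X.shape[1]}, model has {mu.size}")
    vals = _mahalanobis_sq(X, mu, S)
    return float(vals[0]) if single else vals


@dataclass
class ChartCalibration:
    """Monte-Carlo moment-matched scaled-F control limit."""

    d_hat: float
    q_hat: float
    ucl: float
    alpha: float
    p: int
    n: int
    n_mc: int
    seed: int | None = None
    mc_mean: float = float("nan")
    mc_var: float = float("nan")

    def __post_init__(self) -> None:
        if self.ucl <= 0:
            raise ValueError("UCL must be positive")
        if self.q_hat <= 4:
            raise ValueError("q_hat must exceed 4 for the matched-F variance to exist")

    def to_json(self, path: str | Path) -> None:
        rec = {k: (None if isinstance(v, float) and np.isnan(v) else v)
               for k, v in self.__dict__.items()}
        rec["q_hat"] = None if np.isinf(self.q_hat) else rec["q_hat"]
        Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChartCalibration":
        rec = json.loads(Path(path).read_text())
        if rec.get("q_hat") is None:
            rec["q_hat"] = float("inf")
        for k in ("mc_mean", "mc_var"):
            if rec.get(k) is None:
                rec[k] = float("nan")
        return cls(**rec)


def _match_scaled_f(m: float, v: float, p: int) -> tuple[float, float]:
    """Solve the two moment equations of a d-scaled F(p, q) variate for
    (d, q) given empirical mean m and variance v."""
    if m <= 0 or v <= 0:
        raise ValueError("moment matching needs positive mean and variance")
    r = v / (m * m)
    rp = r * p
    if rp <= 2.0 + 1e-12:
        # variance no larger than the chi2_p/p limit: q -> infinity
        return m, float("inf")
    q = (2.0 * p - 4.0 + 4.0 * rp) / (rp - 2.0)
    if q <= 4.0:
        raise ValueError(
            f"moment matching failed: implied q={q:.3f} <= 4 "
            f"(m={m:.4f}, v={v:.4f}, p={p})"
        )
    d = m * (q - 2.0) / q
    return d, q


def calibrate_limits(
    p: int,
    n: int,
    alpha: float = 0.05,
    n_mc: int = 1000,
    seed: int | None = None,
    alpha_trim: float = 0.25,
    robust: bool = True,
    m_oos: int = 10,
) -> ChartCalibration:
    """Monte-Carlo calibration of the T² control limit.

    ``n_mc`` clean p-variate standard-normal datasets of size ``n`` are
    simulated; for each, the chart statistic of ``m_oos`` fresh
    observations against the fitted (MRCD or classical) model is pooled,
    the pooled mean/variance are matched to a d-scaled F(p, q), and
    ``UCL = d_hat * F_{1-alpha}(p, q_hat)``.
    """
    if n_mc < 200:
        raise ValueError("n_mc must be at least 200")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    pooled = np.empty(n_mc * m_oos)
    for i in range(n_mc):
        X = rng.standard_normal((n, p))
        model = fit_mrcd(X, alpha_trim=alpha_trim) if robust else fit_classical(X)
        fresh = rng.standard_normal((m_oos, p))
        pooled[i * m_oos : (i + 1) * m_oos] = t2_statistic(model, fresh)

    m = float(pooled.mean())
    v = float(pooled.var(ddof=1))
    d_hat, q_hat = _match_scaled_f(m, v, p)
    if np.isinf(q_hat):
        ucl = d_hat * stats.chi2.ppf(1.0 - alpha, p) / p
    else:
        ucl = d_hat * stats.f.ppf(1.0 - alpha, p, q_hat)
    return ChartCalibration(d_hat=d_hat, q_hat=q_hat, ucl=float(ucl), alpha=alpha,
                            p=p, n=n, n_mc=n_mc, seed=seed, mc_mean=m, mc_var=v)


@dataclass
class RunRuleCall:
    """One called open region: contiguous window range plus the rules
    (1, 2 and/or 3) that produced it."""

    start_idx: int
    end_idx: int  # inclusive
    rules: frozenset[int]
    window_bp: int = 200
    seg_start: int = 0
    stats: np.ndarray | None = field(default=None, repr=False)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.seg_start + self.start_idx * self.window_bp,
                self.seg_start + (self.end_idx + 1) * self.window_bp)

    @property
    def span_bp(self) -> int:
        return (self.end_idx - self.start_idx + 1) * self.window_bp

    @property
    def n_windows(self) -> int:
        return self.end_idx - self.start_idx + 1


def _exceedance_runs(exceed: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    idx = np.flatnonzero(exceed)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def apply_run_rules(
    stats_seq: Sequence[float] | np.ndarray,
    ucl: float,
    window_bp: int = 200,
    seg_start: int = 0,
) -> list[RunRuleCall]:
    """Turn per-window T² values for one monitored segment into open
    region calls using the three run rules (see module docstring).
    Overlapping calls are merged; each call carries every contributing
    rule id. Merged rule-3 calls include the intervening sub-UCL windows.
    """
    s = np.asarray(stats_seq, dtype=float)
    if s.size == 0:
        raise ValueError("stats sequence must be non-empty")
    exceed = s > ucl
    raw = _exceedance_runs(exceed)

    # rule 3: merge runs separated by fewer than three in-control windows
    groups: list[dict] = []
    for r in raw:
        if groups and r[0] - groups[-1]["end"] - 1 < 3:
            groups[-1]["end"] = r[1]
            groups[-1]["rules"].add(3)
            groups[-1]["runs"].append(r)
        else:
            groups.append({"start": r[0], "end": r[1], "rules": set(), "runs": [r]})

    calls: list[dict] = []
    for g in groups:
        if any(e - b + 1 >= 3 for b, e in g["runs"]):
            g["rules"].add(1)
        if g["rules"]:
            calls.append(g)

    # rule 2: boundary exceedance calls a three-window span pointing inward
    n = s.size
    width = min(3, n)
    if exceed[0]:
        calls.append({"start": 0, "end": width - 1, "rules": {2}})
    if exceed[-1]:
        calls.append({"start": n - width, "end": n - 1, "rules": {2}})

    calls.sort(key=lambda g: (g["start"], g["end"]))
    merged: list[dict] = []
    for g in calls:
        if merged and g["start"] <= merged[-1]["end"]:
            merged[-1]["end"] = max(merged[-1]["end"], g["end"])
            merged[-1]["rules"] |= g["rules"]
        else:
            merged.append({"start": g["start"], "end": g["end"], "rules": set(g["rules"])})

    return [
        RunRuleCall(
            start_idx=g["start"],
            end_idx=g["end"],
            rules=frozenset(g["rules"]),
            window_bp=window_bp,
            seg_start=seg_start,
            stats=s[g["start"] : g["end"] + 1].copy(),
        )
        for g in merged
    ]


def _overlaps(start: int, end: int, calls: Iterable[tuple[int, int]]) -> bool:
    return any(max(start, cs) < min(end, ce) for cs, ce in calls)


def filter_training_set(
    candidates: pd.DataFrame,
    calls: Sequence[RunRuleCall] | Sequence[tuple[int, int]],
    balance: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Overlap-filter a noisy binary training set against chart calls.

    ``candidates`` needs columns ``start``, ``end`` (0-based half-open)
    and ``label`` (1 = open, 0 = closed). An open-labeled candidate is
    retained iff it overlaps (>= 1 bp) any called open region; a
    closed-labeled candidate is retained iff it overlaps none. With
    ``balance=True`` the majority class is downsampled to the minority
    size (seeded).
    """
    required = {"start", "end", "label"}
    if not required.issubset(candidates.columns):
        raise ValueError(f"candidates must have columns {sorted(required)}")
    spans = [c.interval if isinstance(c, RunRuleCall) else (int(c[0]), int(c[1]))
             for c in calls]
    hit = candidates.apply(
        lambda row: _overlaps(int(row["start"]), int(row["end"]), spans), axis=1
    ) if len(candidates) else pd.Series([], dtype=bool)
    keep = np.where(candidates["label"].to_numpy() == 1, hit.to_numpy(),
                    ~hit.to_numpy()) if len(candidates) else np.array([], bool)
    out = candidates.loc[keep].reset_index(drop=True)

    if balance and len(out):
        rng = np.random.default_rng(seed)
        pos = out.index[out["label"] == 1].to_numpy()
        neg = out.index[out["label"] == 0].to_numpy()
        k = min(pos.size, neg.size)
        sel = np.concatenate([
            rng.choice(pos, k, replace=False) if pos.size > k else pos,
            rng.choice(neg, k, replace=False) if neg.size > k else neg,
        ])
        out = out.loc[np.sort(sel)].reset_index(drop=True)
    return out
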