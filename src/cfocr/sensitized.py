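"""Sensitized T² chart: chart/classifier fusion and the three-class rule.

The fused monitoring statistic for a query sample is

    ST² = eta * delta * pT² + (1 - eta * delta) * pC,

where pT² is the MEWMA chart's open-state probability, pC the
classifier's, delta = 2 * |pC - 0.5| the classifier's decisiveness, and
eta the chart weight (default 0.3). When the classifier is undecided
(pC = 0.5, delta = 0) the statistic collapses to pC = 0.5; when it is
decisive, up to eta of the weight shifts to the chart. ST² always lies
between pT² and pC, hence in (0, 1).

The control limit CL is the bootstrap mean of the (1 - alpha) quantile
of in-control ST² values, optionally scaled by the pOCR mixture ratio
tau; the three chromatin states are read off the bands

    CCR:  ST² in [0, CL],   pOCR: (CL, 1 - eta],   OCR: (1 - eta, 1].

eta >= 0.7 collapses the pOCR band onto typical statistic values and is
rejected with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classifier import NoiseTolerantClassifier
from .mewma import MEWMAModel, bootstrap_bd, mewma_t2, prob_t2

__all__ = [
    "SensitizedChart",
    "confidence_delta",
    "sensitized_statistic",
    "calibrate_cl",
    "classify_region",
    "ETA_WARN_THRESHOLD",
]

ETA_WARN_THRESHOLD = 0.7

#: three-class label codes (shared with cfocr.simulate)
CCR, OCR, POCR = 0, 1, 2


def confidence_delta(pc: float | np.ndarray) -> float | np.ndarray:
    """Classifier decisiveness delta = 2 * |pC - 0.5|, in [0, 1]."""
    return 2.0 * np.abs(np.asarray(pc, dtype=float) - 0.5) if not np.isscalar(pc) \
        else 2.0 * abs(pc - 0.5)


def sensitized_statistic(
    pt2: float | np.ndarray,
    pc: float | np.ndarray,
    eta: float = 0.3,
) -> float | np.ndarray:
    """Fused statistic ST² = eta*delta*pT² + (1 - eta*delta)*pC."""
    if not 0.0 < eta <= 1.0:
        raise ValueError("eta must lie in (0, 1]")
    pt2a = np.asarray(pt2, dtype=float)
    pca = np.asarray(pc, dtype=float)
    if np.any(pt2a < 0) or np.any(pt2a > 1) or np.any(pca < 0) or np.any(pca > 1):
        raise ValueError("pT2 and pC must be probabilities")
    w = eta * 2.0 * np.abs(pca - 0.5)
    out = w * pt2a + (1.0 - w) * pca
    return float(out) if np.isscalar(pt2) and np.isscalar(pc) else out


@dataclass
class SensitizedChart:
    """Calibrated fusion chart: MEWMA model (with BD), classifier, eta
    and the bootstrap control limit."""

    mewma: MEWMAModel
    classifier: NoiseTolerantClassifier
    eta: float = 0.3
    cl: float | None = None
    cl_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must lie in (0, 1]")
        if self.eta >= ETA_WARN_THRESHOLD:
            warnings.warn(
                f"eta={self.eta} >= {ETA_WARN_THRESHOLD} pushes partially open "
                "statistics below the control limit and degrades the "
                "three-class bands; values <= 0.6 are recommended",
                UserWarning,
                stacklevel=2,
            )

    # -- per-sample probabilities ---------------------------------------
    def prob_chart(self, summary_vectors: np.ndarray) -> np.ndarray:
        if self.mewma.bd is None:
            raise ValueError("MEWMA model has no bootstrap control value BD")
        t2 = mewma_t2(summary_vectors, self.mewma)
        return prob_t2(t2, self.mewma.bd)

    def prob_model(self, features: np.ndarray) -> np.ndarray:
        return self.classifier.predict_proba(features)[:, 1]

    def statistic(self, summary_vectors: np.ndarray,
                  features: np.ndarray) -> np.ndarray:
        return sensitized_statistic(
            self.prob_chart(summary_vectors), self.prob_model(features), self.eta
        )


def calibrate_cl(
    ic_st2: np.ndarray,
    chart: SensitizedChart,
    alpha: float = 0.05,
    B: int = 1000,
    tau: float | None = None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bootstrap control limit for ST².

    CL is the mean over B resamples of the empirical (1 - alpha)
    quantile of in-control ST² values; the adjusted limit multiplies CL
    by the mixture ratio ``tau`` when one is supplied. Stores both on
    the chart and returns them.
    """
    cl = bootstrap_bd(ic_st2, alpha=alpha, B=B, seed=seed)
    cl_adj = cl * tau if tau is not None else cl
    if cl_adj >= 1.0 - chart.eta:
        raise ValueError(
            f"adjusted CL {cl_adj:.3f} >= 1 - eta = {1 - chart.eta:.3f}: "
            "the partially-open band is empty"
        )
    chart.cl = float(cl)
    chart.cl_adjusted = float(cl_adj)
    return chart.cl, chart.cl_adjusted


def classify_region(
    st2: float | np.ndarray,
    chart: SensitizedChart,
) -> int | np.ndarray:
    """Three-class decision: CCR for ST² in [0, CL], pOCR in (CL, 1-eta],
    OCR in (1-eta, 1]."""
    if chart.cl_adjusted is None:
        raise ValueError("chart has no calibrated control limit")
    s = np.asarray(st2, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("ST2 must lie in [0, 1]")
    labels = np.full(s.shape, POCR, dtype=np.int64)
    labels = np.where(s <= chart.cl_adjusted, CCR, labels)
    labels = np.where(s > 1.0 - chart.eta, OCR, labels)
    return int(labels) if np.isscalar(st2) else labels
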