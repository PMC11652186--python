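"""Evaluation metrics: ACC / REC / PRE / F1 plus AUC and AUPR.

Binary metrics follow the confusion-matrix definitions
ACC = (TP+TN)/(TP+FN+TN+FP), REC = TP/(TP+FN), PRE = TP/(TP+FP),
F1 = 2*PRE*REC/(PRE+REC). Three-class precision/recall/F1 are
macro-averaged over one-vs-rest reductions; AUC and AUPR are
one-vs-rest macro averages over the score columns.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["binary_metrics", "compute_metrics", "balanced_accuracy"]


def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    y_true = np.asarray(y_true).astype(np.int64)
    y_pred = np.asarray(y_pred).astype(np.int64)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / max(tp + tn + fp + fn, 1)
    rec = tp / (tp + fn) if tp + fn else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return {"acc": acc, "rec": rec, "pre": pre, "f1": f1}


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    recalls = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
    return float(np.mean(recalls))


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
) -> dict[str, float]:
    """Metric record for binary or three-class predictions.

    Multi-class PRE/REC/F1 are macro averages of the one-vs-rest binary
    formulas; ``scores`` (n x k class probabilities, or a 1-D positive
    score for binary) adds AUC/AUPR, omitted with a warning when the
    truth is single-class.
    """
    y_true = np.asarray(y_true).astype(np.int64)
    y_pred = np.asarray(y_pred).astype(np.int64)
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))

    if classes.size <= 2 and classes.max(initial=0) <= 1:
        out = binary_metrics(y_true, y_pred)
    else:
        per = [binary_metrics((y_true == c).astype(int), (y_pred == c).astype(int))
               for c in classes]
        out = {
            "acc": float(np.mean(y_true == y_pred)),
            "rec": float(np.mean([m["rec"] for m in per])),
            "pre": float(np.mean([m["pre"] for m in per])),
            "f1": float(np.mean([m["f1"] for m in per])),
        }
    out["balanced_acc"] = balanced_accuracy(y_true, y_pred)

    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if np.unique(y_true).size < 2:
            warnings.warn("single-class truth: AUC/AUPR omitted", UserWarning,
                          stacklevel=2)
            return out
        try:
            if scores.ndim == 1:
                out["auc"] = float(roc_auc_score(y_true, scores))
                out["aupr"] = float(average_precision_score(y_true, scores))
            else:
                out["auc"] = float(
                    roc_auc_score(y_true, scores, multi_class="ovr", average="macro")
                )
                aps = [
                    average_precision_score((y_true == c).astype(int), scores[:, c])
                    for c in np.unique(y_true)
                ]
                out["aupr"] = float(np.mean(aps))
        except ValueError as exc:
            warnings.warn(f"AUC/AUPR omitted: {exc}", UserWarning, stacklevel=2)
    return out
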