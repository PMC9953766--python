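"""Classification evaluation: metrics, ROC/AUC, restricted AUC, importance.

Beyond the usual precision/recall/F1/accuracy (melanoma = positive class),
two quantities matter clinically:

* AUC restricted to FPR > 0.40 — the high-sensitivity operating region a
  dermatologist works in (missing a melanoma is costlier than a benign
  excision). Reported as raw trapezoidal area of TPR over FPR on
  [cutoff, 1] with linear interpolation at the cutoff (a perfect classifier
  scores 1 - cutoff = 0.6; the chance diagonal (1 - cutoff^2)/2 = 0.42).
* permutation feature importance — mean decrease in accuracy after permuting
  one feature column, averaged over seeded repeats; model-agnostic, and
  aggregable across classifier kinds and fold models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, auc, f1_score, precision_score,
                             recall_score, roc_curve)

__all__ = [
    "RocCurve",
    "classification_metrics",
    "roc_and_auc",
    "partial_auc_fpr_above",
    "permutation_importance",
    "aggregate_importance",
]


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC points must be nondecreasing")


def classification_metrics(labels, decisions) -> dict:
    """Record-level precision, recall, F1 and accuracy (melanoma positive)."""
    y = np.asarray(labels, dtype=int)
    d = np.asarray(decisions, dtype=int)
    if len(y) == 0:
        raise ValueError("empty input")
    if y.shape != d.shape:
        raise ValueError("labels and decisions must align")
    return {
        "precision": float(precision_score(y, d, zero_division=0)),
        "recall": float(recall_score(y, d, zero_division=0)),
        "f1": float(f1_score(y, d, zero_division=0)),
        "accuracy": float(accuracy_score(y, d)),
        "n": int(len(y)),
    }


def roc_and_auc(labels, scores) -> tuple[RocCurve, float]:
    """ROC curve over unique score thresholds and its trapezoidal AUC."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr), float(auc(fpr, tpr))


def partial_auc_fpr_above(curve: RocCurve, cutoff: float = 0.40) -> float:
    """Raw area under TPR over FPR restricted to [cutoff, 1].

    The curve is linearly interpolated at FPR = cutoff; no normalization is
    applied, so the value is bounded by 1 - cutoff.
    """
    if not 0.0 <= cutoff < 1.0:
        raise ValueError("cutoff must be in [0, 1)")
    fpr, tpr = curve.fpr, curve.tpr
    keep = fpr >= cutoff
    x = np.concatenate([[cutoff], fpr[keep]])
    y = np.concatenate([[np.interp(cutoff, fpr, tpr)], tpr[keep]])
    return float(np.trapezoid(y, x))


def _default_scorer(model, X, y) -> float:
    return float(accuracy_score(y, model.predict(X)))


def permutation_importance(model, rows, labels, repeats: int = 10,
                           seed: int = 0, feature_names=None,
                           shuffle_fn=None) -> pd.DataFrame:
    """Mean accuracy decrease per feature after seeded column permutation.

    For each feature column, ``repeats`` independent permutations are drawn
    and the decrease from the baseline accuracy is averaged. ``shuffle_fn``
    (rng, column) -> permuted column is injectable for testing; the default
    is a uniform random permutation. Returns a frame with columns
    ``feature, importance, importance_sd`` sorted by importance descending
    (ties broken by original column order).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if feature_names is None:
        feature_names = (list(rows.columns)
                         if isinstance(rows, pd.DataFrame)
                         else [f"f{i}" for i in range(np.shape(rows)[1])])
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_numpy()
    X = np.asarray(rows, dtype=float)
    y = np.asarray(labels)
    if shuffle_fn is None:
        shuffle_fn = lambda rng, col: rng.permutation(col)
    rng = np.random.default_rng(seed)
    baseline = _default_scorer(model, X, y)
    rows_out = []
    for j, name in enumerate(feature_names):
        drops = np.empty(repeats)
        for r in range(repeats):
            Xp = X.copy()
            Xp[:, j] = shuffle_fn(rng, X[:, j])
            drops[r] = baseline - _default_scorer(model, Xp, y)
        rows_out.append({"feature": name,
                         "importance": float(drops.mean()),
                         "importance_sd": float(drops.std())})
    out = pd.DataFrame(rows_out)
    return (out.sort_values("importance", ascending=False, kind="stable")
            .reset_index(drop=True))


def aggregate_importance(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average importance scores across models (fold models, kinds)."""
    if not tables:
        raise ValueError("no importance tables to aggregate")
    cat = pd.concat(tables, ignore_index=True)
    out = (cat.groupby("feature", sort=False)["importance"].mean()
           .reset_index()
           .sort_values("importance", ascending=False, kind="stable")
           .reset_index(drop=True))
    return out
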