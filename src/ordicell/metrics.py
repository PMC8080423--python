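"""Evaluation metrics for ordinal classifiers.

All metrics are computed from a :class:`PredictionSet` — paired true labels,
predicted probability vectors and decoded classes for N observations.

Accuracy treats every error alike; MAE weights errors by their class distance;
Kendall's tau-b measures ordinal association with tie correction (class data is
heavily tied); macro AUROC averages one-vs-rest ROC areas over the classes
present; the UOC index combines accuracy and ranking while being invariant to
class prevalence (lower is better, 0-100 scale); the Gini coefficient measures
how concentrated (sparse) a probability vector is, from 0 for uniform to
(K-1)/K for one-hot.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion, roc_auc_score

from .encodings import OrdinalLabel
from .heads import predict_expectation, predict_mode

__all__ = [
    "PredictionSet",
    "MetricReport",
    "accuracy",
    "mean_absolute_error",
    "kendall_tau",
    "macro_auroc",
    "uoc_index",
    "gini_sparsity",
    "mean_gini",
    "compute_report",
    "confusion_matrix",
]


@dataclass(frozen=True)
class PredictionSet:
    """True labels, predicted probability rows and decoded classes for N samples.

    Labels are 1-based integers in 1..K; ``predicted_probs`` has shape (N, K)
    with rows on the probability simplex.
    """

    true_labels: np.ndarray
    predicted_probs: np.ndarray
    predicted_labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        t = np.asarray(self.true_labels, dtype=int)
        p = np.asarray(self.predicted_probs, dtype=float)
        d = np.asarray(self.predicted_labels, dtype=int)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("true_labels must be a non-empty 1-D array")
        if not (t.size == d.size == p.shape[0]):
            raise ValueError("true_labels, predicted_probs, predicted_labels lengths differ")
        if p.ndim != 2 or p.shape[1] != self.K:
            raise ValueError(f"predicted_probs must have shape (N, {self.K})")
        for arr, name in ((t, "true_labels"), (d, "predicted_labels")):
            if arr.min() < 1 or arr.max() > self.K:
                raise ValueError(f"{name} must lie in 1..{self.K}")
        if np.any(p < -1e-12) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("predicted_probs rows must be probability vectors")
        object.__setattr__(self, "true_labels", t)
        object.__setattr__(self, "predicted_probs", p)
        object.__setattr__(self, "predicted_labels", d)

    @classmethod
    def from_probabilities(
        cls,
        true_labels: Sequence[int] | Sequence[OrdinalLabel],
        predicted_probs: np.ndarray,
        rule: str = "mode",
    ) -> "PredictionSet":
        """Build a set from probabilities, decoding classes by ``mode`` or ``mean``."""
        probs = np.asarray(predicted_probs, dtype=float)
        K = probs.shape[1]
        decode = {"mode": predict_mode, "mean": predict_expectation}[rule]
        decoded = np.array([decode(row).k_star for row in probs])
        truths = np.array([int(t) for t in true_labels])
        return cls(truths, probs, decoded, K)

    def __len__(self) -> int:
        return self.true_labels.size


@dataclass(frozen=True)
class MetricReport:
    """One row of evaluation results for a prediction set."""

    accuracy: float
    mae: float
    uoc: float
    kendall_tau: float
    macro_auroc: float
    mean_gini: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def accuracy(preds: PredictionSet) -> float:
    """Fraction of exactly correct class predictions."""
    return float(np.mean(preds.true_labels == preds.predicted_labels))


def mean_absolute_error(preds: PredictionSet) -> float:
    """Mean absolute class-index distance between truth and prediction."""
    return float(np.mean(np.abs(preds.true_labels - preds.predicted_labels)))


def kendall_tau(preds: PredictionSet) -> float:
    """Kendall's tau-b rank correlation between true and predicted classes."""
    tau = stats.kendalltau(preds.true_labels, preds.predicted_labels).statistic
    return float(tau)


def macro_auroc(preds: PredictionSet) -> float:
    """Mean one-vs-rest ROC AUC over the classes present in the truths.

    Raises ``ValueError`` when fewer than two classes are present (no
    one-vs-rest split exists).
    """
    present = np.unique(preds.true_labels)
    if present.size < 2:
        raise ValueError("macro AUROC undefined: only one class present in truths")
    aucs = [
        roc_auc_score(preds.true_labels == k, preds.predicted_probs[:, k - 1])
        for k in present
    ]
    return float(np.mean(aucs))


def _default_uoc_formula(cm: np.ndarray) -> float:
    """Prevalence-invariant ordinal error index of a confusion matrix, in [0, 100].

    Rows with observations are normalized to class-conditional frequencies, so
    duplicating observations or rescaling class prevalence leaves the index
    unchanged.  Each cell contributes the average of a misclassification
    indicator (the accuracy part) and its absolute rank distance from the
    diagonal normalized by K-1 (the ranking part).  A diagonal matrix scores 0;
    moving mass farther from the diagonal strictly increases the index.
    """
    K = cm.shape[0]
    row_sums = cm.sum(axis=1)
    present = row_sums > 0
    R = cm[present].astype(float) / row_sums[present, None]
    r_idx = np.nonzero(present)[0][:, None]
    c_idx = np.arange(K)[None, :]
    dist = np.abs(r_idx - c_idx)
    cell_cost = 0.5 * ((dist > 0) + dist / (K - 1))
    return float(100.0 * np.mean(np.sum(R * cell_cost, axis=1)))


def uoc_index(
    preds: PredictionSet, formula: Callable[[np.ndarray], float] | None = None
) -> float:
    """Uniform ordinal classification index (lower is better, 0-100).

    The index combines an accuracy term with a ranking term and is robust to
    class imbalance.  ``formula`` may replace the default confusion-matrix
    functional with any drop-in scalar index.
    """
    if len(preds) < 1:
        raise ValueError("empty prediction set")
    cm = confusion_matrix(preds)
    return (formula or _default_uoc_formula)(cm)


def gini_sparsity(probs: np.ndarray) -> float:
    """Gini concentration coefficient of one probability vector.

    ``sum_ij |p_i - p_j| / (2 K sum p)`` — 0 for the uniform distribution,
    (K-1)/K for a one-hot vector; permutation invariant.
    """
    p = np.asarray(probs, dtype=float)
    K = p.size
    return float(np.abs(p[:, None] - p[None, :]).sum() / (2.0 * K * p.sum()))


def mean_gini(preds: PredictionSet) -> float:
    """Mean Gini sparsity of the predicted probability vectors."""
    return float(np.mean([gini_sparsity(row) for row in preds.predicted_probs]))


def confusion_matrix(preds: PredictionSet) -> np.ndarray:
    """K x K confusion matrix; rows are true classes 1..K, columns predictions."""
    return _sk_confusion(
        preds.true_labels, preds.predicted_labels, labels=np.arange(1, preds.K + 1)
    )


def confusion_matrix_frame(preds: PredictionSet) -> pd.DataFrame:
    labels = [str(k) for k in range(1, preds.K + 1)]
    return pd.DataFrame(confusion_matrix(preds), index=labels, columns=labels)


def compute_report(preds: PredictionSet) -> MetricReport:
    """Evaluate all metrics on a prediction set.

    ``macro_auroc`` is reported as NaN when undefined (single-class truths).
    """
    try:
        auc = macro_auroc(preds)
    except ValueError:
        auc = float("nan")
    return MetricReport(
        accuracy=accuracy(preds),
        mae=mean_absolute_error(preds),
        uoc=uoc_index(preds),
        kendall_tau=kendall_tau(preds),
        macro_auroc=auc,
        mean_gini=mean_gini(preds),
    )
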