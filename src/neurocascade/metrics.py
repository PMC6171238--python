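"""Confusion-matrix diagnostics and ROC AUC.

Implements the full screening-test metric panel: accuracy, sensitivity,
specificity, F1, positive/negative likelihood ratios, predictive values, and
pre-/post-test odds.  The identity post_test_odds = LR+ x pre_test_odds holds
exactly by construction when all quantities come from one confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticReport:
    """Metric panel; a metric whose denominator is zero is reported as NaN
    (flagged undefined) rather than raising or propagating silently."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    lr_plus: float
    lr_minus: float
    ppv: float
    npv: float
    pre_test_odds: float
    post_test_odds: float
    post_test_probability: float

    def as_dict(self) -> dict:
        return asdict(self)

    def rounded(self, decimals: int = 4) -> dict:
        return {k: (round(v, decimals) if math.isfinite(v) else v) for k, v in asdict(self).items()}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if not (np.isin(labels, [0, 1]).all() and np.isin(predictions, [0, 1]).all()):
        raise ValueError("labels and predictions must be binary")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def diagnostic_report(c: ConfusionCounts) -> DiagnosticReport:
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    return DiagnosticReport(
        accuracy=_ratio(c.tp + c.tn, c.n),
        sensitivity=sens,
        specificity=spec,
        f1=_ratio(2 * ppv * sens, ppv + sens) if math.isfinite(ppv + sens) else float("nan"),
        lr_plus=lr_plus(sens, spec),
        lr_minus=lr_minus(sens, spec),
        ppv=ppv,
        npv=npv,
        pre_test_odds=_ratio(c.tp + c.fn, c.tn + c.fp),
        post_test_odds=post_test_odds(ppv),
        post_test_probability=ppv,
    )


def lr_plus(sensitivity: float, specificity: float) -> float:
    """Positive likelihood ratio sens / (1 - spec)."""
    return _ratio(sensitivity, 1.0 - specificity)


def lr_minus(sensitivity: float, specificity: float) -> float:
    """Negative likelihood ratio (1 - sens) / spec."""
    return _ratio(1.0 - sensitivity, specificity)


def post_test_odds(ppv: float) -> float:
    """Disease odds after a positive test, ppv / (1 - ppv)."""
    return _ratio(ppv, 1.0 - ppv)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected rank (Mann-Whitney) AUC, equal to the trapezoidal ROC
    area; ties between a case and a control count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = rankdata(scores)
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
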