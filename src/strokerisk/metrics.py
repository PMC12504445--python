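"""Classification metrics: confusion counts, the six headline indicators,
ROC/AUC, the KS statistic and a decision-threshold sweep.

Accuracy = (TP+TN)/(TP+TN+FP+FN), Precision = TP/(TP+FP),
Recall = TP/(TP+FN), Specificity = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN).
A ``printed_eq5`` switch reproduces the alternative specificity denominator
(TP+FN) verbatim for comparison; the standard definition is the default.
Zero-denominator metrics surface as ``None`` (never silently 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .focal import DecisionRule, decide


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    auc: float | None = None
    ks: float | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
            "ks": self.ks,
        }


def _binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, [0, 1]).all():
        raise ValueError(f"{name} must be binary 0/1")
    return v.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard 2x2 tally (positive class = 1)."""
    y_true = _binary(y_true, "y_true")
    y_pred = _binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts, printed_eq5: bool = False) -> MetricsReport:
    """The five confusion-derived indicators (AUC/KS need scores)."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    spe_den = (c.tp + c.fn) if printed_eq5 else (c.tn + c.fp)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, spe_den),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def roc_auc(y_true, scores) -> float | None:
    """Area under the ROC curve; ties handled by rank-averaging
    (equivalent to the Mann-Whitney U statistic)."""
    from sklearn.metrics import roc_auc_score

    y_true = _binary(y_true, "y_true")
    if len(np.unique(y_true)) < 2:
        return None
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def ks_statistic(y_true, scores) -> float | None:
    """Max over thresholds of |TPR - FPR| (two-sample KS between the score
    distributions of the classes)."""
    from sklearn.metrics import roc_curve

    y_true = _binary(y_true, "y_true")
    if len(np.unique(y_true)) < 2:
        return None
    fpr, tpr, _ = roc_curve(y_true, np.asarray(scores, dtype=float))
    return float(np.max(np.abs(tpr - fpr)))


def evaluate_scores(
    y_true, scores, rule: DecisionRule | None = None, printed_eq5: bool = False
) -> MetricsReport:
    """Full report: threshold the scores with ``rule`` then add AUC and KS."""
    rule = rule if rule is not None else DecisionRule()
    y_pred = decide(np.asarray(scores, dtype=float), rule)
    base = metrics(confusion(y_true, y_pred), printed_eq5=printed_eq5)
    return MetricsReport(
        accuracy=base.accuracy,
        precision=base.precision,
        recall=base.recall,
        specificity=base.specificity,
        f1=base.f1,
        auc=roc_auc(y_true, scores),
        ks=ks_statistic(y_true, scores),
    )


DEFAULT_SWEEP_TAUS = (0.2, 0.3, 0.327, 0.4, 0.5)


def threshold_sweep(y_true, scores, taus=DEFAULT_SWEEP_TAUS):
    """Per-threshold confusion counts and metrics.

    Returns a pandas DataFrame with one row per tau, columns
    ``tau, tp, tn, fp, fn, accuracy, precision, recall, specificity, f1``.
    """
    import pandas as pd

    scores = np.asarray(scores, dtype=float)
    rows = []
    for tau in taus:
        c = confusion(y_true, decide(scores, DecisionRule(tau=tau)))
        m = metrics(c)
        rows.append(
            {
                "tau": tau,
                "tp": c.tp,
                "tn": c.tn,
                "fp": c.fp,
                "fn": c.fn,
                **{k: v for k, v in m.as_dict().items() if k not in ("auc", "ks")},
            }
        )
    return pd.DataFrame(rows)


def roc_curve_points(y_true, scores):
    """(FPR, TPR, thresholds) arrays for plotting/export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(_binary(y_true, "y_true"), np.asarray(scores, dtype=float))
    return fpr, tpr, thr
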