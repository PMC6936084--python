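"""Confusion matrix and the ten-metric evaluation report.

The positive class is a thrombosis patient (+1).  Nine metrics derive
from the confusion counts — Acc, sensitivity, specificity, precision,
F-measure, FPR, FNR, FDR, MCC — and the identities FPR = 1 - specificity,
FNR = 1 - sensitivity and FDR = 1 - precision hold exactly.  AUC is the
rank-based Mann-Whitney statistic

    AUC = (sum of positive-class ranks - n0 (n0 + 1) / 2) / (n0 n1)

with ascending mid-ranks over the prediction scores (minimum start rank
1), so a perfect ranking scores 1 and all-tied scores give 0.5.

Degenerate 0/0 ratios: precision and FDR with no predicted positives are
reported as NaN (and propagate through averages); MCC with a zero
marginal is reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionMatrix", "MetricReport", "confusion", "auc_score", "metric_report",
           "METRIC_COLUMNS"]

METRIC_COLUMNS = ["Acc", "AUC", "sensitivity", "specificity", "precision",
                  "F_measure", "FNR", "FPR", "FDR", "MCC"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Exact counts; labels must be +/-1 and lengths equal."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    for arr in (y_true, y_pred):
        if not np.all(np.isin(arr, (-1, 1))):
            raise ValueError("labels must be +1 or -1")
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == -1)).sum()),
        fp=int(((y_true == -1) & (y_pred == 1)).sum()),
        tn=int(((y_true == -1) & (y_pred == -1)).sum()),
    )


def auc_score(y_true, scores) -> float:
    """Rank-based AUC (Mann-Whitney concordance probability)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n0 = int((y_true == 1).sum())
    n1 = int((y_true == -1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs at least one patient in each class")
    ranks = rankdata(scores)  # ascending mid-ranks, minimum start rank 1
    r_pos = ranks[y_true == 1].sum()
    return float((r_pos - n0 * (n0 + 1) / 2) / (n0 * n1))


@dataclass
class MetricReport:
    """The ten evaluation metrics for one fitted model on one test fold."""

    cm: ConfusionMatrix
    Acc: float
    sensitivity: float
    specificity: float
    precision: float
    F_measure: float
    FNR: float
    FPR: float
    FDR: float
    MCC: float
    AUC: float = float("nan")
    n0: int = 0
    n1: int = 0
    ranks: np.ndarray | None = None  # per-patient ranks retained for audit
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def _ratio(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(f"{name}:0/0")
        return float("nan")
    return num / den


def metric_report(cm: ConfusionMatrix, scores=None, y_true=None) -> MetricReport:
    """All formula metrics from a confusion matrix; AUC is filled in when
    the per-patient scores and true labels are supplied."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    flags: list = []
    sens = _ratio(tp, tp + fn, flags, "sensitivity")
    spec = _ratio(tn, fp + tn, flags, "specificity")
    prec = _ratio(tp, tp + fp, flags, "precision")
    f = _ratio(2 * tp, 2 * tp + fp + fn, flags, "F_measure")
    mcc_den = (tp + fn) * (fp + tn) * (tp + fp) * (fn + tn)
    if mcc_den == 0:
        flags.append("MCC:zero-marginal")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den)
    rep = MetricReport(
        cm=cm,
        Acc=(tp + tn) / cm.n,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        F_measure=f,
        FNR=1.0 - sens,
        FPR=1.0 - spec,
        FDR=1.0 - prec,
        MCC=float(mcc),
        flags=flags,
    )
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true is required alongside scores for AUC")
        y_true = np.asarray(y_true)
        rep.AUC = auc_score(y_true, scores)
        rep.n0 = int((y_true == 1).sum())
        rep.n1 = int((y_true == -1).sum())
        rep.ranks = rankdata(np.asarray(scores, dtype=float))
    return rep
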