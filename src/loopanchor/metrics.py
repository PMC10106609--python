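"""Binary-classification metrics: Sn, Sp, precision, F1, accuracy, MCC and
the two curve areas (AUROC, AUPRC).

Conventions, fixed and tested:

* a sample is called positive when its score is >= the threshold (default 0.5);
* degenerate denominators yield 0 (with a debug log), so metrics are total
  functions — real runs never hit these cases but edge tests do;
* AUROC is computed from the Mann–Whitney rank statistic (ties counted half),
  which equals the trapezoidal area under the ROC with grouped thresholds;
* AUPRC is average precision (step-interpolated area under the PR curve).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    precision: float
    f1: float
    acc: float
    mcc: float
    auroc: float
    auprc: float

    #: column order used by the pretty table / TSV output
    FIELDS = ("sn", "sp", "precision", "acc", "mcc", "f1", "auroc", "auprc")
    HEADERS = ("Sn", "Sp", "Pre", "Acc", "MCC", "F1", "AUROC", "AUPRC")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/FP/TN/FN calling positive iff score >= threshold."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, denom: float, name: str) -> float:
    if denom == 0:
        logger.debug("degenerate denominator in %s; returning 0", name)
        return 0.0
    return num / denom


def sensitivity(cc: ConfusionCounts) -> float:
    """Sn = TP / (TP + FN); also called recall."""
    return _ratio(cc.tp, cc.tp + cc.fn, "sensitivity")


recall = sensitivity


def specificity(cc: ConfusionCounts) -> float:
    """Sp = TN / (TN + FP)."""
    return _ratio(cc.tn, cc.tn + cc.fp, "specificity")


def precision(cc: ConfusionCounts) -> float:
    """Precision = TP / (TP + FP)."""
    return _ratio(cc.tp, cc.tp + cc.fp, "precision")


def f1(cc: ConfusionCounts) -> float:
    """F1 = 2 * Precision * Recall / (Precision + Recall)."""
    p, r = precision(cc), sensitivity(cc)
    return _ratio(2.0 * p * r, p + r, "f1")


def accuracy(cc: ConfusionCounts) -> float:
    """Acc = (TP + TN) / total."""
    return _ratio(cc.tp + cc.tn, cc.total, "accuracy")


def mcc(cc: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), in [-1, 1];
    defined as 0 when any factor of the denominator vanishes.
    """
    tp, fp, tn, fn = (float(v) for v in (cc.tp, cc.fp, cc.tn, cc.fn))
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        logger.debug("degenerate denominator in mcc; returning 0")
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom_sq)


def _check_both_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present for curve metrics")


def auroc(labels, scores) -> float:
    """Area under the ROC curve via the rank-sum (Mann–Whitney) statistic:
    U / (n1 * n0), with tied scores contributing half."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    _check_both_classes(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auprc(labels, scores) -> float:
    """Area under the precision–recall curve with step interpolation
    (average precision)."""
    labels = np.asarray(labels, dtype=int)
    _check_both_classes(labels)
    return float(average_precision_score(labels, scores))


def evaluate(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full metric suite for one set of predictions."""
    cc = confusion(labels, scores, threshold)
    return MetricsReport(
        sn=sensitivity(cc),
        sp=specificity(cc),
        precision=precision(cc),
        f1=f1(cc),
        acc=accuracy(cc),
        mcc=mcc(cc),
        auroc=auroc(labels, scores),
        auprc=auprc(labels, scores),
    )


def report_table(reports: dict[str, MetricsReport]) -> str:
    """Pretty table, one row per model, columns Sn Sp Pre Acc MCC F1 AUROC
    AUPRC."""
    name_w = max([len(n) for n in reports] + [5])
    lines = [
        "model".ljust(name_w) + "  " + "  ".join(h.rjust(6) for h in MetricsReport.HEADERS)
    ]
    for name, rep in reports.items():
        vals = [getattr(rep, f) for f in MetricsReport.FIELDS]
        lines.append(
            name.ljust(name_w) + "  " + "  ".join(f"{v:6.4f}" for v in vals)
        )
    return "\n".join(lines)


def write_report_tsv(reports: dict[str, MetricsReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("model\t" + "\t".join(MetricsReport.HEADERS) + "\n")
        for name, rep in reports.items():
            vals = [getattr(rep, f) for f in MetricsReport.FIELDS]
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")
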