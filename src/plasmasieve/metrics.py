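"""Confusion-count bookkeeping and the evaluation metrics.

All filtering strategies are compared by precision, recall, F1, the Matthews
correlation coefficient and Youden's J computed from pooled or per-patient
confusion counts.  Zero-denominator conventions: an empty denominator in
precision, recall or specificity yields 0; a zero factor under the MCC root
yields MCC 0; pr + rc = 0 yields F1 0.  Under these conventions the
accept-everything strategy (TN = FN = 0) scores recall 1, MCC 0, J 0 —
i.e. random-guessing performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    mcc: float
    youden_j: float

    def __add__(self, other: "MetricsReport") -> "MetricsReport":
        return compute_metrics(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def f1_from_pr_rc(pr: float, rc: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if pr + rc == 0:
        return 0.0
    return 2.0 * pr * rc / (pr + rc)


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValueError("all-zero confusion table")
    pr = _ratio(tp, tp + fp)
    rc = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=pr,
        recall=rc,
        f1=f1_from_pr_rc(pr, rc),
        mcc=mcc,
        youden_j=rc + specificity - 1.0,
    )


def confusion_from_labels(truth: list[bool] | tuple[bool, ...],
                          predicted: list[bool] | tuple[bool, ...]) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) from parallel truth/prediction label lists."""
    if len(truth) != len(predicted):
        raise ValueError("label lists differ in length")
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        if t and p:
            tp += 1
        elif t:
            fn += 1
        elif p:
            fp += 1
        else:
            tn += 1
    return tp, fp, tn, fn
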