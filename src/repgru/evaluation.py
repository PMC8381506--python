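"""Per-base and boundary-level comparison against a gold annotation.

All per-base metrics are set-theoretic over genome positions: with
P_c the predicted and A_c the annotated position set of class c,
FPR_c = |P_c \\ A_c| / |A_{not c}| and FNR_c = |A_c \\ P_c| / |A_c|.
The joint 5-class quality is summarised by the multi-class Matthews
correlation coefficient (Gorodkin's R_k statistic); one-vs-rest binary
MCCs are exposed per repeat class as well.  Boundary-level agreement
counts a gold segment as recovered when a same-class prediction matches
both of its end points within a tolerance of delta bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import N_CLASSES, RepeatClass
from .segmentation import Segment

__all__ = [
    "ConfusionMatrix",
    "ClassRates",
    "confusion",
    "class_rates",
    "mcc_k",
    "mcc_one_vs_rest",
    "boundary_match",
    "evaluation_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """5 x 5 confusion counts; rows = gold class, columns = predicted."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Rows divided by the gold (true) base-pair totals per class."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)


@dataclass(frozen=True)
class ClassRates:
    """Per-base false positive / false negative rate for one class.

    A rate is NaN when its denominator is empty.
    """

    fpr: float
    fnr: float


def _as_tracks(pred, gold, mask=None):
    pred = np.asarray(pred, dtype=np.int64)
    gold = np.asarray(gold, dtype=np.int64)
    if pred.shape != gold.shape:
        raise ValueError(
            f"length mismatch: prediction {pred.shape} vs gold {gold.shape}"
        )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        pred, gold = pred[mask], gold[mask]
    return pred, gold


def confusion(pred, gold, mask=None) -> ConfusionMatrix:
    """Tally the 5 x 5 confusion matrix over positions.

    ``mask``, if given, selects the positions entering the evaluation
    (e.g. to exclude N positions).
    """
    pred, gold = _as_tracks(pred, gold, mask)
    counts = np.bincount(
        gold * N_CLASSES + pred, minlength=N_CLASSES * N_CLASSES
    ).reshape(N_CLASSES, N_CLASSES)
    return ConfusionMatrix(counts)


def class_rates(pred, gold, repeat_class: RepeatClass | int, mask=None) -> ClassRates:
    """Per-base FPR and FNR for one class from the position sets."""
    pred, gold = _as_tracks(pred, gold, mask)
    c = int(repeat_class)
    gold_c = gold == c
    pred_c = pred == c
    n_gold_c = int(gold_c.sum())
    n_gold_not_c = int((~gold_c).sum())
    fpr = (
        float((pred_c & ~gold_c).sum()) / n_gold_not_c
        if n_gold_not_c > 0
        else math.nan
    )
    fnr = float((gold_c & ~pred_c).sum()) / n_gold_c if n_gold_c > 0 else math.nan
    return ClassRates(fpr=fpr, fnr=fnr)


def mcc_k(conf: ConfusionMatrix) -> float:
    """Multi-class Matthews correlation coefficient (Gorodkin's R_k).

    With c the trace, s the total count, t_k the gold and p_k the
    predicted per-class totals:

        MCC_k = (c*s - sum_k t_k*p_k)
                / sqrt((s^2 - sum_k p_k^2) * (s^2 - sum_k t_k^2))

    Returns 0 when either variance term vanishes (constant prediction
    or constant gold).
    """
    counts = conf.counts.astype(np.float64)
    s = counts.sum()
    if s == 0:
        raise ValueError("empty confusion matrix")
    c = np.trace(counts)
    t = counts.sum(axis=1)
    p = counts.sum(axis=0)
    numerator = c * s - float(t @ p)
    var_pred = s * s - float(p @ p)
    var_gold = s * s - float(t @ t)
    if var_pred <= 0 or var_gold <= 0:
        return 0.0
    return numerator / math.sqrt(var_pred * var_gold)


def mcc_one_vs_rest(conf: ConfusionMatrix, repeat_class: RepeatClass | int) -> float:
    """Binary MCC of one repeat class against all other labels."""
    c = int(repeat_class)
    counts = conf.counts
    tp = counts[c, c]
    fn = counts[c, :].sum() - tp
    fp = counts[:, c].sum() - tp
    tn = counts.sum() - tp - fn - fp
    collapsed = ConfusionMatrix(np.array([[tn, fp], [fn, tp]], dtype=np.int64))
    return mcc_k(collapsed)


def boundary_match(
    pred_segments: Sequence[Segment],
    gold_segments: Sequence[Segment],
    delta: int = 50,
) -> tuple[float, float]:
    """Boundary-tolerant segment recovery at tolerance ``delta`` bp.

    A gold segment is recovered iff a predicted segment of the same
    class matches both its start and its end within delta (inclusive);
    matching is greedy one-to-one in coordinate order.  Returns
    (sensitivity, specificity) = (recovered gold fraction, matched
    prediction fraction); a ratio over an empty list is reported as 1.
    """
    unmatched_pred = sorted(
        range(len(pred_segments)), key=lambda i: pred_segments[i].start
    )
    matched_pred: set[int] = set()
    recovered = 0
    for gold in sorted(gold_segments, key=lambda seg: seg.start):
        for i in unmatched_pred:
            if i in matched_pred:
                continue
            pred = pred_segments[i]
            if (
                pred.repeat_class == gold.repeat_class
                and abs(pred.start - gold.start) <= delta
                and abs(pred.end - gold.end) <= delta
            ):
                matched_pred.add(i)
                recovered += 1
                break
    sensitivity = recovered / len(gold_segments) if gold_segments else 1.0
    specificity = len(matched_pred) / len(pred_segments) if pred_segments else 1.0
    return sensitivity, specificity


def evaluation_report(pred, gold, delta: int = 50, mask=None,
                      pred_segments=None, gold_segments=None) -> dict:
    """Bundle per-class rates, MCCs, the confusion table and (optionally)
    boundary agreement into one plain dictionary suitable for reports."""
    conf = confusion(pred, gold, mask)
    report: dict = {
        "mcc5": mcc_k(conf),
        "confusion": conf.counts.tolist(),
        "per_class": {},
    }
    for repeat_class in (RepeatClass.HSAT23, RepeatClass.ALPHOID,
                         RepeatClass.ALU, RepeatClass.LINE1):
        rates = class_rates(pred, gold, repeat_class, mask)
        report["per_class"][repeat_class.name] = {
            "fpr": rates.fpr,
            "fnr": rates.fnr,
            "mcc2": mcc_one_vs_rest(conf, repeat_class),
        }
    if pred_segments is not None and gold_segments is not None:
        sensitivity, specificity = boundary_match(pred_segments, gold_segments, delta)
        report["boundary"] = {
            "delta": delta,
            "sensitivity": sensitivity,
            "specificity": specificity,
        }
    return report
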