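"""Confusion-matrix tallying and the seven splice-site evaluation metrics.

All metrics are reported on a 0-100 scale (Mcc on -100..100):

    Sn  = TP/(TP+FN)                     sensitivity
    Sp  = TN/(TN+FP)                     specificity
    Acc = (TP+TN)/(TP+FP+FN+TN)          accuracy
    Mcc = (TP·TN - FN·FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))
    Ppv = TP/(TP+FP)                     positive predictive value
    Pc  = TP/(TP+FN+FP)                  performance coefficient (Jaccard)
    F1  = 2TP/(2TP+FP+FN)

Any metric with a zero denominator is flagged invalid and rendered "–".
The formulas are scale-invariant, so confusion cells may be raw counts or
percentages of the total. A classifier that emitted a single class for
every sample (TN=FN=0 or TP=FP=0) is flagged as a training failure and
rendered with a "*" marker.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "METRIC_NAMES",
    "tally_confusion",
    "compute_metrics",
    "detect_training_failure",
    "format_report",
    "parse_report",
    "report_to_json",
]

METRIC_NAMES = ("Sn", "Sp", "Acc", "Mcc", "Ppv", "Pc", "F1")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion cells; raw counts or percent-of-total (as_percent)."""

    tp: float
    fp: float
    fn: float
    tn: float
    as_percent: bool = False

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Seven metrics on the 0-100 scale; ``None`` marks an invalid value
    (zero denominator) and ``training_failure`` marks a degenerate
    single-class classifier."""

    Sn: float | None
    Sp: float | None
    Acc: float | None
    Mcc: float | None
    Ppv: float | None
    Pc: float | None
    F1: float | None
    training_failure: bool = False

    def value(self, name: str) -> float | None:
        return getattr(self, name)

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        """Metric dict rounded for display (full precision kept in the
        fields)."""
        return {
            m: (None if self.value(m) is None else round(self.value(m), ndigits))
            for m in METRIC_NAMES
        }


def tally_confusion(
    truth: Sequence[int],
    predicted: Sequence[int],
    as_percent: bool = False,
) -> ConfusionCounts:
    """Tally the 2x2 confusion matrix of binary labels.

    With ``as_percent`` each cell is scaled to percent of the total, the
    unit Tables-style reports use.
    """
    t = np.asarray(truth, dtype=int).ravel()
    p = np.asarray(predicted, dtype=int).ravel()
    if t.shape != p.shape or t.size == 0:
        raise ValueError("truth and predicted must be equal non-zero length")
    tp = float(np.sum((t == 1) & (p == 1)))
    fp = float(np.sum((t == 0) & (p == 1)))
    fn = float(np.sum((t == 1) & (p == 0)))
    tn = float(np.sum((t == 0) & (p == 0)))
    if as_percent:
        n = t.size
        return ConfusionCounts(
            100 * tp / n, 100 * fp / n, 100 * fn / n, 100 * tn / n, True
        )
    return ConfusionCounts(tp, fp, fn, tn, False)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive the seven metrics from confusion cells.

    Zero-denominator metrics come back ``None`` (invalid). Raises on
    all-zero counts.
    """
    if c.total == 0:
        raise ValueError("all confusion cells are zero")
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    mcc_den = math.sqrt((tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    mcc = None if mcc_den == 0 else 100.0 * (tp * tn - fn * fp) / mcc_den
    return MetricsReport(
        Sn=_ratio(tp, tp + fn),
        Sp=_ratio(tn, tn + fp),
        Acc=_ratio(tp + tn, c.total),
        Mcc=mcc,
        Ppv=_ratio(tp, tp + fp),
        Pc=_ratio(tp, tp + fn + fp),
        F1=_ratio(2 * tp, 2 * tp + fp + fn),
        training_failure=detect_training_failure(c),
    )


def detect_training_failure(c: ConfusionCounts) -> bool:
    """True iff every prediction fell in one class (TP+FP or TN+FN is the
    whole total), the degenerate outcome a failed training run produces."""
    if c.total == 0:
        raise ValueError("all confusion cells are zero")
    return c.tp + c.fp == c.total or c.tn + c.fn == c.total


def format_report(r: MetricsReport) -> str:
    """Render the seven metrics as a fixed one-decimal two-column table.

    Invalid values print as "–"; a training failure appends a "*" marker
    line. ``parse_report`` inverts this rendering.
    """
    lines = ["metric\tvalue"]
    for m in METRIC_NAMES:
        v = r.value(m)
        lines.append(f"{m}\t{'–' if v is None else format(v, '.1f')}")
    if r.training_failure:
        lines.append("*\ttraining failure: not eligible for comparison")
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> MetricsReport:
    """Recover a (display-precision) report from :func:`format_report`
    output."""
    values: dict[str, float | None] = {}
    failure = False
    for line in text.strip().splitlines():
        name, _, val = line.partition("\t")
        if name == "metric":
            continue
        if name == "*":
            failure = True
            continue
        if name in METRIC_NAMES:
            values[name] = None if val == "–" else float(val)
    missing = [m for m in METRIC_NAMES if m not in values]
    if missing:
        raise ValueError(f"report missing metrics: {missing}")
    return MetricsReport(**values, training_failure=failure)


def report_to_json(r: MetricsReport, path: str | None = None) -> str:
    """Serialize a report (full precision) to JSON; optionally write it."""
    doc = {m: r.value(m) for m in METRIC_NAMES}
    doc["training_failure"] = r.training_failure
    text = json.dumps(doc, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
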