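"""Confusion-count bookkeeping and binary performance measures.

Counts are kept as nonnegative reals rather than integers so that
rate-scaled counts (e.g., TP = sensitivity on a balanced dataset) are
admissible; all six measures are invariant to a positive rescaling of
the whole confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts (nonnegative reals)."""

    TP: float
    TN: float
    FP: float
    FN: float

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> float:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, accuracy, MCC, precision, F1."""

    SN: float
    SP: float
    ACC: float
    MCC: float
    precision: float
    F1: float

    def rounded(self, ndigits: int = 3) -> "MetricSet":
        """Report-style rounding (3 decimals by default); internal values
        stay at full precision."""
        return MetricSet(*(round(v, ndigits) for v in self.as_tuple()))

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.SN, self.SP, self.ACC, self.MCC, self.precision, self.F1)

    def as_dict(self) -> dict[str, float]:
        return {
            "SN": self.SN,
            "SP": self.SP,
            "ACC": self.ACC,
            "MCC": self.MCC,
            "precision": self.precision,
            "F1": self.F1,
        }


def _ratio(num: float, den: float) -> float:
    """num/den with the 0-denominator convention: undefined := 0."""
    return num / den if den > 0 else 0.0


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """The six binary measures from a confusion matrix.

    SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total,
    precision = TP/(TP+FP), F1 = 2·SN·precision/(SN+precision),
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Any measure with a zero denominator is defined as 0 (MCC included).
    """
    if counts.total <= 0:
        raise ValueError("confusion counts are all zero")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    acc = (tp + tn) / counts.total
    precision = _ratio(tp, tp + fp)
    f1 = _ratio(2 * sn * precision, sn + precision)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den)
    return MetricSet(SN=sn, SP=sp, ACC=acc, MCC=mcc, precision=precision, F1=f1)
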