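"""Confusion-count metrics, in both the verbatim and the standard forms.

The verbatim formula set used by this model family defines::

    verbatim_accuracy    = (TP + FP) / (TP + TN + FP + FN)
    verbatim_specificity = TP / (TP + FP)      # algebraically precision (PPV)
    sensitivity       = TP / (TP + FN)      # recall
    f1                = 2 * spec * sens / (spec + sens)

The accuracy numerator (TP + FP) is an evident typo — on balanced random
data it scores 0.5 — and "specificity" is algebraically precision, so the
standard definitions are also computed and reported side by side:
``standard_accuracy = (TP + TN)/n``, ``precision``, ``recall``,
``standard_specificity = TN/(TN + FP)``.  The verbatim f1 is identical to
the standard F1 of (precision, recall).  Wilson 95% intervals are attached
to each defined proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = ["ConfusionCounts", "MetricReport", "evaluate_metrics", "wilson_interval", "counts_from_predictions"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (float("nan"), float("nan"))
    z = norm.ppf(0.5 + confidence / 2)
    phat = successes / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    # at the boundaries the Wilson bound is exactly the observed proportion
    lo = 0.0 if successes == 0 else max(center - half, 0.0)
    hi = 1.0 if successes == n else min(center + half, 1.0)
    return (lo, hi)


@dataclass
class MetricReport:
    verbatim_accuracy: float | None
    verbatim_specificity: float | None  # = precision
    sensitivity: float | None  # = recall
    f1: float | None
    standard_accuracy: float | None
    precision: float | None
    recall: float | None
    standard_specificity: float | None
    undefined: list[str] = field(default_factory=list)
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "verbatim_accuracy": self.verbatim_accuracy,
            "verbatim_specificity": self.verbatim_specificity,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "standard_accuracy": self.standard_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "standard_specificity": self.standard_specificity,
            "undefined": list(self.undefined),
            "intervals": {k: list(v) for k, v in self.intervals.items()},
        }


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float | None:
    if den == 0:
        undefined.append(name)
        return None
    return num / den


def evaluate_metrics(counts: ConfusionCounts, confidence: float = 0.95) -> MetricReport:
    """Compute the verbatim and standard metric sets from confusion counts.

    Zero-denominator metrics are reported as ``None`` and listed in
    ``undefined`` rather than silently coerced to 0.
    """
    if counts.total < 1:
        raise ValueError("need at least one evaluated sample")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.total
    undefined: list[str] = []

    verbatim_accuracy = (tp + fp) / n
    precision = _ratio(tp, tp + fp, "verbatim_specificity", undefined)
    recall = _ratio(tp, tp + fn, "sensitivity", undefined)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
        undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    standard_accuracy = (tp + tn) / n
    standard_specificity = _ratio(tn, tn + fp, "standard_specificity", undefined)

    intervals = {
        "verbatim_accuracy": wilson_interval(tp + fp, n, confidence),
        "standard_accuracy": wilson_interval(tp + tn, n, confidence),
    }
    if precision is not None:
        intervals["precision"] = wilson_interval(tp, tp + fp, confidence)
    if recall is not None:
        intervals["sensitivity"] = wilson_interval(tp, tp + fn, confidence)
    if standard_specificity is not None:
        intervals["standard_specificity"] = wilson_interval(tn, tn + fp, confidence)

    return MetricReport(
        verbatim_accuracy=verbatim_accuracy,
        verbatim_specificity=precision,
        sensitivity=recall,
        f1=f1,
        standard_accuracy=standard_accuracy,
        precision=precision,
        recall=recall,
        standard_specificity=standard_specificity,
        undefined=undefined,
        intervals=intervals,
    )


def counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Binary confusion counts with class 1 = positive."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )
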