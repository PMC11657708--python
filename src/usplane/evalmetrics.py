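"""Per-class (one-vs-rest) and macro-averaged classification metrics.

Eight metrics per class: accuracy, specificity, sensitivity, precision,
F1, Matthews correlation coefficient (MCC), false rejection rate
FRR = FN/(TP+FN) and false acceptance rate FAR = FP/(TN+FP).  By
construction FRR = 1 - sensitivity and FAR = 1 - specificity.  Any 0/0
ratio is defined as 0.  The macro report is the unweighted arithmetic
mean across classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "METRIC_NAMES",
    "Confusion",
    "MetricsReport",
    "confusion_per_class",
    "metrics_from_confusion",
    "macro_report",
]

METRIC_NAMES = (
    "accuracy",
    "specificity",
    "sensitivity",
    "precision",
    "f1",
    "mcc",
    "frr",
    "far",
)


@dataclass(frozen=True)
class Confusion:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict
    macro: dict


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def confusion_per_class(truth, pred, c) -> Confusion:
    """One-vs-rest confusion counts for class ``c``."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have equal length")
    pos_t = truth == c
    pos_p = pred == c
    return Confusion(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def metrics_from_confusion(conf: Confusion) -> dict:
    """The eight metric values for one binary confusion."""
    if conf.n == 0:
        raise ValueError("empty confusion")
    tp, tn, fp, fn = conf.tp, conf.tn, conf.fp, conf.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    # FRR = FN/(TP+FN) is computed as 1 - sensitivity (identical value,
    # exact in floating point); likewise FAR = 1 - specificity.
    return {
        "accuracy": _ratio(tp + tn, conf.n),
        "specificity": spec,
        "sensitivity": sens,
        "precision": prec,
        "f1": _ratio(2.0 * prec * sens, prec + sens),
        "mcc": _ratio(tp * tn - fp * fn, mcc_den),
        "frr": 1.0 - sens if tp + fn > 0 else 0.0,
        "far": 1.0 - spec if tn + fp > 0 else 0.0,
    }


def macro_report(truth, pred, classes: Sequence | None = None) -> MetricsReport:
    """Per-class metrics plus their unweighted mean.

    Classes listed but absent from ``truth`` are flagged (warning) and
    excluded from the macro average.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if classes is None:
        classes = sorted(np.unique(np.concatenate([truth, pred])).tolist())
    present = set(np.unique(truth).tolist())
    missing = [c for c in classes if c not in present]
    if not set(np.unique(truth)) <= set(classes):
        raise ValueError("classes does not cover all labels present in truth")
    if missing:
        warnings.warn(
            f"classes absent from truth excluded from macro average: {missing}",
            stacklevel=2,
        )
    per_class = {}
    for c in classes:
        if c in present:
            per_class[c] = metrics_from_confusion(confusion_per_class(truth, pred, c))
        else:
            per_class[c] = None
    valid = [m for m in per_class.values() if m is not None]
    macro = {name: float(np.mean([m[name] for m in valid])) for name in METRIC_NAMES}
    return MetricsReport(per_class=per_class, macro=macro)
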