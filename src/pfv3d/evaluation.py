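"""One-vs-rest confusion counts and classification metrics.

Per class: accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity (recall) =
TP/(TP+FN), specificity = TN/(TN+FP), precision = TP/(TP+FP) and
F1 = 2·precision·recall/(precision+recall).  Every 0/0 case is defined as 0
(logged), so reports never contain undefined entries.  Macro metrics are the
unweighted mean over classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "ClassCounts",
    "ConfusionCounts",
    "EvalReport",
    "confusion_from_labels",
    "compute_metrics",
]

logger = logging.getLogger(__name__)

_METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ClassCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class."""

    per_class: dict[object, ClassCounts]

    def __post_init__(self) -> None:
        totals = {c.total for c in self.per_class.values()}
        if len(totals) > 1:
            raise ValueError(
                f"per-class totals disagree ({sorted(totals)}); every class "
                "must count the same evaluation set"
            )


@dataclass(frozen=True)
class EvalReport:
    """Per-class and macro-averaged metrics, all fractions in [0, 1]."""

    per_class: dict[object, dict[str, float]]
    macro: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {"per_class": {str(k): v for k, v in self.per_class.items()},
             "macro": self.macro},
            indent=2,
        )

    def to_table(self) -> str:
        """Plain-text table: one row per class plus a macro row."""
        header = ["class"] + list(_METRICS)
        rows = [header]
        for label, metrics in self.per_class.items():
            rows.append([str(label)] + [f"{metrics[m]:.4f}" for m in _METRICS])
        rows.append(["macro"] + [f"{self.macro[m]:.4f}" for m in _METRICS])
        widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
        lines = ["  ".join(cell.ljust(w) for cell, w in zip(r, widths)) for r in rows]
        lines.insert(1, "  ".join("-" * w for w in widths))
        return "\n".join(lines)


def confusion_from_labels(true_labels: Sequence, predicted_labels: Sequence,
                          class_list: Sequence) -> ConfusionCounts:
    """Count one-vs-rest TP/TN/FP/FN for every class in ``class_list``."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label sequences differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    if not true_labels:
        raise ValueError("empty label sequences")
    known = set(class_list)
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}; classes are {sorted(map(str, known))}")
    per_class = {}
    for cls in class_list:
        tp = sum(1 for t, p in zip(true_labels, predicted_labels) if t == cls and p == cls)
        fn = sum(1 for t, p in zip(true_labels, predicted_labels) if t == cls and p != cls)
        fp = sum(1 for t, p in zip(true_labels, predicted_labels) if t != cls and p == cls)
        tn = len(true_labels) - tp - fn - fp
        per_class[cls] = ClassCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return ConfusionCounts(per_class=per_class)


def _ratio(num: float, den: float, name: str, cls) -> float:
    if den == 0:
        logger.info("metric %s for class %r is 0/0; defined as 0", name, cls)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> EvalReport:
    """Derive per-class and macro metrics from confusion counts."""
    per_class = {}
    for cls, k in c.per_class.items():
        accuracy = _ratio(k.tp + k.tn, k.total, "accuracy", cls)
        sensitivity = _ratio(k.tp, k.tp + k.fn, "sensitivity", cls)
        specificity = _ratio(k.tn, k.tn + k.fp, "specificity", cls)
        precision = _ratio(k.tp, k.tp + k.fp, "precision", cls)
        if precision + sensitivity == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * sensitivity / (precision + sensitivity)
        per_class[cls] = {
            "accuracy": accuracy,
            "sensitivity": sensitivity,
            "specificity": specificity,
            "precision": precision,
            "f1": f1,
        }
    n = len(per_class)
    macro = {
        m: sum(v[m] for v in per_class.values()) / n for m in _METRICS
    }
    return EvalReport(per_class=per_class, macro=macro)
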