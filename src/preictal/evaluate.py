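"""Classification metrics: sensitivity, specificity, accuracy.

Preictal is the positive class. With P = TP + FN positives and N = TN + FP
negatives,

    SS  = 100 * TP / P          (sensitivity, true positive rate)
    SP  = 100 * TN / N          (specificity, true negative rate)
    Acc = 100 * (TP + TN) / (P + N)

On a balanced set (P = N) the accuracy equals (SS + SP) / 2; the report
flags any set where the printed accuracy and that identity disagree beyond
display rounding, rather than silently reconciling them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round2(x: float) -> float:
    """Round half-up to 2 decimals, matching conventional table formatting."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    split_name: str = ""
    subject_id: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / self.p if self.p else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / self.n if self.n else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.p + self.n
        return 100.0 * (self.tp + self.tn) / total if total else float("nan")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "split": self.split_name,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": round2(self.sensitivity) if self.p else None,
            "specificity": round2(self.specificity) if self.n else None,
            "accuracy": round2(self.accuracy),
            "flags": list(self.flags),
        }


def score(
    predictions, truth, split_name: str = "", subject_id: str = ""
) -> MetricsReport:
    """Confusion counts and metrics from binary label vectors (1 = preictal)."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(truth, dtype=int)
    if pred.shape != y.shape or pred.ndim != 1:
        raise ValueError("predictions and truth must be equal-length 1-D vectors")
    if len(y) == 0:
        raise ValueError("cannot score an empty label set")
    if not (set(np.unique(pred)) <= {0, 1} and set(np.unique(y)) <= {0, 1}):
        raise ValueError("labels must be in {0, 1}")
    rep = MetricsReport(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        split_name=split_name,
        subject_id=subject_id,
    )
    if rep.p == 0:
        rep.flags.append("no positive (preictal) samples: sensitivity undefined")
    if rep.n == 0:
        rep.flags.append("no negative (interictal) samples: specificity undefined")
    if rep.p and rep.n and rep.p != rep.n:
        rep.flags.append(
            f"classes imbalanced (P={rep.p}, N={rep.n}): accuracy differs from (SS+SP)/2"
        )
    return rep


def aggregate(reports: list[MetricsReport]) -> dict:
    """Unweighted across-subject means of SS, SP and Acc, 2-decimal display.

    The averaging is deliberately unweighted (each subject counts equally,
    regardless of its seizure count).
    """
    if not reports:
        raise ValueError("need at least one report to aggregate")
    summary = {
        "n_subjects": len(reports),
        "sensitivity": round2(float(np.mean([r.sensitivity for r in reports]))),
        "specificity": round2(float(np.mean([r.specificity for r in reports]))),
        "accuracy": round2(float(np.mean([r.accuracy for r in reports]))),
        "per_subject": [r.to_dict() for r in reports],
    }
    flags = [f"{r.subject_id}: {msg}" for r in reports for msg in r.flags]
    if flags:
        summary["flags"] = flags
    return summary


def balanced_accuracy_identity(ss: float, sp: float) -> float:
    """Accuracy implied by SS and SP on a balanced set: (SS + SP) / 2."""
    return (ss + sp) / 2.0
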