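"""Scoring of binning output against ground truth.

Precision is computed over assigned reads only — withholding a read below the
confidence threshold is abstention, not error — and the unassigned rate is
reported separately. Decoy reads (true populations absent from the training
anchors) assigned to ANY class count as false positives: that is the
operational meaning this package gives to minimizing false positives while
maximizing true positives when calibrating the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

UNASSIGNED = "unassigned"


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits; symmetric, in [0, 1].

    Zero components contribute 0·log 0 = 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must have the same shape")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("profiles must be non-negative")
    d = float(jensenshannon(p, q, base=2) ** 2)
    # jensenshannon returns the distance (sqrt of the divergence)
    return min(max(d, 0.0), 1.0)


@dataclass(frozen=True)
class ClassScores:
    precision: float | None  # None when no read was assigned to the class
    recall: float
    f1: float | None
    n_true: int
    n_assigned: int


@dataclass(frozen=True)
class BinReport:
    per_class: dict[str, ClassScores]
    macro_precision: float | None
    macro_recall: float
    macro_f1: float | None
    unassigned_rate: float
    decoy_fpr: float | None      # None when the truth contains no decoy reads
    n_reads: int
    confusion: pd.DataFrame      # rows: true labels (+decoys); cols: classes + unassigned

    def to_dict(self) -> dict:
        return {
            "per_class": {
                k: {
                    "precision": v.precision,
                    "recall": v.recall,
                    "f1": v.f1,
                    "n_true": v.n_true,
                    "n_assigned": v.n_assigned,
                }
                for k, v in self.per_class.items()
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "unassigned_rate": self.unassigned_rate,
            "decoy_fpr": self.decoy_fpr,
            "n_reads": self.n_reads,
        }


def evaluate_bins(
    assignment: dict[str, str],
    truth: dict[str, str],
    model_classes: list[str] | None = None,
) -> BinReport:
    """Score read->label assignments against complete ground truth.

    ``assignment`` maps read_id to predicted label; reads absent from it are
    unassigned. ``truth`` must cover every assigned read. True labels outside
    the assignable classes are decoys; their row in the confusion matrix has
    no matching column, and any assignment of a decoy read is a false
    positive.
    """
    missing = sorted(set(assignment) - set(truth))
    if missing:
        raise ValueError(f"truth missing read ids: {missing[:10]}" +
                         (" ..." if len(missing) > 10 else ""))
    if model_classes is None:
        model_classes = sorted(set(assignment.values()))
    class_set = set(model_classes)
    true_labels = sorted(set(truth.values()))
    cols = list(model_classes) + [UNASSIGNED]
    conf = pd.DataFrame(0, index=true_labels, columns=cols, dtype=int)
    for rid, true_lab in truth.items():
        pred = assignment.get(rid, UNASSIGNED)
        conf.loc[true_lab, pred] += 1

    per_class: dict[str, ClassScores] = {}
    for k in model_classes:
        tp = int(conf.loc[k, k]) if k in conf.index else 0
        n_assigned = int(conf[k].sum())
        n_true = int(conf.loc[k].sum()) if k in conf.index else 0
        precision = tp / n_assigned if n_assigned > 0 else None
        recall = tp / n_true if n_true > 0 else 0.0
        if precision is None or precision + recall == 0:
            f1 = None if precision is None else 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        per_class[k] = ClassScores(precision, recall, f1, n_true, n_assigned)

    precisions = [s.precision for s in per_class.values() if s.precision is not None]
    f1s = [s.f1 for s in per_class.values() if s.f1 is not None]
    macro_precision = float(np.mean(precisions)) if precisions else None
    macro_recall = float(np.mean([s.recall for s in per_class.values()]))
    macro_f1 = float(np.mean(f1s)) if f1s else None

    n_reads = len(truth)
    n_unassigned = int(conf[UNASSIGNED].sum())
    decoy_rows = [lab for lab in true_labels if lab not in class_set]
    if decoy_rows:
        decoy_total = int(conf.loc[decoy_rows].sum().sum())
        decoy_assigned = decoy_total - int(conf.loc[decoy_rows, UNASSIGNED].sum())
        decoy_fpr = decoy_assigned / decoy_total if decoy_total else None
    else:
        decoy_fpr = None

    return BinReport(
        per_class=per_class,
        macro_precision=macro_precision,
        macro_recall=macro_recall,
        macro_f1=macro_f1,
        unassigned_rate=n_unassigned / n_reads if n_reads else 0.0,
        decoy_fpr=decoy_fpr,
        n_reads=n_reads,
        confusion=conf,
    )
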