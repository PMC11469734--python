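"""Prediction metrics and run-level aggregation.

Per-task F1 (macro over the item's declared classes for multinomial
items, positive-class F1 for binary items), the item-averaged overall
F1, the multi-task performance improvement (MPI) score -- the fraction
of tasks on which a candidate's F1 strictly exceeds a reference's --
and mean/STD/95% CI aggregation over repeated-split runs.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import f1_score

from .profiles import ItemSpec

__all__ = ["task_f1", "overall_f1", "mpi_score", "aggregate_runs", "normal_ci"]


def task_f1(true_classes, predicted_classes, item: ItemSpec, positive_class: int = 1) -> float:
    """F1 for one item's predictions (class indices 0..K-1).

    Multinomial items use the unweighted mean of per-class F1 over every
    declared class (a class absent from both truth and prediction
    contributes 0).  Binary items use the F1 of the positive class,
    which is by convention the higher level (index 1).
    """
    t = np.asarray(true_classes)
    p = np.asarray(predicted_classes)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("truth and prediction must be equal-length non-empty vectors")
    if item.kind == "binary":
        return float(f1_score(t, p, pos_label=positive_class, zero_division=0))
    labels = list(range(item.n_classes))
    return float(f1_score(t, p, labels=labels, average="macro", zero_division=0))


def overall_f1(per_task_f1) -> float:
    """Arithmetic mean of per-item F1 scores."""
    v = np.asarray(list(per_task_f1), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one task F1")
    return float(v.mean())


def mpi_score(f1_candidate, f1_reference) -> float:
    """Fraction of tasks where the candidate strictly beats the reference."""
    a = np.asarray(list(f1_candidate), dtype=float)
    b = np.asarray(list(f1_reference), dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("candidate and reference must be equal-length vectors")
    return float(np.mean(a > b))


def normal_ci(mean: float, std: float, n: int) -> tuple[float, float]:
    """95% normal-approximation CI: mean +/- 1.96 * std / sqrt(n)."""
    half = 1.96 * std / np.sqrt(n)
    return float(mean - half), float(mean + half)


def aggregate_runs(values) -> dict[str, float]:
    """Mean, sample STD and 95% CI of a per-seed metric."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 runs to aggregate")
    mean = float(v.mean())
    std = float(v.std(ddof=1))
    lo, hi = normal_ci(mean, std, v.size)
    return {"mean": mean, "std": std, "ci_low": lo, "ci_high": hi, "n": int(v.size)}
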