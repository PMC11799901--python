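"""Tolerance-based PSQA verdicts, confusion counts, and sensitivity.

A QA comparison declares an sCT *acceptable* (the positive class) when the
metric falls inside the tolerance: point metrics (mean error, DVH deltas,
both in % of prescription) accept iff |value| <= tolerance (inclusive,
default +/-1%); the gamma pass rate accepts iff it is >= the floor
(inclusive, default 90%).

Verdicts obtained against a QA reference are scored against the verdicts
obtained against the ground-truth CT:

    TP = QA accepts and CT accepts      FN = QA rejects and CT accepts
    FP = QA accepts and CT rejects      TN = QA rejects and CT rejects

Sensitivity = TP / (TP + FN): the fraction of truly acceptable sCTs that
the QA reference also accepts.  Specificity = TN / (TN + FP) is reported
too, as a missing value whenever its denominator is empty (true rejections
are rare in practice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

__all__ = [
    "ToleranceSet",
    "Verdict",
    "ConfusionCounts",
    "apply_tolerance",
    "confusion",
    "sensitivity",
    "specificity",
]

Decision = Literal["accept", "reject"]


@dataclass(frozen=True)
class ToleranceSet:
    """Tolerance limits: +/-% for point metrics, a floor for gamma."""

    point_metric_tolerance: float = 1.0  # % of prescription
    gamma_pass_floor: float = 90.0  # %

    def __post_init__(self) -> None:
        if self.point_metric_tolerance <= 0:
            raise ValueError("point_metric_tolerance must be > 0")
        if not 0.0 < self.gamma_pass_floor <= 100.0:
            raise ValueError("gamma_pass_floor must be in (0, 100]")


@dataclass(frozen=True)
class Verdict:
    """One tolerance decision; determined solely by value, kind, tolerance."""

    patient_id: int
    metric: str
    value: float
    decision: Decision


def apply_tolerance(
    value: float,
    metric_kind: Literal["point_percent", "gamma_rate"],
    tol: ToleranceSet | None = None,
) -> Decision:
    """Accept/reject one metric value; boundaries are inclusive."""
    tol = tol or ToleranceSet()
    if metric_kind == "point_percent":
        return "accept" if abs(value) <= tol.point_metric_tolerance else "reject"
    if metric_kind == "gamma_rate":
        return "accept" if value >= tol.gamma_pass_floor else "reject"
    raise ValueError(f"unknown metric kind {metric_kind!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(
    reference_verdicts: Mapping[int, Decision],
    qa_verdicts: Mapping[int, Decision],
) -> ConfusionCounts:
    """Score per-patient QA decisions against the reference (CT) decisions.

    Both mappings must cover the same patient set: a QA generator that
    refuses some patients (e.g. automatic artifact rejection) must have
    them excluded from *both* sides before counting.
    """
    if set(reference_verdicts) != set(qa_verdicts):
        only_ref = set(reference_verdicts) - set(qa_verdicts)
        only_qa = set(qa_verdicts) - set(reference_verdicts)
        raise ValueError(
            f"patient sets differ (only in reference: {sorted(only_ref)}, "
            f"only in QA: {sorted(only_qa)}); exclude refused patients from both sides"
        )
    tp = fn = fp = tn = 0
    for pid, ref in reference_verdicts.items():
        qa = qa_verdicts[pid]
        if qa == "accept" and ref == "accept":
            tp += 1
        elif qa == "reject" and ref == "accept":
            fn += 1
        elif qa == "accept" and ref == "reject":
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def sensitivity(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None (missing) when no condition-positive patients."""
    if counts.tp + counts.fn == 0:
        return None
    return counts.tp / (counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None (missing) when no condition-negative patients."""
    if counts.tn + counts.fp == 0:
        return None
    return counts.tn / (counts.tn + counts.fp)
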