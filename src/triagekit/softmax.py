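"""Empirical triage on estimated soft-max scores.

The oracle rule thresholds the true winning-class probability; in practice
one only has the soft-max output q(a_k | x) of an upstream classifier.  When
the soft-max is a monotone increasing transform of the true conditionals
(M-consistency), thresholding the per-row maximum score recovers the optimal
decision set, so the same finite-sample machinery applies: fit a threshold to
a refusal budget epsilon, sweep thresholds to trace the precision-coverage
curve, or invert that curve to hit a target precision.  The class-count
filter implements the pragmatic refinement of refusing any class that is too
rare in training to be well characterized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    REFUSE,
    CondProbMatrix,
    TriageLoss,
    TriageResult,
    TriageRule,
    _argmax_lowest_index,
    _refusal_order_and_count,
    triage_loss,
)

__all__ = [
    "ScoreMatrix",
    "PrecisionCoverageCurve",
    "PrecisionTarget",
    "fit_threshold",
    "apply_triage",
    "precision_coverage_curve",
    "threshold_for_precision",
    "class_error_by_count",
    "min_count_filter",
]


@dataclass(frozen=True)
class ScoreMatrix(CondProbMatrix):
    """Estimated per-item class scores (soft-max output of any classifier).

    Same shape and invariants as :class:`~triagekit.core.CondProbMatrix` but
    the entries are estimates q(a_k | x_i), not assumed equal to the true
    conditionals; the row-sum tolerance is loosened to 1e-6 accordingly.
    """

    row_tol: float = 1e-6


@dataclass(frozen=True)
class PrecisionCoverageCurve:
    """Precision (and joint loss) as a function of the fraction classified.

    One point per distinct max-score threshold, ordered by decreasing
    coverage; the first point (threshold 0) classifies everything.
    """

    points: pd.DataFrame  # columns: threshold, coverage, precision, joint_loss

    def __post_init__(self) -> None:
        required = ["threshold", "coverage", "precision", "joint_loss"]
        if list(self.points.columns) != required:
            raise ValueError(f"curve columns must be {required}")

    def to_frame(self) -> pd.DataFrame:
        return self.points.copy()


@dataclass(frozen=True)
class PrecisionTarget:
    """Outcome of inverting the precision-coverage curve at a target precision.

    ``attainable`` is False — and ``rule`` is None — when no threshold reaches
    the target, an explicit signal rather than an exception or a fake rule.
    """

    attainable: bool
    target_precision: float
    rule: TriageRule | None = None
    threshold: float | None = None
    coverage: float | None = None
    precision: float | None = None


def fit_threshold(scores: ScoreMatrix, epsilon: float) -> TriageRule:
    """Fit a refusal threshold to budget ``epsilon`` on a score matrix.

    Applies the finite-sample rule of the oracle side to the per-row score
    maxima: refuse the smallest-maximum rows up to mass epsilon, and record
    the largest threshold b realizing that refusal set via {max score > b}.
    The fitted rule may be applied to the same scores (in-sample, as when
    reproducing a precision-coverage operating point) or to fresh ones.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon={epsilon!r} outside [0, 1]")
    if scores.n_items == 0:
        raise ValueError("cannot fit a threshold on an empty score matrix")
    maxima = scores.row_maxima()
    order, n_refused = _refusal_order_and_count(maxima, scores.weights, epsilon)
    threshold_b = float(maxima[order[n_refused - 1]]) if n_refused else 0.0
    return TriageRule(
        threshold_b=threshold_b, labels=list(scores.labels), epsilon=epsilon
    )


def apply_triage(scores: ScoreMatrix, rule: TriageRule) -> TriageResult:
    """Apply a fitted rule: refuse on low max-score or a masked winning class."""
    if list(scores.labels) != list(rule.labels):
        missing = sorted(set(rule.labels) - set(scores.labels))
        extra = sorted(set(scores.labels) - set(rule.labels))
        raise ValueError(
            "score columns do not match the rule's labels"
            + (f"; missing {missing}" if missing else "")
            + (f"; unexpected {extra}" if extra else "")
            + ("; label order differs" if not missing and not extra else "")
        )
    maxima = scores.row_maxima()
    argmax_idx = _argmax_lowest_index(scores.values)
    labels_arr = np.asarray(scores.labels, dtype=object)
    argmax_label = labels_arr[argmax_idx]
    decided = (maxima > rule.threshold_b) & rule.class_mask[argmax_idx]
    decisions = np.where(decided, argmax_label, REFUSE).astype(object)
    return TriageResult(
        decisions=decisions, decided=decided, argmax_label=argmax_label
    )


def _loss_at_threshold(
    scores: ScoreMatrix, rule: TriageRule, truth: Sequence
) -> TriageLoss:
    return triage_loss(apply_triage(scores, rule), truth, scores.weights)


def precision_coverage_curve(
    scores: ScoreMatrix, truth: Sequence
) -> PrecisionCoverageCurve:
    """Sweep the refusal threshold and record coverage, precision, joint loss.

    Thresholds run over the sorted distinct per-row maxima plus a zero
    endpoint (full coverage), so the curve is exact for the sample; points
    are ordered by decreasing coverage, which is strictly decreasing along
    the sweep.
    """
    truth_arr = np.asarray([str(t) for t in truth], dtype=object)
    if truth_arr.shape[0] != scores.n_items:
        raise ValueError(
            f"truth has length {truth_arr.shape[0]} for {scores.n_items} rows"
        )
    maxima = scores.row_maxima()
    thresholds = np.concatenate([[0.0], np.unique(maxima)])
    rows = []
    for b in thresholds:
        rule = TriageRule(threshold_b=float(b), labels=list(scores.labels))
        loss = _loss_at_threshold(scores, rule, truth_arr)
        rows.append((float(b), loss.coverage, loss.precision, loss.joint_loss))
    frame = pd.DataFrame(
        rows, columns=["threshold", "coverage", "precision", "joint_loss"]
    )
    return PrecisionCoverageCurve(points=frame)


def threshold_for_precision(
    scores: ScoreMatrix, truth: Sequence, target_precision: float
) -> PrecisionTarget:
    """Smallest-threshold (maximal-coverage) rule reaching a target precision.

    Ties resolve in favor of maximal coverage — the operating point that
    auto-classifies the most items at the required precision, minimizing the
    manual workload on the refused remainder.  Coverage-zero points (where
    precision is undefined) never qualify.
    """
    if not 0.0 <= target_precision <= 1.0:
        raise ValueError(
            f"target_precision={target_precision!r} outside [0, 1]"
        )
    curve = precision_coverage_curve(scores, truth).points
    ok = curve[
        (curve["coverage"] > 0) & (curve["precision"] >= target_precision)
    ]
    if ok.empty:
        return PrecisionTarget(attainable=False, target_precision=target_precision)
    best = ok.loc[ok["coverage"].idxmax()]
    rule = TriageRule(
        threshold_b=float(best["threshold"]), labels=list(scores.labels)
    )
    return PrecisionTarget(
        attainable=True,
        target_precision=target_precision,
        rule=rule,
        threshold=float(best["threshold"]),
        coverage=float(best["coverage"]),
        precision=float(best["precision"]),
    )


def class_error_by_count(
    result: TriageResult,
    truth: Sequence,
    counts: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """Per-true-class error rate among decided items, with training counts.

    Returns one row per true class: ``count`` (training examples),
    ``n_decided``, ``n_errors`` and ``error_rate``; classes with no decided
    item get a NaN rate.  Classes rarely seen in training tend to show the
    highest rates, which motivates the min-count filter.
    """
    truth_arr = np.asarray([str(t) for t in truth], dtype=object)
    if truth_arr.shape[0] != result.n_items:
        raise ValueError("truth length must match decisions")
    counts_map = dict(counts.items()) if hasattr(counts, "items") else dict(counts)
    missing = sorted(set(truth_arr) - {str(k) for k in counts_map})
    if missing:
        raise ValueError(f"no training count for true class(es) {missing}")
    rows = []
    for label in sorted(set(truth_arr), key=list(truth_arr).index):
        of_class = truth_arr == label
        decided = of_class & result.decided
        n_decided = int(decided.sum())
        n_errors = int((decided & (result.decisions != truth_arr)).sum())
        rate = n_errors / n_decided if n_decided else float("nan")
        rows.append((label, int(counts_map[label]), n_decided, n_errors, rate))
    return pd.DataFrame(
        rows, columns=["label", "count", "n_decided", "n_errors", "error_rate"]
    ).set_index("label")


def min_count_filter(
    counts: Mapping[str, int] | pd.Series,
    min_count: int,
    labels: Sequence[str],
) -> np.ndarray:
    """Class mask retaining only classes with >= ``min_count`` training examples.

    Composing the mask into a rule (``rule.with_mask``) makes the triage
    refuse any item whose winning class is too rare; the realized coverage
    then drops below 1 - epsilon and is always reported as such rather than
    silently re-normalized.  Typical operating cutoffs are 100, 500, 1000.
    """
    if min_count < 0:
        raise ValueError(f"min_count={min_count!r} must be >= 0")
    counts_map = dict(counts.items()) if hasattr(counts, "items") else dict(counts)
    mask = np.zeros(len(labels), dtype=bool)
    for j, label in enumerate(labels):
        c = counts_map.get(str(label), 0)
        if c < 0:
            raise ValueError(f"negative count for class {label!r}")
        mask[j] = c >= min_count
    return mask
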