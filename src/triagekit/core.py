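"""Oracle-side triage: the Bayes classifier and the optimal epsilon-refusal rule.

A classifier that must label every item can do no better than the Bayes
classifier, whose error is the Bayes risk.  A *triage* rule is allowed to
refuse a fraction of items (routing them to a human expert) and is only
charged for errors on the items it does label.  Given the true conditional
class probabilities p(a_k | x), the optimal rule with refusal budget
epsilon labels an item exactly when its winning-class probability
max_k p(a_k | x) exceeds a threshold b, chosen as large as the coverage
constraint P[labeled] >= 1 - epsilon allows, and assigns the Bayes label on
the labeled set.  This module implements that rule on finite samples, the
joint loss / precision / coverage functional, and the two-class
specialization in which the refusal region is a likelihood-ratio band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "REFUSE",
    "CondProbMatrix",
    "TriageRule",
    "TriageResult",
    "TriageLoss",
    "BinaryBand",
    "bayes_classify",
    "optimal_triage",
    "triage_loss",
    "binary_ratio_band",
]

#: Sentinel emitted for refused items ("no classification"). Reserved: it may
#: never appear as a class label.
REFUSE = "REFUSE"

#: Mass tolerance when accumulating refusals against the epsilon budget.
#: Guards against floating-point drift in cumulative sums of uniform weights
#: (e.g. 3 * (1/10) > 0.3), so a budget of epsilon = k/n refuses exactly k
#: uniform-weight items.
_BUDGET_RTOL = 1e-9
_BUDGET_ATOL = 1e-12


def _as_labels(labels: Sequence) -> list[str]:
    out = [str(lab) for lab in labels]
    if len(set(out)) != len(out):
        raise ValueError(f"duplicate class labels: {out}")
    if REFUSE in out:
        raise ValueError(
            f"class label {REFUSE!r} collides with the refusal sentinel"
        )
    return out


@dataclass(frozen=True)
class CondProbMatrix:
    """True conditional class probabilities for n items over m classes.

    ``values[i, k]`` is p(a_k | x_i).  ``weights`` carry the probability mass
    of each item (a Monte-Carlo stand-in for the feature density f(x) dx) and
    default to uniform 1/n.
    """

    values: np.ndarray
    labels: list[str]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    #: row-sum tolerance; exact conditionals are computed, not exported
    row_tol: float = 1e-9

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] < 2:
            raise ValueError(
                f"expected an n x m matrix with m >= 2, got shape {values.shape}"
            )
        if values.shape[0] == 0:
            raise ValueError("the matrix must contain at least one item row")
        labels = _as_labels(self.labels)
        if len(labels) != values.shape[1]:
            raise ValueError(
                f"{len(labels)} labels for {values.shape[1]} columns"
            )
        if np.any(values < 0) or np.any(values > 1):
            bad = int(np.argwhere((values < 0) | (values > 1))[0, 0])
            raise ValueError(f"entries outside [0, 1] (first offending row {bad})")
        sums = values.sum(axis=1)
        off = np.abs(sums - 1.0) > self.row_tol
        if np.any(off):
            bad = int(np.argmax(off))
            raise ValueError(
                f"row {bad} sums to {sums[bad]!r}, not 1 within {self.row_tol}"
            )
        if self.weights is None:
            weights = np.full(values.shape[0], 1.0 / values.shape[0])
        else:
            weights = np.asarray(self.weights, dtype=float)
            if weights.shape != (values.shape[0],):
                raise ValueError("weights must be one scalar per row")
            if np.any(weights < 0):
                raise ValueError("weights must be non-negative")
            total = weights.sum()
            if not np.isclose(total, 1.0, rtol=0, atol=1e-9):
                raise ValueError(f"weights sum to {total!r}, not 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "weights", weights)

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def row_maxima(self) -> np.ndarray:
        """max_k p(a_k | x_i), the winning-class probability per item."""
        return self.values.max(axis=1)


@dataclass(frozen=True)
class TriageRule:
    """A fitted refusal rule: threshold, class mask, and the budget it serves.

    An item is labeled iff its maximal score strictly exceeds ``threshold_b``
    and its winning class is unmasked; ties between classes go to the lowest
    column index.
    """

    threshold_b: float
    labels: list[str]
    class_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    epsilon: float | None = None
    tie_break: str = "lowest-index"

    def __post_init__(self) -> None:
        labels = _as_labels(self.labels)
        if not 0.0 <= self.threshold_b <= 1.0:
            raise ValueError(f"threshold_b={self.threshold_b!r} outside [0, 1]")
        if self.tie_break != "lowest-index":
            raise ValueError("only the lowest-index tie-break is supported")
        if self.class_mask is None:
            mask = np.ones(len(labels), dtype=bool)
        else:
            mask = np.asarray(self.class_mask, dtype=bool)
            if mask.shape != (len(labels),):
                raise ValueError("class_mask length must match labels")
            if not mask.any():
                raise ValueError("at least one class must remain unmasked")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_mask", mask)

    def with_mask(self, class_mask: np.ndarray) -> "TriageRule":
        """Return a copy with ``class_mask`` replaced (e.g. a min-count filter)."""
        return replace(self, class_mask=np.asarray(class_mask, dtype=bool))


@dataclass(frozen=True)
class TriageResult:
    """Per-item decisions: label or REFUSE, plus the Z* / Y* factorization.

    ``decisions[i] == argmax_label[i]`` wherever ``decided[i]`` — the triage
    rule is the Bayes/plug-in classifier restricted to its decision set.
    """

    decisions: np.ndarray
    decided: np.ndarray
    argmax_label: np.ndarray

    def __post_init__(self) -> None:
        decisions = np.asarray(self.decisions, dtype=object)
        decided = np.asarray(self.decided, dtype=bool)
        argmax_label = np.asarray(self.argmax_label, dtype=object)
        if not (decisions.shape == decided.shape == argmax_label.shape):
            raise ValueError("decision vectors must share one length")
        if not np.array_equal(decisions == REFUSE, ~decided):
            raise ValueError("decisions must be REFUSE exactly where undecided")
        if not np.array_equal(decisions[decided], argmax_label[decided]):
            raise ValueError("decided items must carry their argmax label")
        object.__setattr__(self, "decisions", decisions)
        object.__setattr__(self, "decided", decided)
        object.__setattr__(self, "argmax_label", argmax_label)

    @property
    def n_items(self) -> int:
        return self.decisions.shape[0]


@dataclass(frozen=True)
class TriageLoss:
    """Joint loss, precision and coverage of a triage result against truth.

    ``joint_loss`` is the mass of items that are labeled AND mislabeled,
    normalized by total mass (refusals are unpenalized); ``coverage`` is the
    labeled mass; ``precision = 1 - joint_loss / coverage`` is the conditional
    accuracy on the decision set, NaN when nothing is labeled.
    """

    joint_loss: float
    precision: float
    coverage: float


@dataclass(frozen=True)
class BinaryBand:
    """Two-class refusal band: refuse iff 1/b' <= p(1|x)/p(0|x) <= b'."""

    ratio_bound_bprime: float

    def __post_init__(self) -> None:
        if self.ratio_bound_bprime < 1.0:
            raise ValueError("ratio bound must be >= 1")

    def refuse_mask(self, probs: CondProbMatrix) -> np.ndarray:
        """Refusal indicator for each row of a 2-class probability matrix."""
        if probs.n_classes != 2:
            raise ValueError("the ratio band applies to two-class problems only")
        p0 = probs.values[:, 0]
        p1 = probs.values[:, 1]
        b = self.ratio_bound_bprime
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p0 > 0, p1 / p0, np.inf)
        return (ratio >= 1.0 / b) & (ratio <= b)


def _argmax_lowest_index(values: np.ndarray) -> np.ndarray:
    # np.argmax returns the first maximal index, which is the required
    # lowest-index tie-break.
    return np.argmax(values, axis=1)


def bayes_classify(probs: CondProbMatrix) -> np.ndarray:
    """Label each item with its maximal-probability class.

    Ties go to the class with the smallest column index, so the induced sets
    partition the feature space.
    """
    idx = _argmax_lowest_index(probs.values)
    return np.asarray(probs.labels, dtype=object)[idx]


def _refusal_order_and_count(
    maxima: np.ndarray, weights: np.ndarray, epsilon: float
) -> tuple[np.ndarray, int]:
    """Stable ascending order of row maxima and how many fit the budget.

    Items are refused smallest-maximum first; exact ties at the cut keep their
    original row order and only as many tied items are refused as the mass
    budget epsilon allows (the coverage constraint is one-sided).
    """
    order = np.argsort(maxima, kind="stable")
    cum = np.cumsum(weights[order])
    budget = epsilon * (1.0 + _BUDGET_RTOL) + _BUDGET_ATOL
    n_refused = int(np.searchsorted(cum, budget, side="right"))
    return order, n_refused


def optimal_triage(
    probs: CondProbMatrix, epsilon: float
) -> tuple[TriageRule, TriageResult]:
    """Optimal epsilon-budget triage on known conditional probabilities.

    Refuses the items with the smallest winning-class probability, up to
    refused mass epsilon (maximal refusal within the budget, the
    loss-minimizing choice), and labels the rest with the Bayes classifier.
    Returns the fitted rule — carrying the realized threshold b, the largest
    value keeping labeled mass >= 1 - epsilon — together with the decisions.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon={epsilon!r} outside [0, 1]")
    maxima = probs.row_maxima()
    order, n_refused = _refusal_order_and_count(maxima, probs.weights, epsilon)

    decided = np.ones(probs.n_items, dtype=bool)
    decided[order[:n_refused]] = False
    # Realized threshold: the largest refused maximum; {max > b} then refuses
    # every refused item (plus any exact ties, which the stable order may
    # instead label to honor the one-sided budget).
    threshold_b = float(maxima[order[n_refused - 1]]) if n_refused else 0.0

    labels_arr = np.asarray(probs.labels, dtype=object)
    argmax_label = labels_arr[_argmax_lowest_index(probs.values)]
    decisions = np.where(decided, argmax_label, REFUSE).astype(object)

    rule = TriageRule(
        threshold_b=threshold_b, labels=list(probs.labels), epsilon=epsilon
    )
    result = TriageResult(
        decisions=decisions, decided=decided, argmax_label=argmax_label
    )
    return rule, result


def triage_loss(
    result: TriageResult,
    truth: Sequence,
    weights: np.ndarray | None = None,
) -> TriageLoss:
    """Joint loss, precision and coverage of decisions against true labels."""
    truth_arr = np.asarray([str(t) for t in truth], dtype=object)
    if truth_arr.shape != result.decisions.shape:
        raise ValueError(
            f"truth has length {truth_arr.shape[0]}, "
            f"decisions have length {result.n_items}"
        )
    if weights is None:
        w = np.full(result.n_items, 1.0 / result.n_items)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != truth_arr.shape:
            raise ValueError("weights length must match decisions")
    wrong_and_decided = result.decided & (result.decisions != truth_arr)
    joint = float(w[wrong_and_decided].sum())
    coverage = float(w[result.decided].sum())
    precision = 1.0 - joint / coverage if coverage > 0 else float("nan")
    return TriageLoss(joint_loss=joint, precision=precision, coverage=coverage)


def binary_ratio_band(threshold_b: float) -> BinaryBand:
    """Two-class refusal band equivalent to the max-probability threshold.

    For m = 2 the winning probability is always >= 1/2, and refusing when
    max_k p(k|x) <= b is pointwise identical to refusing when the class ratio
    p(1|x)/p(0|x) lies in [1/b', b'] with b' = b / (1 - b).  At b = 1/2 the
    band degenerates to the measure-zero set {p(1|x) = p(0|x)}.
    """
    if not 0.5 <= threshold_b < 1.0:
        raise ValueError(
            f"threshold_b={threshold_b!r} outside [1/2, 1): a two-class "
            "winning probability is always >= 1/2 and a threshold of 1 "
            "refuses everything"
        )
    return BinaryBand(ratio_bound_bprime=threshold_b / (1.0 - threshold_b))
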