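"""Classifier evaluation: confusion matrices, overall and balanced accuracy.

The evaluation protocol mirrors the model's intended use: a hold-out set of
consensus-classified lakes is standardized with the *training* spec, each
lake's continuous index eta is computed, the interval rule on the cutpoints
assigns a discrete state, and the predictions are tabulated against the
observed states.  Balanced accuracy (mean of one-vs-rest sensitivity and
specificity) complements overall accuracy on class-imbalanced lake sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .lake_data import (
    DesignMatrix,
    InsufficientDataError,
    LakeSample,
    StandardizationSpec,
    TrophicState,
    ValidationError,
    apply_standardization,
)
from .polr_core import (
    N_STATES,
    POLRParameters,
    _states_to_codes,
    class_probabilities,
    classify_interval,
    trophic_index,
)

logger = logging.getLogger("laketsi")

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "overall_accuracy",
    "balanced_accuracy",
    "evaluate_holdout",
    "probability_curves",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 counts; rows are actual states, columns predicted states."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (N_STATES, N_STATES) or np.any(counts < 0):
            raise ValidationError("confusion matrix must be 4x4 nonnegative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    """Overall accuracy plus per-class sensitivity/specificity/balanced accuracy.

    Classes absent from the evaluation set have NaN per-class metrics.
    """

    overall_accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    balanced_accuracy: dict[str, float]
    n_eval: int

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "sensitivity": dict(self.sensitivity),
            "specificity": dict(self.specificity),
            "balanced_accuracy": dict(self.balanced_accuracy),
            "n_eval": self.n_eval,
        }


def confusion_matrix(actual, predicted) -> ConfusionMatrix:
    """Tabulate counts with entry (i, j) = #(actual state i, predicted state j)."""
    a = _states_to_codes(actual)
    p = _states_to_codes(predicted)
    if a.shape[0] != p.shape[0]:
        raise ValidationError("actual and predicted lengths differ")
    if a.shape[0] == 0:
        raise InsufficientDataError("need at least one labeled pair")
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    np.add.at(counts, (a - 1, p - 1), 1)
    return ConfusionMatrix(counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of correct classifications: trace / total."""
    if cm.total == 0:
        raise InsufficientDataError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def balanced_accuracy(cm: ConfusionMatrix, k: TrophicState | int) -> float:
    """One-vs-rest balanced accuracy for state ``k``.

    Sensitivity is the true-positive rate on row k; specificity the
    true-negative rate on the complement; the balanced accuracy is their
    mean.  Raises when class k has no actual instances.
    """
    k = int(k)
    counts = cm.counts
    row = counts[k - 1]
    if row.sum() == 0:
        raise ValidationError(
            f"class {TrophicState(k).label!r} has no actual instances; "
            "balanced accuracy undefined"
        )
    tp = counts[k - 1, k - 1]
    fn = row.sum() - tp
    fp = counts[:, k - 1].sum() - tp
    tn = cm.total - tp - fn - fp
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return float((sensitivity + specificity) / 2.0)


def evaluate_holdout(
    params: POLRParameters,
    spec: StandardizationSpec,
    eval_set: list[LakeSample],
    training_ids: set[str] | None = None,
) -> MetricsReport:
    """Score the fitted model on a labeled hold-out set.

    Standardizes with the training spec, predicts via the interval rule on
    eta, and computes the full metrics report.  Classes absent from the
    evaluation set get NaN per-class metrics (with a log entry); if
    ``training_ids`` is supplied, overlapping lake ids trigger a warning.
    """
    labeled = [s for s in eval_set if s.observed_state is not None]
    if not labeled:
        raise InsufficientDataError("evaluation set has no labeled lakes")
    if training_ids is not None:
        overlap = {s.lake_id for s in labeled} & set(training_ids)
        if overlap:
            warnings.warn(
                f"{len(overlap)} evaluation lake(s) also appear in training",
                RuntimeWarning,
                stacklevel=2,
            )
    design = apply_standardization(labeled, spec)
    eta = trophic_index(design.X, params)
    predicted = classify_interval(eta, params)
    actual = [s.observed_state for s in labeled]
    cm = confusion_matrix(actual, predicted)

    sens: dict[str, float] = {}
    spec_: dict[str, float] = {}
    bal: dict[str, float] = {}
    for state in TrophicState:
        row = cm.counts[state - 1]
        if row.sum() == 0:
            logger.info("evaluate_holdout: class %s absent; metrics undefined", state.label)
            sens[state.label] = spec_[state.label] = bal[state.label] = float("nan")
            continue
        tp = cm.counts[state - 1, state - 1]
        fn = row.sum() - tp
        fp = cm.counts[:, state - 1].sum() - tp
        tn = cm.total - tp - fn - fp
        sens[state.label] = float(tp / (tp + fn))
        spec_[state.label] = float(tn / (tn + fp))
        bal[state.label] = (sens[state.label] + spec_[state.label]) / 2.0

    return MetricsReport(
        overall_accuracy=overall_accuracy(cm),
        sensitivity=sens,
        specificity=spec_,
        balanced_accuracy=bal,
        n_eval=cm.total,
    )


def probability_curves(params: POLRParameters, grid) -> np.ndarray:
    """Class-probability curves along an index grid.

    Returns an (n, 5) array with columns (eta, p_oligo, p_meso, p_eu,
    p_hyper) — the tabular form of the index-versus-probability plot.
    """
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValidationError("grid must be finite")
    probs = class_probabilities(grid, params)
    return np.column_stack([grid, probs])
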