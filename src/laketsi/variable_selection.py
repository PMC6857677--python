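"""Random-forest variable importance ranking and minimal-subset selection.

Candidate predictors are ranked by out-of-bag (OOB) permutation importance
from a regression forest, then nested forests on the top-m predictors trace
an OOB error curve; the chosen subset is the smallest m beyond which no
further variable improves the error by at least the threshold (default 0.1).

The 4-level ordinal trophic state is treated as numeric 1-4 in regression
mode: the importance measure is the percent increase in OOB mean squared
error under feature permutation, which only a regression forest defines.
Tree induction is delegated to scikit-learn; the OOB permutation importance
and the error-increment selection rule live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

# no public accessor exists for per-tree bootstrap membership
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from .lake_data import InsufficientDataError, ValidationError
from .polr_core import _states_to_codes

logger = logging.getLogger("laketsi")

__all__ = [
    "ImportanceRanking",
    "SelectionCurve",
    "rank_importance",
    "select_minimal_subset",
    "choose_subset_size",
]

#: mtry for regression forests: p/3, the convention for %IncMSE-style forests
_MAX_FEATURES = 1.0 / 3.0


@dataclass(frozen=True)
class ImportanceRanking:
    """Predictors ordered by decreasing OOB permutation importance.

    ``scores`` are percent increases in OOB mean squared error when the
    feature is permuted; ties keep input column order.
    """

    features: tuple[str, ...]
    scores: tuple[float, ...]
    n_trees: int
    seed: int | None

    def __post_init__(self) -> None:
        if list(self.scores) != sorted(self.scores, reverse=True):
            raise ValidationError("scores must be descending")


@dataclass(frozen=True)
class SelectionCurve:
    """OOB error for nested top-m forests and the chosen subset size."""

    subset_sizes: tuple[int, ...]
    errors: tuple[float, ...]
    chosen_size: int
    threshold: float
    features: tuple[str, ...]  # ranked order; the chosen subset is features[:chosen_size]

    @property
    def chosen_features(self) -> tuple[str, ...]:
        return self.features[: self.chosen_size]


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    arr = np.asarray(features, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{j + 1}" for j in range(arr.shape[1])])


def _fit_forest(Xf: np.ndarray, yf: np.ndarray, n_trees: int, seed) -> RandomForestRegressor:
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=_MAX_FEATURES,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(Xf, yf)
    return forest


def _oob_mse(forest: RandomForestRegressor, Xf: np.ndarray, yf: np.ndarray) -> float:
    pred = forest.oob_prediction_
    ok = ~np.isnan(pred)
    return float(np.mean((pred[ok] - yf[ok]) ** 2))


def rank_importance(
    features,
    response,
    n_trees: int = 5000,
    seed: int | None = None,
) -> ImportanceRanking:
    """Rank predictors by OOB permutation importance (%IncMSE analogue).

    For each tree, the MSE on its out-of-bag lakes is compared with the MSE
    after permuting one feature among those lakes; the mean increase across
    trees, as a percent of the forest's OOB MSE, is the feature's score.
    Zero-variance features are excluded with a logged warning.  Deterministic
    for a fixed seed.

    The response is the ordinal trophic state treated as numeric 1-4.
    """
    frame = _as_frame(features)
    if frame.shape[1] < 2:
        raise InsufficientDataError("need at least 2 candidate features")
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    yf = _states_to_codes(response).astype(float)
    if frame.shape[0] != yf.shape[0]:
        raise ValidationError("features and response length differ")

    variances = frame.var(axis=0, ddof=0)
    dropped = [name for name in frame.columns if variances[name] == 0]
    if dropped:
        logger.warning("rank_importance: excluding zero-variance feature(s) %s", dropped)
        frame = frame.drop(columns=dropped)

    names = list(frame.columns)
    Xf = frame.to_numpy(dtype=float)
    n = Xf.shape[0]
    forest = _fit_forest(Xf, yf, n_trees, seed)
    baseline_mse = _oob_mse(forest, Xf, yf)

    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    rng = np.random.default_rng(seed)
    increases = np.zeros((len(forest.estimators_), len(names)))
    for t, tree in enumerate(forest.estimators_):
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if oob.size < 2:
            continue
        X_oob = Xf[oob]
        err = np.mean((tree.predict(X_oob) - yf[oob]) ** 2)
        for j in range(len(names)):
            X_perm = X_oob.copy()
            X_perm[:, j] = rng.permutation(X_perm[:, j])
            err_perm = np.mean((tree.predict(X_perm) - yf[oob]) ** 2)
            increases[t, j] = err_perm - err

    scores = 100.0 * increases.mean(axis=0) / baseline_mse
    # stable sort keeps input order on ties
    order = np.argsort(-scores, kind="stable")
    return ImportanceRanking(
        features=tuple(names[j] for j in order),
        scores=tuple(float(scores[j]) for j in order),
        n_trees=n_trees,
        seed=seed,
    )


def choose_subset_size(errors, threshold: float) -> int:
    """Smallest m beyond which no additional variable cuts error by >= threshold.

    Scans the error curve for nested subsets of size 1..M and returns the
    first m whose every subsequent one-variable increment is below the
    threshold; a flat curve gives 1.
    """
    errors = list(errors)
    if not errors:
        raise InsufficientDataError("empty error curve")
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    gains = [errors[m] - errors[m + 1] for m in range(len(errors) - 1)]
    for m in range(len(errors)):
        if all(g < threshold for g in gains[m:]):
            return m + 1
    return len(errors)


def select_minimal_subset(
    features,
    response,
    ranking: ImportanceRanking,
    threshold: float = 0.1,
    max_subset: int = 15,
    n_trees: int = 500,
    seed: int | None = None,
) -> SelectionCurve:
    """Trace the OOB error curve of nested top-m forests and pick the elbow.

    Fits a regression forest on the top-m ranked predictors for m = 1..M
    (M capped at ``max_subset`` and the feature count), records each OOB mean
    squared error, and applies :func:`choose_subset_size` with ``threshold``.
    """
    frame = _as_frame(features)
    yf = _states_to_codes(response).astype(float)
    M = min(max_subset, len(ranking.features))
    if max_subset > len(ranking.features):
        logger.info(
            "select_minimal_subset: cap %d exceeds %d ranked features; using all",
            max_subset,
            len(ranking.features),
        )
    errors = []
    for m in range(1, M + 1):
        cols = list(ranking.features[:m])
        forest = _fit_forest(frame[cols].to_numpy(dtype=float), yf, n_trees, seed)
        errors.append(_oob_mse(forest, frame[cols].to_numpy(dtype=float), yf))
    chosen = choose_subset_size(errors, threshold)
    return SelectionCurve(
        subset_sizes=tuple(range(1, M + 1)),
        errors=tuple(errors),
        chosen_size=chosen,
        threshold=threshold,
        features=tuple(ranking.features[:M]),
    )
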