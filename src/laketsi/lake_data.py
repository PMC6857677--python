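"""Lake water-quality tables: I/O, transformation, standardization, splitting.

The modeling pipeline works on per-lake records of Secchi disk depth (m),
total nitrogen (µg/L), total phosphorus (µg/L) and elevation (m), with an
optional observed trophic state and up to three single-variable reference
classifications (chlorophyll-a-, N- and P-based schemes).  Concentration-like
predictors (Secchi, TN, TP) are natural-log transformed before centering and
scaling; elevation is standardized on its raw scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("laketsi")

__all__ = [
    "TrophicState",
    "LakeSample",
    "StandardizationSpec",
    "DesignMatrix",
    "LakeDataError",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "DegenerateDataError",
    "InsufficientDataError",
    "DEFAULT_COLUMNS",
    "PREDICTOR_NAMES",
    "read_lakes",
    "write_lakes",
    "fit_standardization",
    "apply_standardization",
    "consensus_filter",
    "holdout_split",
]


class LakeDataError(ValueError):
    """Base class for lake-table errors."""


class SchemaError(LakeDataError):
    """A required column is missing from the input table."""


class ParseError(LakeDataError):
    """A numeric column contains a non-numeric value."""


class ValidationError(LakeDataError):
    """A value violates a domain constraint (e.g. nonpositive concentration)."""


class DegenerateDataError(LakeDataError):
    """The data carry no usable variation (e.g. a constant predictor)."""


class InsufficientDataError(LakeDataError):
    """Too few observations for the requested operation."""


class TrophicState(IntEnum):
    """Ordered lake trophic state: nutrient-poor through algae-dominated."""

    OLIGOTROPHIC = 1
    MESOTROPHIC = 2
    EUTROPHIC = 3
    HYPEREUTROPHIC = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def parse(cls, value) -> "TrophicState":
        """Accept an ordinal code 1-4, a level name, or a TrophicState."""
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        if isinstance(value, (float, np.floating)) and float(value).is_integer():
            return cls(int(value))
        if isinstance(value, str):
            text = value.strip().lower()
            if text.isdigit():
                return cls(int(text))
            for state in cls:
                if state.label == text:
                    return state
        raise ValidationError(f"unrecognized trophic state: {value!r}")


#: Fixed predictor order used by every design matrix in the package.
PREDICTOR_NAMES = ("secchi_depth", "total_nitrogen", "total_phosphorus", "elevation")

#: Default CSV column names (override via the ``dialect`` mapping).
DEFAULT_COLUMNS = {
    "lake_id": "lake_id",
    "secchi_depth": "secchi_m",
    "total_nitrogen": "tn_ugl",
    "total_phosphorus": "tp_ugl",
    "elevation": "elevation_m",
    "observed_state": "trophic_state",
    "ref_chla": "ref_chla",
    "ref_tn": "ref_tn",
    "ref_tp": "ref_tp",
}

_REQUIRED_FIELDS = ("lake_id", "secchi_depth", "total_nitrogen", "total_phosphorus", "elevation")
_POSITIVE_FIELDS = ("secchi_depth", "total_nitrogen", "total_phosphorus")
_REF_FIELDS = ("ref_chla", "ref_tn", "ref_tp")


@dataclass
class LakeSample:
    """One lake's raw measurements plus optional labels.

    Secchi depth, TN and TP must be strictly positive because the pipeline
    log-transforms them; elevation may be any real (lakes below sea level
    exist).
    """

    lake_id: str
    secchi_depth: float
    total_nitrogen: float
    total_phosphorus: float
    elevation: float
    observed_state: TrophicState | None = None
    reference_labels: tuple[TrophicState, ...] | None = None

    def validate(self) -> None:
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"lake {self.lake_id!r}: {name}={value!r} must be strictly "
                    "positive (log transform domain)"
                )
        if not np.isfinite(self.elevation):
            raise ValidationError(f"lake {self.lake_id!r}: elevation must be finite")


def read_lakes(
    path,
    dialect: Mapping[str, str] | None = None,
    strict: bool = True,
) -> list[LakeSample]:
    """Read a lakes CSV into a list of :class:`LakeSample`, in file order.

    Rows missing any required field are dropped and the count logged.  Under
    ``strict=True`` a nonpositive Secchi/TN/TP raises :class:`ValidationError`;
    otherwise such rows are dropped with a logged count.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row.
    dialect : mapping, optional
        Overrides for :data:`DEFAULT_COLUMNS` (canonical field -> column name).
    strict : bool
        Whether domain violations raise or drop rows.
    """
    columns = dict(DEFAULT_COLUMNS)
    if dialect:
        unknown = set(dialect) - set(columns)
        if unknown:
            raise SchemaError(f"unknown dialect keys: {sorted(unknown)}")
        columns.update(dialect)

    frame = pd.read_csv(path, dtype={columns["lake_id"]: str})
    for name in _REQUIRED_FIELDS:
        if columns[name] not in frame.columns:
            raise SchemaError(f"missing required column {columns[name]!r} ({name})")

    numeric_fields = ("secchi_depth", "total_nitrogen", "total_phosphorus", "elevation")
    for name in numeric_fields:
        col = columns[name]
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {frame[col].iloc[row]!r} in column {col!r}, "
                f"data row {row + 1}"
            )
        frame[col] = coerced

    required_cols = [columns[n] for n in _REQUIRED_FIELDS]
    complete = frame[required_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("read_lakes: dropped %d row(s) with missing required fields", n_dropped)
    frame = frame[complete]

    samples: list[LakeSample] = []
    n_invalid = 0
    seen_ids: set[str] = set()
    for _, row in frame.iterrows():
        sample = LakeSample(
            lake_id=str(row[columns["lake_id"]]),
            secchi_depth=float(row[columns["secchi_depth"]]),
            total_nitrogen=float(row[columns["total_nitrogen"]]),
            total_phosphorus=float(row[columns["total_phosphorus"]]),
            elevation=float(row[columns["elevation"]]),
        )
        state_col = columns["observed_state"]
        if state_col in frame.columns and pd.notna(row.get(state_col)):
            sample.observed_state = TrophicState.parse(row[state_col])
        refs = []
        for ref_name in _REF_FIELDS:
            col = columns[ref_name]
            if col in frame.columns and pd.notna(row.get(col)):
                refs.append(TrophicState.parse(row[col]))
        if refs:
            sample.reference_labels = tuple(refs)
        try:
            sample.validate()
        except ValidationError:
            if strict:
                raise
            n_invalid += 1
            continue
        if sample.lake_id in seen_ids:
            if strict:
                raise ValidationError(f"duplicate lake_id {sample.lake_id!r}")
            n_invalid += 1
            continue
        seen_ids.add(sample.lake_id)
        samples.append(sample)
    if n_invalid:
        logger.warning("read_lakes: dropped %d invalid row(s)", n_invalid)
    return samples


def write_lakes(samples: Sequence[LakeSample], path, dialect: Mapping[str, str] | None = None) -> None:
    """Write samples to CSV using the standard (or overridden) column names."""
    columns = dict(DEFAULT_COLUMNS)
    if dialect:
        columns.update(dialect)
    records = []
    any_state = any(s.observed_state is not None for s in samples)
    any_refs = any(s.reference_labels for s in samples)
    for s in samples:
        rec = {
            columns["lake_id"]: s.lake_id,
            columns["secchi_depth"]: s.secchi_depth,
            columns["total_nitrogen"]: s.total_nitrogen,
            columns["total_phosphorus"]: s.total_phosphorus,
            columns["elevation"]: s.elevation,
        }
        if any_state:
            rec[columns["observed_state"]] = s.observed_state.label if s.observed_state else ""
        if any_refs:
            refs = s.reference_labels or ()
            for i, ref_name in enumerate(_REF_FIELDS):
                rec[columns[ref_name]] = refs[i].label if i < len(refs) else ""
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


@dataclass(frozen=True)
class StandardizationSpec:
    """Per-predictor centers and scales fitted on a training set.

    ``log_transformed`` records which predictors enter on the natural-log
    scale (Secchi, TN, TP); elevation stays raw.  The same spec must be
    reused when standardizing new lakes for prediction — never re-fit on
    evaluation data.
    """

    centers: tuple[float, float, float, float]
    scales: tuple[float, float, float, float]
    log_transformed: tuple[bool, bool, bool, bool] = (True, True, True, False)

    def __post_init__(self) -> None:
        if len(self.centers) != 4 or len(self.scales) != 4:
            raise ValidationError("spec needs exactly 4 centers and 4 scales")
        if any(not np.isfinite(s) or s <= 0 for s in self.scales):
            raise ValidationError("every scale must be finite and > 0")

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Standardize an (n, 4) array of raw predictor values."""
        raw = np.asarray(raw, dtype=float)
        out = np.array(raw, copy=True)
        for j, is_log in enumerate(self.log_transformed):
            if is_log:
                if np.any(out[..., j] <= 0):
                    raise ValidationError(
                        f"{PREDICTOR_NAMES[j]} must be > 0 (log transform domain)"
                    )
                out[..., j] = np.log(out[..., j])
        return (out - np.asarray(self.centers)) / np.asarray(self.scales)

    def inverse_transform(self, standardized: np.ndarray) -> np.ndarray:
        """Map standardized values back to the raw measurement scale."""
        z = np.asarray(standardized, dtype=float)
        out = z * np.asarray(self.scales) + np.asarray(self.centers)
        for j, is_log in enumerate(self.log_transformed):
            if is_log:
                out[..., j] = np.exp(out[..., j])
        return out

    def to_dict(self) -> dict:
        return {
            "predictors": list(PREDICTOR_NAMES),
            "centers": [float(c) for c in self.centers],
            "scales": [float(s) for s in self.scales],
            "log_transformed": list(self.log_transformed),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "StandardizationSpec":
        return cls(
            centers=tuple(float(c) for c in data["centers"]),
            scales=tuple(float(s) for s in data["scales"]),
            log_transformed=tuple(bool(b) for b in data["log_transformed"]),
        )


@dataclass(frozen=True)
class DesignMatrix:
    """Standardized (n, 4) predictor matrix with aligned lake ids.

    Column order is fixed: Secchi, TN, TP, elevation.
    """

    X: np.ndarray
    lake_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValidationError(f"design matrix must be (n, 4), got {X.shape}")
        if X.shape[0] != len(self.lake_ids):
            raise ValidationError("row count does not match lake_ids")
        if not np.all(np.isfinite(X)):
            raise ValidationError("design matrix contains non-finite entries")
        object.__setattr__(self, "X", X)

    def __len__(self) -> int:
        return self.X.shape[0]


def _raw_matrix(samples: Sequence[LakeSample]) -> np.ndarray:
    for s in samples:
        s.validate()
    return np.array(
        [[s.secchi_depth, s.total_nitrogen, s.total_phosphorus, s.elevation] for s in samples],
        dtype=float,
    )


def fit_standardization(samples: Sequence[LakeSample]) -> StandardizationSpec:
    """Fit centers and scales on a training set.

    Secchi, TN and TP are natural-log transformed before the mean and the
    sample standard deviation (n-1 denominator) are taken; elevation is used
    raw.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise InsufficientDataError("need at least 2 samples to fit standardization")
    raw = _raw_matrix(samples)
    transformed = raw.copy()
    log_flags = (True, True, True, False)
    for j, is_log in enumerate(log_flags):
        if is_log:
            transformed[:, j] = np.log(transformed[:, j])
    centers = transformed.mean(axis=0)
    scales = transformed.std(axis=0, ddof=1)
    for j, scale in enumerate(scales):
        if scale == 0:
            raise DegenerateDataError(
                f"predictor {PREDICTOR_NAMES[j]!r} is constant across samples (SD = 0)"
            )
    return StandardizationSpec(
        centers=tuple(map(float, centers)),
        scales=tuple(map(float, scales)),
        log_transformed=log_flags,
    )


def apply_standardization(
    samples: Sequence[LakeSample], spec: StandardizationSpec
) -> DesignMatrix:
    """Build the standardized design matrix for ``samples`` under ``spec``."""
    samples = list(samples)
    raw = _raw_matrix(samples)
    X = spec.transform(raw) if len(samples) else np.empty((0, 4))
    return DesignMatrix(X=X, lake_ids=tuple(s.lake_id for s in samples))


def consensus_filter(samples: Iterable[LakeSample]) -> list[LakeSample]:
    """Keep lakes whose single-variable reference classifications all agree.

    A retained sample must carry at least two reference labels, all identical;
    its ``observed_state`` is set to the consensus label.  Lakes where the
    chlorophyll-a, TN and TP schemes disagree are dropped — the evaluation
    protocol trusts only consistently classified lakes.
    """
    samples = list(samples)
    if not any(s.reference_labels for s in samples):
        raise InsufficientDataError("no sample carries reference labels")
    kept = []
    for s in samples:
        refs = s.reference_labels or ()
        if len(refs) >= 2 and len(set(refs)) == 1:
            kept.append(replace(s, observed_state=refs[0]))
    return kept


def holdout_split(
    samples: Sequence[LakeSample], eval_fraction: float = 0.1, seed: int | None = None
) -> tuple[list[LakeSample], list[LakeSample]]:
    """Random disjoint train/evaluation partition (default 90/10).

    Evaluation size is round(n * eval_fraction), at least 1; the split is
    deterministic for a fixed seed.
    """
    samples = list(samples)
    n = len(samples)
    if n < 2:
        raise InsufficientDataError("need at least 2 samples to split")
    if not 0 < eval_fraction < 1:
        raise ValidationError("eval_fraction must be in (0, 1)")
    n_eval = max(1, int(round(n * eval_fraction)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    eval_idx = set(order[:n_eval].tolist())
    train = [s for i, s in enumerate(samples) if i not in eval_idx]
    evaluation = [s for i, s in enumerate(samples) if i in eval_idx]
    return train, evaluation
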