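"""Generative simulator for national-survey-like lake datasets.

Lakes are drawn from the model's own latent-variable reading: predictors X
(either directly standardized-normal, or raw lognormal concentrations and
normal elevation pushed through the pipeline's preprocessing), a continuous
index eta = X A, a latent z = eta + standard-logistic noise, and the ordinal
trophic state from the cutpoint intervals.  Three imperfect single-variable
reference classifiers can be layered on top to exercise the consensus
filter.  Every draw is reproducible from the seed; the logistic noise uses
inverse-CDF sampling from uniform deviates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lake_data import (
    DesignMatrix,
    InsufficientDataError,
    LakeSample,
    StandardizationSpec,
    TrophicState,
    ValidationError,
    apply_standardization,
    fit_standardization,
)
from .polr_core import NLA_2007_PARAMS, POLRParameters, classify_interval

__all__ = [
    "RawPredictorParams",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate",
    "make_reference_labels",
]


@dataclass(frozen=True)
class RawPredictorParams:
    """Log-scale location/spread for Secchi/TN/TP and mean/SD for elevation.

    Defaults sketch a national lake survey: median Secchi ~1.4 m, median TN
    ~600 ug/L, median TP ~30 ug/L, each lognormal with log-SD 1 (environmental
    concentrations are canonically log-normal), and elevation ~N(500, 400) m.
    """

    secchi_log_mean: float = float(np.log(1.4))
    secchi_log_sd: float = 1.0
    tn_log_mean: float = float(np.log(600.0))
    tn_log_sd: float = 1.0
    tp_log_mean: float = float(np.log(30.0))
    tp_log_sd: float = 1.0
    elevation_mean: float = 500.0
    elevation_sd: float = 400.0

    def __post_init__(self) -> None:
        for name in ("secchi_log_sd", "tn_log_sd", "tp_log_sd", "elevation_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    def as_spec(self) -> StandardizationSpec:
        """The standardization spec under which these raw draws are N(0, 1)."""
        return StandardizationSpec(
            centers=(
                self.secchi_log_mean,
                self.tn_log_mean,
                self.tp_log_mean,
                self.elevation_mean,
            ),
            scales=(
                self.secchi_log_sd,
                self.tn_log_sd,
                self.tp_log_sd,
                self.elevation_sd,
            ),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Size, generating parameters, predictor mode, and seed of one simulation."""

    n: int
    params: POLRParameters = NLA_2007_PARAMS
    predictor_mode: str = "standardized_normal"
    raw_params: RawPredictorParams = field(default_factory=RawPredictorParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        if self.predictor_mode not in ("standardized_normal", "raw_lognormal"):
            raise ValidationError(f"unknown predictor_mode {self.predictor_mode!r}")


@dataclass(frozen=True)
class SyntheticDataset:
    """Simulated lakes with the latent quantities retained for testing."""

    samples: tuple[LakeSample, ...]
    design: DesignMatrix
    eta: np.ndarray
    z: np.ndarray
    states: np.ndarray  # ordinal codes 1..4, aligned with samples
    standardization: StandardizationSpec
    truth: SimulationConfig

    def __len__(self) -> int:
        return len(self.samples)


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Draw a synthetic lake dataset from the latent ordinal model.

    ``standardized_normal`` mode draws the four design columns iid standard
    normal (raw measurements are synthesized by inverting the raw-parameter
    standardization, so samples always carry plausible raw values).
    ``raw_lognormal`` mode draws raw Secchi/TN/TP lognormal and elevation
    normal, then the pipeline's own preprocessing (log, center, scale on the
    simulated sample) builds the design matrix.  In both modes
    z = eta + logistic(0, 1) noise and the observed state is the cutpoint
    interval containing z.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    params = config.params
    raw_spec = config.raw_params.as_spec()

    if n == 0:
        return SyntheticDataset(
            samples=(),
            design=DesignMatrix(X=np.empty((0, 4)), lake_ids=()),
            eta=np.empty(0),
            z=np.empty(0),
            states=np.empty(0, dtype=int),
            standardization=raw_spec,
            truth=config,
        )

    if config.predictor_mode == "standardized_normal":
        X = rng.standard_normal((n, 4))
        raw = raw_spec.inverse_transform(X)
        spec = raw_spec
        samples = _build_samples(raw)
        design = DesignMatrix(X=X, lake_ids=tuple(s.lake_id for s in samples))
    else:
        if n < 2:
            raise InsufficientDataError("raw_lognormal mode needs n >= 2 to standardize")
        z01 = rng.standard_normal((n, 4))
        raw = raw_spec.inverse_transform(z01)
        samples = _build_samples(raw)
        spec = fit_standardization(samples)
        design = apply_standardization(samples, spec)
        X = design.X

    eta = X @ params.coef_array
    u = rng.uniform(size=n)
    z = eta + params.latent_scale * (np.log(u) - np.log1p(-u))
    states = classify_interval(z, params)
    states = np.atleast_1d(np.asarray(states, dtype=int))

    labeled = tuple(
        replace(s, observed_state=TrophicState(int(k))) for s, k in zip(samples, states)
    )
    return SyntheticDataset(
        samples=labeled,
        design=design,
        eta=eta,
        z=z,
        states=states,
        standardization=spec,
        truth=config,
    )


def _build_samples(raw: np.ndarray) -> list[LakeSample]:
    width = len(str(raw.shape[0]))
    return [
        LakeSample(
            lake_id=f"sim-{i + 1:0{width}d}",
            secchi_depth=float(row[0]),
            total_nitrogen=float(row[1]),
            total_phosphorus=float(row[2]),
            elevation=float(row[3]),
        )
        for i, row in enumerate(raw)
    ]


def make_reference_labels(
    dataset: SyntheticDataset, noise_rate: float, seed: int | None = None
) -> SyntheticDataset:
    """Attach three imperfect single-variable reference classifications.

    Each of the three schemes (emulating chlorophyll-a-, TN- and TP-based
    classifiers) copies the observed state and independently perturbs it to
    an adjacent state with probability ``noise_rate`` (end states move
    inward; interior states move up or down with equal probability).
    """
    if not 0 <= noise_rate < 1:
        raise ValidationError("noise_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    if n == 0:
        return dataset
    base = dataset.states
    labels = np.tile(base[:, None], (1, 3))
    perturb = rng.uniform(size=(n, 3)) < noise_rate
    direction = np.where(rng.uniform(size=(n, 3)) < 0.5, -1, 1)
    direction = np.where(labels == 1, 1, direction)
    direction = np.where(labels == 4, -1, direction)
    labels = np.where(perturb, labels + direction, labels)

    relabeled = tuple(
        replace(s, reference_labels=tuple(TrophicState(int(v)) for v in row))
        for s, row in zip(dataset.samples, labels)
    )
    return replace(dataset, samples=relabeled)
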