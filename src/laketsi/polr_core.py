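"""Proportional-odds logistic regression core for the trophic state index.

The model: a lake's continuous trophic state index is the linear predictor
eta = X A over the four standardized predictors (log Secchi depth, log TN,
log TP, elevation).  A latent variable z ~ logistic(eta, 1) is discretized
by three ordered cutpoints c into the four trophic states, so that

    logit(Pr(state > k)) = eta - c_k,   k = 1, 2, 3.

There is no intercept: the cutpoints absorb location, which is the usual
identifiable parameterization of a cumulative-logit model.  The latent
logistic scale is fixed at 1.

Class probabilities are differences of adjacent exceedance probabilities and
equal the logistic density mass between adjacent cutpoints.  All log
probabilities are computed through log-sigmoid identities, avoiding the
catastrophic cancellation of a naive F(a) - F(b) for extreme eta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, log_expit

from .lake_data import (
    PREDICTOR_NAMES,
    StandardizationSpec,
    TrophicState,
    ValidationError,
)

__all__ = [
    "POLRParameters",
    "NLA_2007_PARAMS",
    "trophic_index",
    "exceedance_probability",
    "class_probabilities",
    "classify_interval",
    "classify_map",
    "log_likelihood",
    "log_likelihood_terms",
    "save_model",
    "load_model",
]

N_STATES = 4
CUTPOINT_NAMES = ("oligo|meso", "meso|eu", "eu|hyper")


@dataclass(frozen=True)
class POLRParameters:
    """Slope coefficients, ordered cutpoints, and the fixed latent scale.

    ``coefficients`` follow the design-matrix column order (Secchi, TN, TP,
    elevation); ``cutpoints`` are the thresholds separating oligo|meso,
    meso|eu and eu|hyper on the index scale.  ``latent_scale`` exists for
    completeness but is fixed at 1: a free scale is not jointly identifiable
    with the coefficients and cutpoints.
    """

    coefficients: tuple[float, float, float, float]
    cutpoints: tuple[float, float, float]
    latent_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.coefficients) != 4:
            raise ValidationError("exactly 4 coefficients required")
        if len(self.cutpoints) != 3:
            raise ValidationError("exactly 3 cutpoints required")
        c = np.asarray(self.cutpoints, dtype=float)
        if not np.all(np.isfinite(c)) or not np.all(np.diff(c) > 0):
            raise ValidationError("cutpoints must be finite and strictly increasing")
        if not np.isfinite(self.latent_scale) or self.latent_scale <= 0:
            raise ValidationError("latent_scale must be positive")
        object.__setattr__(
            self, "coefficients", tuple(float(a) for a in self.coefficients)
        )
        object.__setattr__(self, "cutpoints", tuple(float(ck) for ck in self.cutpoints))

    @property
    def coef_array(self) -> np.ndarray:
        return np.asarray(self.coefficients, dtype=float)

    @property
    def cut_array(self) -> np.ndarray:
        return np.asarray(self.cutpoints, dtype=float)

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(PREDICTOR_NAMES, self.coefficients)),
            "cutpoints": list(self.cutpoints),
            "latent_scale": self.latent_scale,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "POLRParameters":
        coefs = data["coefficients"]
        if isinstance(coefs, Mapping):
            coefs = [coefs[name] for name in PREDICTOR_NAMES]
        return cls(
            coefficients=tuple(float(a) for a in coefs),
            cutpoints=tuple(float(c) for c in data["cutpoints"]),
            latent_scale=float(data.get("latent_scale", 1.0)),
        )


#: Point estimates from the 2007 EPA National Lakes Assessment fit of this
#: model (~1,000 lakes): the package-wide default generating parameters.
NLA_2007_PARAMS = POLRParameters(
    coefficients=(-1.69, 0.69, 0.55, -0.56),
    cutpoints=(-3.36, -0.18, 2.62),
)


def trophic_index(row: np.ndarray, params: POLRParameters) -> float | np.ndarray:
    """Continuous trophic state index eta = X A.

    ``row`` may be a single standardized 4-vector (returns a float) or an
    (n, 4) matrix (returns an n-vector).
    """
    row = np.asarray(row, dtype=float)
    if row.shape[-1] != 4:
        raise ValidationError(f"expected 4 predictors, got shape {row.shape}")
    eta = row @ params.coef_array
    return float(eta) if eta.ndim == 0 else eta


def exceedance_probability(eta, k: int, params: POLRParameters):
    """Pr(trophic state > k) = inverse-logit(eta - c_k) for k in {1, 2, 3}.

    By convention Pr(> 0) = 1 and Pr(> 4) = 0.
    """
    eta = np.asarray(eta, dtype=float)
    if k == 0:
        out = np.ones_like(eta)
    elif k == N_STATES:
        out = np.zeros_like(eta)
    elif 1 <= k <= 3:
        out = expit((eta - params.cutpoints[k - 1]) / params.latent_scale)
    else:
        raise ValidationError(f"k must be in 0..4, got {k}")
    return float(out) if out.ndim == 0 else out


def class_probabilities(eta, params: POLRParameters) -> np.ndarray:
    """Probabilities of the four states: p_k = Pr(> k-1) - Pr(> k).

    Equivalently the logistic(eta, 1) density mass between adjacent
    cutpoints.  Returns shape (..., 4); each row sums to 1.
    """
    eta = np.asarray(eta, dtype=float)
    exceed = np.stack(
        [exceedance_probability(eta, k, params) for k in range(N_STATES + 1)], axis=-1
    )
    probs = exceed[..., :-1] - exceed[..., 1:]
    # guard against tiny negative round-off at extreme eta
    return np.clip(probs, 0.0, 1.0)


def classify_interval(z, params: POLRParameters):
    """Discretize a latent value (or index) by the cutpoint intervals.

    Boundary convention: half-open intervals assigned upward, i.e. a value
    exactly at a cutpoint belongs to the higher state.
    """
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ValidationError("latent value must be finite")
    codes = 1 + np.searchsorted(params.cut_array, z_arr, side="right")
    if codes.ndim == 0:
        return TrophicState(int(codes))
    return codes.astype(int)


def classify_map(probs) -> TrophicState | np.ndarray:
    """Maximum-probability state; ties break toward the lower state."""
    p = np.asarray(probs, dtype=float)
    if p.shape[-1] != N_STATES:
        raise ValidationError("probability vector must have 4 entries")
    codes = 1 + np.argmax(p, axis=-1)  # argmax takes the first maximum: lower state
    if codes.ndim == 0:
        return TrophicState(int(codes))
    return codes.astype(int)


def _states_to_codes(y) -> np.ndarray:
    codes = np.asarray(
        [int(v) if not isinstance(v, TrophicState) else v.value for v in y], dtype=int
    )
    if codes.size and (codes.min() < 1 or codes.max() > N_STATES):
        raise ValidationError("state codes must be in 1..4")
    return codes


def log_likelihood_terms(params: POLRParameters, X, y) -> np.ndarray:
    """Per-observation log probability log p_{y_i}(eta_i).

    Stable for |eta| up to ~700: interior classes use
    log p = log sigmoid(a) + log sigmoid(-b) + log1p(-exp(b - a))
    with a = eta - c_{k-1}, b = eta - c_k (a > b), and the edge classes use a
    single log-sigmoid.  Probabilities that underflow give -inf, not an
    exception.
    """
    X = np.asarray(getattr(X, "X", X), dtype=float)
    codes = _states_to_codes(y)
    if X.shape[0] != codes.shape[0]:
        raise ValidationError("X rows and y length differ")
    eta = X @ params.coef_array
    c = params.cut_array
    out = np.empty_like(eta)

    for k in range(1, N_STATES + 1):
        mask = codes == k
        if not mask.any():
            continue
        e = eta[mask]
        if k == 1:
            out[mask] = log_expit(c[0] - e)
        elif k == N_STATES:
            out[mask] = log_expit(e - c[2])
        else:
            a = e - c[k - 2]
            b = e - c[k - 1]
            with np.errstate(divide="ignore"):
                out[mask] = log_expit(a) + log_expit(-b) + np.log1p(-np.exp(b - a))
    return out


def log_likelihood(params: POLRParameters, X, y) -> float:
    """Total log likelihood sum_i log p_{y_i}(eta_i); -inf if any p underflows."""
    return float(np.sum(log_likelihood_terms(params, X, y)))


def save_model(
    path,
    params: POLRParameters,
    standardization: StandardizationSpec | None = None,
    standard_errors: Mapping[str, float] | None = None,
    meta: Mapping | None = None,
) -> None:
    """Write the model JSON file (parameters, standardization, SEs, metadata)."""
    payload = params.to_dict()
    payload["standardization"] = standardization.to_dict() if standardization else None
    payload["se"] = dict(standard_errors) if standard_errors else None
    payload["meta"] = dict(meta) if meta else {}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> tuple[POLRParameters, StandardizationSpec | None, dict]:
    """Read a model JSON file; returns (params, standardization or None, extras).

    ``extras`` carries the ``se`` and ``meta`` blocks unchanged, so a
    save/load/save round-trip is bit-identical.
    """
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    params = POLRParameters.from_dict(payload)
    spec = None
    if payload.get("standardization"):
        spec = StandardizationSpec.from_dict(payload["standardization"])
    extras = {"se": payload.get("se"), "meta": payload.get("meta", {})}
    return params, spec, extras
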