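"""Estimation of the proportional-odds model: maximum likelihood and Bayes.

The ordering constraint on the cutpoints is handled by the unconstrained
reparameterization

    c1 = t1,  c2 = t1 + exp(t2),  c3 = t1 + exp(t2) + exp(t3),

so a quasi-Newton optimizer (or an ensemble MCMC sampler) can move freely in
R^7 while every visited parameter vector has strictly ordered cutpoints.
The likelihood gradient is analytic; standard errors come from the observed
information (numerically differentiated analytic gradient) at the optimum,
on the natural (A, c) scale.

The Bayesian fit samples the same likelihood under independent Cauchy
(scale 2.5 by default) priors on the standardized coefficients and a flat
ordered prior on the cutpoints, using affine-invariant ensemble MCMC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .lake_data import (
    DegenerateDataError,
    InsufficientDataError,
    PREDICTOR_NAMES,
    ValidationError,
)
from .polr_core import (
    CUTPOINT_NAMES,
    N_STATES,
    POLRParameters,
    _states_to_codes,
    log_likelihood,
)

logger = logging.getLogger("laketsi")

__all__ = ["FitResult", "NonIdentifiableError", "fit_mle", "fit_bayes", "PARAM_NAMES"]

PARAM_NAMES = PREDICTOR_NAMES + CUTPOINT_NAMES


class NonIdentifiableError(ValidationError):
    """The likelihood has no interior maximum (e.g. a class never observed)."""


@dataclass
class FitResult:
    """Point estimates (or posterior means) with uncertainty and diagnostics."""

    params: POLRParameters
    standard_errors: dict[str, float] | None
    log_likelihood: float
    n_observations: int
    converged: bool
    method: str
    seed: int | None = None
    posterior_draws: np.ndarray | None = None  # (n_draws, 7) natural scale
    rhat: dict[str, float] | None = None

    def se_dict(self) -> dict[str, float]:
        return dict(self.standard_errors or {})


def _prepare(X, y):
    X = np.asarray(getattr(X, "X", X), dtype=float)
    codes = _states_to_codes(y)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValidationError(f"design matrix must be (n, 4), got {X.shape}")
    if X.shape[0] != codes.shape[0]:
        raise ValidationError("X rows and y length differ")
    n = X.shape[0]
    if n < 20:
        raise InsufficientDataError(f"need at least 20 observations, got {n}")
    present = set(codes.tolist())
    for k in range(1, N_STATES + 1):
        if k not in present:
            from .lake_data import TrophicState

            raise NonIdentifiableError(
                f"class {TrophicState(k).label!r} never observed; "
                "its cutpoints are not identifiable"
            )
    if np.any(X.std(axis=0) == 0):
        j = int(np.flatnonzero(X.std(axis=0) == 0)[0])
        raise DegenerateDataError(f"design column {PREDICTOR_NAMES[j]!r} is constant")
    return X, codes


def _unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unconstrained theta (7,) -> (coefficients (4,), ordered cutpoints (3,))."""
    A = theta[:4]
    c1, g2, g3 = theta[4], theta[5], theta[6]
    c = np.array([c1, c1 + np.exp(g2), c1 + np.exp(g2) + np.exp(g3)])
    return A, c


def _pack(A: np.ndarray, c: np.ndarray) -> np.ndarray:
    gaps = np.diff(c)
    if np.any(gaps <= 0):
        raise ValidationError("cutpoints must be strictly increasing")
    return np.concatenate([A, [c[0], np.log(gaps[0]), np.log(gaps[1])]])


def _loglik_and_grad_natural(A, c, X, codes):
    """Log likelihood and its gradient w.r.t. the natural (A, c1, c2, c3).

    Per-observation derivative identities (a = eta - c_{k-1}, b = eta - c_k):
      d log p / d eta   = sigmoid(c_{k-1} - eta) - sigmoid(eta - c_k)
      d log p / d c_{k-1} = -sigmoid(c_{k-1} - eta) - r
      d log p / d c_k     =  sigmoid(eta - c_k)   + r
    with r = 1 / (exp(c_k - c_{k-1}) - 1), and the obvious one-sided forms
    for the edge classes.  All terms stay bounded for extreme eta.
    """
    eta = X @ A
    n = eta.shape[0]
    logp = np.empty(n)
    deta = np.empty(n)
    dc = np.zeros((n, 3))

    for k in range(1, N_STATES + 1):
        m = codes == k
        if not m.any():
            continue
        e = eta[m]
        if k == 1:
            logp[m] = log_expit(c[0] - e)
            s = expit(e - c[0])
            deta[m] = -s
            dc[m, 0] = s
        elif k == N_STATES:
            logp[m] = log_expit(e - c[2])
            s = expit(c[2] - e)
            deta[m] = s
            dc[m, 2] = -s
        else:
            lo, hi = c[k - 2], c[k - 1]
            a = e - lo
            b = e - hi
            with np.errstate(divide="ignore"):
                logp[m] = log_expit(a) + log_expit(-b) + np.log1p(-np.exp(b - a))
            r = 1.0 / np.expm1(hi - lo)
            s_lo = expit(lo - e)
            s_hi = expit(e - hi)
            deta[m] = s_lo - s_hi
            dc[m, k - 2] = -s_lo - r
            dc[m, k - 1] = s_hi + r

    grad_A = X.T @ deta
    grad_c = dc.sum(axis=0)
    return float(logp.sum()), np.concatenate([grad_A, grad_c])


def _nll_unconstrained(theta, X, codes):
    A, c = _unpack(theta)
    ll, g_nat = _loglik_and_grad_natural(A, c, X, codes)
    # chain rule: c2, c3 depend on (c1, g2), (c1, g2, g3)
    gA, gc = g_nat[:4], g_nat[4:]
    g = np.empty(7)
    g[:4] = gA
    g[4] = gc.sum()
    g[5] = (gc[1] + gc[2]) * np.exp(theta[5])
    g[6] = gc[2] * np.exp(theta[6])
    return -ll, -g


def _observed_information(theta_nat, X, codes, rel_step=1e-6):
    """Negative-log-likelihood Hessian via central differences of the gradient."""
    p = theta_nat.size

    def grad(t):
        A, c = t[:4], t[4:]
        _, g = _loglik_and_grad_natural(A, c, X, codes)
        return -g

    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * (1.0 + abs(theta_nat[j]))
        up = theta_nat.copy()
        dn = theta_nat.copy()
        up[j] += h
        dn[j] -= h
        H[:, j] = (grad(up) - grad(dn)) / (2 * h)
    return 0.5 * (H + H.T)


def _default_init(codes: np.ndarray) -> np.ndarray:
    """Zero coefficients; cutpoints at the logits of cumulative class frequencies."""
    n = codes.size
    cum = np.array([(codes <= k).sum() for k in (1, 2, 3)]) / n
    cum = np.clip(cum, 1.0 / (n + 1), n / (n + 1.0))
    c = np.log(cum / (1 - cum))
    # enforce strict ordering if empirical frequencies tie
    for j in (1, 2):
        if c[j] <= c[j - 1]:
            c[j] = c[j - 1] + 1e-3
    return _pack(np.zeros(4), c)


def fit_mle(
    X,
    y,
    tol: float = 1e-8,
    init: POLRParameters | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the proportional-odds model.

    Maximizes the ordinal log likelihood over coefficients and ordered
    cutpoints via BFGS in the unconstrained reparameterization; ``converged``
    requires the gradient norm to fall below ``tol``.  Standard errors are
    the square roots of the diagonal of the inverse observed information.

    Raises :class:`NonIdentifiableError` when a class is absent from ``y``.
    Perfect separation (unbounded likelihood) is reported as a warning with
    ``converged=False`` rather than an exception.
    """
    X, codes = _prepare(X, y)
    theta0 = (
        _pack(init.coef_array, init.cut_array) if init is not None else _default_init(codes)
    )

    res = minimize(
        _nll_unconstrained,
        theta0,
        args=(X, codes),
        method="BFGS",
        jac=True,
        options={"gtol": tol, "maxiter": 500},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(grad_norm < max(tol, 1e-6))
    A, c = _unpack(res.x)

    separated = bool(np.max(np.abs(A)) > 30)
    if separated:
        warnings.warn(
            "coefficients diverged (possible perfect separation); "
            f"max |coef| = {np.max(np.abs(A)):.1f}",
            RuntimeWarning,
            stacklevel=2,
        )
        converged = False

    se: dict[str, float] | None = None
    if not separated:
        theta_nat = np.concatenate([A, c])
        H = _observed_information(theta_nat, X, codes)
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(diag > 0):
                se = dict(zip(PARAM_NAMES, np.sqrt(diag)))
            else:
                warnings.warn(
                    "observed information not positive definite; no standard errors",
                    RuntimeWarning,
                    stacklevel=2,
                )
        except np.linalg.LinAlgError:
            warnings.warn("singular information matrix; no standard errors",
                          RuntimeWarning, stacklevel=2)

    params = POLRParameters(coefficients=tuple(A), cutpoints=tuple(c))
    return FitResult(
        params=params,
        standard_errors=se,
        log_likelihood=-float(res.fun),
        n_observations=X.shape[0],
        converged=converged,
        method="mle",
    )


def _log_posterior(theta, X, codes, prior_scale):
    A, c = _unpack(theta)
    ll, _ = _loglik_and_grad_natural(A, c, X, codes)
    # Cauchy(0, prior_scale) on each standardized coefficient
    lp = -np.sum(np.log1p((A / prior_scale) ** 2))
    # flat ordered prior on cutpoints: Jacobian of the gap reparameterization
    lp += theta[5] + theta[6]
    return ll + lp


def fit_bayes(
    X,
    y,
    prior_scale: float = 2.5,
    chains: int = 4,
    draws: int = 2000,
    warmup: int = 1000,
    seed: int | None = None,
) -> FitResult:
    """Bayesian fit via affine-invariant ensemble MCMC.

    Weakly-informative Cauchy(0, ``prior_scale``) priors on the standardized
    coefficients; flat ordered prior on the cutpoints.  Each of ``chains``
    independent ensembles runs ``warmup + draws`` steps; post-warmup walker
    states are pooled per chain and split-R-hat is computed per parameter
    across chains.  R-hat above 1.1 produces a convergence warning in the
    result, never an exception.  Fully reproducible for a fixed seed.
    """
    import emcee

    if chains < 2:
        raise ValidationError("need at least 2 chains for convergence diagnostics")
    X, codes = _prepare(X, y)
    ndim = 7
    nwalkers = 4 * ndim  # even, > 2*ndim as the ensemble sampler requires

    mle = fit_mle(X, codes)
    center = _pack(mle.params.coef_array, mle.params.cut_array)

    root = np.random.SeedSequence(seed if seed is not None else 0)
    chain_seeds = root.spawn(chains)
    per_chain: list[np.ndarray] = []  # each (draws*nwalkers, 7) natural scale
    for ci in range(chains):
        rng = np.random.default_rng(chain_seeds[ci])
        p0 = center + 0.01 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, _log_posterior, args=(X, codes, prior_scale)
        )
        sampler.random_state = np.random.RandomState(
            int(rng.integers(0, 2**31 - 1))
        ).get_state()
        state = sampler.run_mcmc(p0, warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, draws, progress=False)
        flat = sampler.get_chain(flat=True)  # (draws*nwalkers, 7) unconstrained
        nat = np.empty_like(flat)
        nat[:, :4] = flat[:, :4]
        for i, t in enumerate(flat):
            _, c = _unpack(t)
            nat[i, 4:] = c
        per_chain.append(nat)

    stacked = np.stack(per_chain)  # (chains, draws*nwalkers, 7)
    pooled = stacked.reshape(-1, ndim)

    import arviz as az

    idata = az.convert_to_dataset({"theta": stacked})
    rhat_arr = np.asarray(az.rhat(idata)["theta"])
    rhat = dict(zip(PARAM_NAMES, (float(r) for r in rhat_arr)))
    if any(r > 1.1 for r in rhat.values()):
        warnings.warn(
            "R-hat exceeds 1.1 for some parameters; chains may not have mixed",
            RuntimeWarning,
            stacklevel=2,
        )

    means = pooled.mean(axis=0)
    sds = pooled.std(axis=0, ddof=1)
    cuts = np.sort(means[4:])  # posterior means of ordered draws stay ordered
    params = POLRParameters(coefficients=tuple(means[:4]), cutpoints=tuple(cuts))
    return FitResult(
        params=params,
        standard_errors=dict(zip(PARAM_NAMES, sds)),
        log_likelihood=log_likelihood(params, X, codes),
        n_observations=X.shape[0],
        converged=all(r <= 1.1 for r in rhat.values()),
        method="bayes",
        seed=seed,
        posterior_draws=pooled,
        rhat=rhat,
    )
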