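# Methods

## Model

Lake trophic state is modeled as an ordered categorical response with four
levels (oligotrophic < mesotrophic < eutrophic < hypereutrophic) generated
by a latent continuous trophic state index. For lake *i*:

- predictors: Secchi disk depth (m), total nitrogen (µg/L), total
  phosphorus (µg/L) — each natural-log transformed, since environmental
  concentration variables are canonically log-normal — and raw elevation
  (m, may be ≤ 0); all four are centered and scaled on the training set
  (sample SD, n−1 denominator);
- index: η_i = x_i'α with one slope per standardized predictor;
- latent state: z_i = η_i + ε_i, ε_i ~ standard logistic;
- observation: y_i = k iff c_{k−1} ≤ z_i < c_k for ordered cutpoints
  (c₁, c₂, c₃), c₀ = −∞, c₄ = +∞.

Equivalently logit Pr(y > k) = η − c_k (the proportional-odds /
cumulative-logit form). Two conventions are deliberate:

- **No intercept, unit latent scale.** Location is absorbed by the
  cutpoints and scale by the coefficients; a free intercept or latent scale
  would not be identifiable. All three cutpoints are free, ordered
  parameters.
- **Boundary convention.** The latent intervals are half-open, assigned
  upward: a value exactly at a cutpoint belongs to the higher state. (The
  interval classifier as usually written leaves boundary points unassigned;
  ties have probability zero under the continuous model, so this only fixes
  the documented edge case.)

Default parameters (`NLA_2007_PARAMS`) are the published point estimates
from the 2007 EPA National Lakes Assessment fit of this model:
α = (−1.69, 0.69, 0.55, −0.56) for (Secchi, TN, TP, elevation) and
c = (−3.36, −0.18, 2.62). The published source prints the phosphorus slope
as 0.55 in the classification formula and 0.56 in its coefficient table; we
use the formula value and note the 0.01 discrepancy here. The same source
reports a latent-scale entry τ² = 54.28 alongside the unit-scale latent
formulation; a free scale is not identifiable jointly with α and c, so the
package fixes the scale at 1 and does not use τ².

## Two classifiers

`classify_interval` applies the cutpoint-interval rule to η (the published
classification rule); `classify_map` takes the class with maximum
probability, breaking ties toward the less eutrophic state. The two agree
everywhere except in narrow bands (width < 0.2 for the default cutpoints)
just above c₁ and just below c₃, where the open-ended outer class keeps
probability ≥ 0.5 slightly past the cutpoint. Evaluation uses the interval
rule; both are exposed.

## Estimation

**Maximum likelihood.** The ordering constraint is removed by the
reparameterization c = (t₁, t₁ + e^{t₂}, t₁ + e^{t₂} + e^{t₃}) and the
likelihood is maximized by BFGS with an analytic gradient; the convergence
flag requires a gradient max-norm below `tol` (default 1e-8, floored at
1e-6 for the flag because BFGS halts at line-search precision on large
problems). Initialization: zero coefficients, cutpoints at the logits of
the cumulative class frequencies. Log probabilities use log-sigmoid
identities — for an interior class,
log p = log σ(a) + log σ(−b) + log1p(−e^{b−a}) with a = η − c_{k−1},
b = η − c_k — which are exact and cancellation-free for |η| far beyond 30,
where the naive F(a) − F(b) underflows. Standard errors are from the
inverse observed information, obtained by central finite differences of the
analytic gradient on the natural (α, c) scale; observed rather than
expected information is standard practice and matches reference software.
A class absent from the labels raises a non-identifiability error naming
the class; diverging coefficients (|α| > 30, the perfect-separation
signature) produce a warning and `converged=False`, never an exception.

**Bayesian fit.** `fit_bayes` samples the same likelihood in the
unconstrained space with affine-invariant ensemble MCMC (emcee), under
independent Cauchy(0, 2.5) priors on the standardized coefficients — the
conventional weakly-informative choice on this scale — and a flat ordered
prior on the cutpoints (the gap reparameterization's Jacobian e^{t₂+t₃} is
added to the log posterior). Defaults: 4 independent ensembles ("chains")
of 28 walkers, 1,000 warm-up + 2,000 retained steps, initialized in a tight
ball around the MLE. Post-warm-up walker states are pooled per chain;
split-R-hat across chains is reported per parameter and values above 1.1
set a convergence warning in the result. Runs are bit-reproducible for a
fixed seed. Posterior summaries are means/SDs of the pooled draws mapped
back to the natural scale.

## Variable selection

Candidates are ranked by out-of-bag permutation importance from a
regression forest: the 4-level response is treated as numeric 1–4, because
the importance measure is the percent increase in OOB mean squared error
under feature permutation and only a regression forest defines an MSE. For
each tree, the MSE on its out-of-bag lakes is compared with the MSE after
permuting one feature among those lakes; a feature's score is the mean
increase across trees as a percent of the forest's OOB MSE. Defaults:
5,000 trees, mtry = p/3. Tree induction is scikit-learn's
`RandomForestRegressor`; the OOB bookkeeping, the importance statistic and
the selection rule are implemented here.

Subset choice fits nested forests on the top-m ranked predictors
(m = 1..M, M capped at 15) and records each OOB MSE. The chosen size is the
smallest m beyond which **no** subsequent single-variable step reduces the
error by at least the threshold (default 0.1) — an error-increment (elbow)
reading of the "< 0.1 incremental impact" stopping rule, which also covers
curves with late dips. A flat curve selects one variable.

## Evaluation protocol

Reference single-variable classifications (chlorophyll-a-, TN- and
TP-based) rarely agree on every lake; the consensus filter keeps only lakes
whose available reference labels (at least two) are unanimous, and uses the
consensus as the observed state. Model assessment uses a random 90/10
train/evaluation split (evaluation size = round(n/10), minimum 1,
seed-deterministic), standardizes the evaluation lakes with the *training*
spec — never re-fit, to avoid leakage — predicts with the interval rule,
and reports overall accuracy plus one-vs-rest sensitivity, specificity and
balanced accuracy per class. Metrics are kept at full precision internally
and rounded only for display.

The published evaluation of the national-survey fit prints an overall
accuracy of 0.68 and balanced accuracies 0.93/0.83/0.72/0.73, alongside a
73-lake confusion matrix. Only the oligotrophic balanced accuracy (0.93)
is derivable from that matrix under its stated row-actual orientation (the
matrix itself gives 47/73 ≈ 0.64 overall and 0.93/0.75/0.70/0.75); the
package's tests pin the reproducible value and treat the others as an
unresolved inconsistency of the source report, not as targets.

## Synthetic data generator

The simulator draws survey-like datasets from the model's own generative
reading, which is exactly the condition under which parameter recovery is a
meaningful test:

- `standardized_normal` mode: the four design columns are iid N(0, 1) —
  the asymptotic behaviour of standardized predictors; raw measurements
  are synthesized by inverting the raw-parameter standardization so every
  sample still carries plausible positive concentrations.
- `raw_lognormal` mode: Secchi/TN/TP are lognormal and elevation normal,
  then the pipeline's own preprocessing (log, center, scale on the
  simulated sample) builds the design matrix — exercising the full
  read → transform → fit path.

Default raw distributions sketch a national survey: median Secchi 1.4 m,
median TN 600 µg/L, median TP 30 µg/L, each with log-SD 1, elevation
N(500, 400) m. Latent noise is added by inverse-CDF sampling of the
logistic from uniform deviates, for exact cross-platform reproducibility
given a seed. Reference labels for consensus-filter testing copy the true
state and independently perturb each of three pseudo-classifiers to an
adjacent state with a configurable probability (end states move inward).

What the generator does **not** emulate: spatial structure (ecoregions,
survey design weights), measurement error in Secchi readings, correlated
predictors (real log-TN and log-TP are strongly correlated), and reference
classifiers whose errors depend on the variable they use. Passing recovery
and accuracy tests therefore demonstrates correctness of the estimator and
pipeline under the model's own assumptions, not robustness to the
misspecification present in real survey data.

## Problem sizes and numerical choices

The test suite runs the recovery experiment at n = 20,000 (tolerance ±0.05
on every parameter), interval coverage at 110 replicates of n = 2,000, and
the variable-selection check on 10 seeds of a 400-lake, 70-feature table
with strong equal-magnitude signals — sizes chosen so the full suite
completes in about two minutes on one CPU while keeping Monte-Carlo error
well inside each tolerance. Quadrature oracles integrate the logistic
density between cutpoints with `scipy.integrate.quad` at 1e-13 absolute
tolerance and agree with the closed-form implementation to 1e-8.

## Known limitations

- Single-level model: no lake- or region-level random effects.
- Logit link only; no unequal-slopes (non-proportional) relaxation.
- The Bayesian sampler is an ensemble method: effective sample size per
  draw is lower than a well-tuned HMC sampler's; defaults are sized for the
  7-parameter posterior, not for extensions.
- Missing data are handled by row-wise deletion with a logged count; no
  imputation.
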