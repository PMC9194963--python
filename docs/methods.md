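# Methods

## Problem and model

`riskvoi` evaluates how much net benefit (NB) is expected to be lost because
a risk prediction model was developed on a finite sample. All quantities are
defined at a risk threshold *z* ∈ [0, 1): treating a patient is worth one
true positive minus *z*/(1 − *z*) per false positive (the exchange rate at
which a decision maker with threshold *z* is indifferent). The opt-in
convention fixes treat-none at NB ≡ 0. Thresholds equal to the predicted
risk leave the patient untreated (strict indicator); *z* = 1 is excluded
because the exchange rate diverges.

The unknown is the *correct model* — the strongly calibrated map from a
covariate pattern to the true average risk *p*θᵢ, indexed by parameters θ.
Conditional on a draw of correct risks, three strategies are scored on the
development sample:

* model: treat if *π*ᵢ > *z* (the proposed model's prediction),
* treat all,
* optimal: treat if *p*θᵢ > *z*.

Averaging over draws from P(θ | D) gives posterior-mean NBs, and

* EVPI(z) = NB̄_max − max{0, NB̄_model, NB̄_all},
* ΔNB_current = max{0, NB̄_model, NB̄_all} − max{0, NB̄_all},
* ΔNB_perfect = ΔNB_current + EVPI,
* EVPI_r = ΔNB_perfect / ΔNB_current.

EVPI_r is ≥ 1 where defined; it is represented as the explicit float `inf`
when ΔNB_current = 0 < ΔNB_perfect (the model adds nothing yet the correct
model would) and as an undefined flag (`nan` plus a boolean mask; an empty
CSV field) when ΔNB_perfect = 0. No silent NaN arithmetic occurs.

## Posterior sampling

Draws of correct risks are obtained by refitting the *entire*
model-development recipe on reweighted data and evaluating the refit model
on the original sample:

* **Bayesian bootstrap** — weights ~ Dirichlet(1,…,1), built as gaps
  between n − 1 sorted uniforms (u₀ = 0, uₙ = 1). Interpretable as posterior
  draws under a non-informative prior; every observation keeps positive
  weight, so developers must accept a weighted likelihood (all built-in
  ones do).
* **Ordinary bootstrap** — weights = Multinomial(n; 1/n,…,1/n)/n,
  equivalent to resampling rows with replacement (verified against
  resample-then-fit).
* **Likelihood-based MVN** — coefficients drawn from
  N(β̂_ML, Cov(β̂)) of an unpenalized logistic fit (a large-sample
  posterior under a flat prior), pushed through the inverse logit.
  Non-convergence or a non-positive-definite covariance raises explicitly.

Randomness is organized as one master seed whose `SeedSequence` spawns one
substream per draw, so draw *i* is reproducible regardless of execution
order and the whole sequence is bit-reproducible. Cross-validation folds
inside a developer are re-randomized from each draw's own substream, so
selection and shrinkage uncertainty propagate into the posterior.

**Degenerate-resample guard.** A weighted resample whose effective event
count n·Σwᵢyᵢ falls below `min_events` (default 1; set 8 to mirror the
practice of discarding sparse data sets where penalized optimizers are
unreliable) or with no non-event mass is redrawn up to `max_redraws = 100`
times; exhaustion is recorded as a failed draw, excluded from posterior
means, and reported in the diagnostics.

## Exact nonnegativity

EVPI ≥ 0 should hold per run, not merely in expectation, because all three
posterior means at a threshold use the *same* draws and the optimal rule
dominates per draw. Floating-point subset sums can in principle violate
such orderings, so the engine computes, per draw, the patient-level
contribution *t*ᵢ = *p*ᵢ − (1 − *p*ᵢ)·z/(1−z) and assembles the paired
differences "optimal minus strategy" from sign-definite partial sums
(positive terms the strategy misses, minus nonpositive terms it keeps).
EVPI is then the minimum over strategies of the mean paired difference —
algebraically identical to the defining formula, and nonnegative exactly in
IEEE arithmetic. For the same reason the optimal rule's treated set is
selected by *t*ᵢ > 0, which is mathematically equivalent to *p*ᵢ > *z*.
ΔNB_perfect is stored as ΔNB_current + EVPI so the decision-curve identity
is exact. Ties in max{0, NB̄_model, NB̄_all} are resolved toward the simpler
strategy (none > all > model), crediting the model only when strictly
better.

**Monte Carlo error.** The reported `mc_se` is the standard error of the
EVPI estimate, computed from the per-draw paired differences of the
strategy that is best under current information; per-mean SEs of the three
NB curves are kept alongside. A warning fires when `mc_se` exceeds 10% of
the EVPI. The default is 1000 draws.

## Model developers

A developer encapsulates the development recipe behind
`fit(sample, weights, rng) → model.predict_risk(X)`:

* `LogisticDeveloper` — exact maximum-likelihood logistic regression
  (scikit-learn, `newton-cholesky`, C = ∞). Covariates are standardized
  internally for the optimizer and coefficients mapped back — exact for an
  unpenalized fit and markedly faster on clinical covariate scales. Under
  quasi-separation the solver falls back gracefully and returns the usual
  large-but-finite coefficients.
* `LassoLogisticDeveloper` — L1-penalized logistic regression with the
  penalty chosen by stratified k-fold cross-validation (default 10-fold,
  10 penalty values) *inside every fit call*, folds drawn from the caller's
  rng. Standardization makes the penalty scale-invariant (the glmnet
  convention). This is the faithful recipe for shrinkage-based development
  but costs ~100 inner fits per draw; at 1000 draws budget minutes, not
  seconds.
* `InterceptOnlyDeveloper`, `OracleDeveloper` / `point_mass_developer` —
  degenerate posteriors used for calibration of the machinery: an oracle
  wrapping the proposed model must give EVPI ≡ 0 (no uncertainty), and an
  oracle wrapping the true data-generating risks is the
  perfect-information limit.

## Optimism correction

`harrell_correct` estimates, per bootstrap replicate, metric(new model on
the resample) − metric(new model on the original sample), averaged over
replicates; corrected = apparent − mean optimism, computed pointwise per
threshold for the decision-curve NB (no smoothing) and for the c-statistic
(ties count ½). Resample metrics are computed as weighted metrics on the
original rows with multinomial weights, which is what makes `joint_loop`
possible: one ordinary-bootstrap pass yields both the EVPI draws and the
optimism contributions, and equals the two separate runs under a shared
seed. The classical estimator is defined for resamples, so the joint loop
always uses the ordinary bootstrap; Bayesian-bootstrap replicates are never
used for optimism.

## Synthetic data

`LogisticDGP` draws covariates per predictor spec (normal or Bernoulli),
applies transforms — `truncate_above(c)` (risk flat above a cap) and
`linear_spline(knot)` (basis *x*, max(0, *x* − knot)) — forms true risks
through the inverse logit, and samples Bernoulli outcomes. True risks are
returned only alongside the sample, for oracle tests; no fitting interface
accepts them.

The `gusto_like` preset emulates the *structure* of a 30-day
post-infarction mortality setting: ~7% event rate, an age-like predictor,
a truncated systolic-blood-pressure-like predictor (min(X, 100)), a
pulse-like predictor with a spline knot at 50, and four binary indicators.
Coefficients are package defaults, not estimates from any real cohort. The
intercept (−1.326) was calibrated once by large-n simulation to a 7%
marginal event rate. The pulse distribution (N(70, 17)) is deliberately
centered near the knot: a knot far below the data leaves the hinge column
nearly collinear with the intercept, and the flat likelihood direction
destabilizes unpenalized refits. What the generator does *not* emulate:
correlated predictors, measurement error, missing data, miscalibration of
the logistic form, or clustering — so green tests demonstrate the
machinery's correctness under a well-specified DGP, not performance on
real registry data.

`sample_size_sweep` draws data sets of increasing size (fresh from a DGP,
or without replacement from a parent sample), develops a model on each,
and reports the mean EVPI and the median relative EVPI across replicates
per (size, threshold). Data sets with fewer than `min_events_dataset`
(default 8) events are redrawn. Undefined relative-EVPI values are excluded
from the median and counted; the +∞ sentinel orders normally, so a median
can itself be +∞ at small n.

## Numerical and design choices

* Default threshold grid 0.00–0.99 in steps of 0.01 plus user-specified
  thresholds; grids and configs reject z ≥ 1.
* CSV output uses 6 significant digits; `Inf` and empty-field encodings of
  the relative EVPI round-trip through `read_voi_csv`.
* One-hot encoding drops an alphabetical reference level, which is
  recorded in the diagnostics; missing values are an error (no imputation).
* Problem sizes in the test suite (e.g. 150–1000 rows, 20–500 draws,
  sweep sizes 250/1000/4000 with 200 draws) were chosen as the smallest
  configurations at which the statistical properties under test are
  well-resolved.

## Known limitations

* The two bootstrap flavours agree only to second order. With an
  unpenalized developer at n = 1000 and a 7% event rate, the ordinary
  bootstrap yields systematically higher EVPI (≈5–25% at thresholds
  0.01–0.25) than the Bayesian bootstrap: multinomial resampling discards
  ~e⁻¹ of the (rare) events entirely, producing heavier-tailed refit draws
  than the strictly positive Dirichlet weights. Shrinkage-based developers
  tame those tails and bring the schemes closer, at substantial
  computational cost. When the two flavours disagree materially, that is
  itself a sign that the posterior is tail-sensitive at the current sample
  size.
* Development EVPI only: validation-phase EVPI and the expected value of
  sample information are out of scope, as are treatment-benefit models and
  risk-attitude-adjusted criteria.
* The likelihood-based MVN sampler assumes the unpenalized logistic MLE
  exists and its covariance is positive definite; it propagates no
  selection/shrinkage uncertainty.
* No missing-data handling inside the resampling loop.
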