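# Methods

## Model and estimation

The discrete-time survival mediation model combines a linear mediator
regression with a proportional-odds discrete-time hazard:

```
M_i = β01 + a·X_i + ε1_i,                       ε1 ~ N(0, σ_m²)
logit P_h(t_j | X_i, M_i) = β02 + c′·X_i + b·M_i
```

`b` and `c′` are log odds ratios; the corresponding design factors are
stated as odds ratios (so a mediator odds ratio of 1 is a null effect) and
log-transformed before entering the linear predictor. The baseline hazard
is constant across intervals; `β02 = logit(h0)` is stored at full
precision (e.g. −1.38629… for `h0 = 0.2`, −2.9444… for `h0 = 0.05`).

The mediator model is fit by OLS (residual SD uses the n−2 denominator).
The hazard model is fit by Newton–Raphson maximum likelihood on the
person-period expansion, with step halving so the log-likelihood is
non-decreasing across iterations. Convergence is declared when the maximum
absolute score component falls below 1e−8 or the step norm below 1e−10
(at most 100 iterations); a fit that fails to converge while some
coefficient exceeds 15 in absolute value is flagged as separated. Fits are
cross-checked in the test suite against statsmodels' logistic regression
to ≤1e−6 agreement.

Because covariates are time-invariant and the baseline is constant, a
subject's person-period rows share one linear predictor and collapse to a
single binomial observation (intervals at risk, event indicator). The
default constant-baseline fit uses this collapsed likelihood — it is
algebraically identical to the row-level one and roughly `J` times
cheaper. A per-interval-intercept baseline (`baseline="per-interval"`) is
available and fits at the person-period level with one intercept per
interval; the constant baseline is the default because it matches the
generating process and the single-intercept hazard equation, aligning the
estimand with the simulation design. A probe during development showed the
two baselines give practically identical bias for the mediated effect
under this generating process.

Post-event intervals are recoded to a missing sentinel and contribute no
likelihood terms. Under administrative, non-informative censoring at `J`
this is exactly the full-information maximum-likelihood treatment of the
censored event times; no imputation is involved. The latent logistic
disturbance of the threshold representation of the hazard equation is not
an estimable residual and carries no parameter.

## Mediated effects

* Product of coefficients: `ab = â·b̂`, exactly, by construction.
* ACME on the logit scale: `E[η(t, M(1))] − E[η(t, M(0))]` with
  `M(x) ~ N(β̂01 + â·x, σ̂²)` and `η` the fitted linear predictor.
  Integration is 64-node probabilists' Gauss–Hermite quadrature by
  default, or plain Monte Carlo (≥1e5 draws) as an independent check.
  With a linear `η` the two counterfactual means differ by `â`, so the
  ACME equals `â·b̂` for either exposure arm; the test suite asserts this
  equivalence to 1e−6 on every converged fit, and exposure-arm invariance
  to 1e−8.

The ACME is reported on the logit (linear-predictor) scale, where the
product-of-coefficients identity holds; a hazard-probability-scale effect
is out of scope. The identity requires no exposure–mediator interaction
and sequential ignorability; neither is testable from the simulated data,
which satisfy both by construction.

## Bootstrap inference

Percentile bootstrap with subject-level resampling (entire rows — never
person-period rows, which would break within-subject dependence). Defaults:
1000 draws, α = 0.05. Confidence limits are the α/2 and 1−α/2 empirical
quantiles with linear interpolation between order statistics (numpy's
default "linear" method); the convention is recorded on the result object.
Non-converged refits are dropped (not redrawn) and counted; if more than
20% fail the result is flagged unreliable. Both the `ab` and ACME
intervals are formed from the same resamples, one refit per resample.

Two refit engines exist: a reference loop over `fit_dtsm`, and a
vectorized engine that runs the Newton iterations for all resamples
simultaneously on the collapsed binomial likelihood. Both consume the same
resample-index matrix, and the test suite asserts their draws agree to
1e−8; the vectorized engine is the default. The vectorized engine damps
(rather than halves) oversized Newton steps and discards diverging
resamples as non-converged.

## Data generation

Exposure `X ~ Bernoulli(0.5)`; mediator `M = a·X + ε`, `ε ~ N(0,1)`
(`β01 = 0`); event indicators drawn interval by interval from standard
logistic thresholds, `e_ij = 1` iff `y_ij > −(β02 + ln(c)·X + ln(b)·M)`,
which is Bernoulli with the model hazard; entries after the first event
are recoded missing. Each interval uses its own spawned PCG64 sub-stream,
and all study randomness derives from `(master seed, condition id,
replication)` seed-sequence keys, so any replication is reproducible in
isolation and no global RNG state is involved. Only administrative
censoring at `J` is generated — no dropout, competing risks, or
time-varying covariates — so passing tests speak to the model's behaviour
under clean, correctly-specified conditions, not under the messier
missingness patterns of real panel data.

## Monte Carlo study

Factor levels (full factorial, 384 cells): `J ∈ {4,8}`,
`n ∈ {250,500,1000}`, `a ∈ {0,0.14,0.39,0.59}`, `b ∈ {1,1.5,2,4}` (odds
ratio), `c′ ∈ {1,1.5}` (odds ratio), `h0 ∈ {0.05,0.2}`. The population
mediated effect is `θ = a·ln(b)` on the log-odds scale; defining `θ` on
the odds-ratio scale instead would leave `b = 1` cells with an undefined
rather than zero effect, which is incompatible with analysing them as
Type I error cells. Null cells are those with `a = 0` or `b = 1`
(96 + 96 − 24 = 168 of 384).

Outcome measures per cell: relative bias `(Ê(θ̂) − θ)/θ` (defined only for
θ ≠ 0), raw bias `Ê(θ̂) − θ`, MSE `(1/R)Σ(θ̂ − θ)²` with its exact
decomposition into variance (1/R denominator) plus squared bias, and the
rejection rate of the 95% bootstrap interval (power when θ ≠ 0, Type I
error when θ = 0). Replications whose base fit fails are excluded from
aggregates and counted.

The full-scale design is R = 500 replications and 1000 bootstrap draws.
The built-in evaluation runs (acceptance script and test suite) use
reduced sizes chosen to keep single-CPU runs in the minutes range while
leaving Monte Carlo error well inside the assertion bands: R = 200 for
bias/MSE over all 384 cells, and R = 150 with 300 bootstrap draws over a
stratified sample of six null cells (spanning both hazards, all sample
sizes, both interval counts and both null types) for Type I error.
Parameter-recovery checks use a single replicate of n = 50 000 per
effect-size combination and a 4-SE band.

The cell-level factorial ANOVA decomposes one outcome value per cell over
all 63 main effects and interactions of the six factors via the balanced
inclusion–exclusion of conditional means; with one value per cell there
is no residual and the effect sums of squares add exactly to the total.
η² = SS_effect/SS_total, screened at η² ≥ 0.01 (at least 1% of variance).
Cell-level analysis is used because MSE and rejection rates only exist at
cell level. η² magnitudes from full-scale runs are inherently stochastic;
the package asserts the qualitative orderings (MSE falls with n; power
rises with n, a and b; the baseline hazard matters most when b is small)
on scaled-down runs rather than any particular η² value.

## Numerical and design notes

* Missing event entries use an integer sentinel distinct from 0/1 and are
  serialized as empty CSV cells.
* The bootstrap quantile convention, the drop-and-count policy for failed
  refits, and the subject-level resampling unit are deliberate choices
  where more than one defensible convention exists; each is recorded on
  the result objects or here.
* A fully degenerate dataset (zero mediator variance within exposure
  groups) makes exposure and mediator collinear in the hazard model, so
  the fit is not identified; such inputs surface as non-converged fits
  rather than silent output. The zero-variance limit of the percentile
  interval (all draws equal ⇒ the interval collapses to a point) is
  exercised directly on the quantile routine instead.
* Relative-bias and MSE averages over cells weight cells equally,
  regardless of completed replications.

## Known limitations

Time-varying exposures or mediators, exposure–mediator interactions,
non-proportional effects, probit links, multiple mediators, frailty terms,
informative censoring and competing risks are all out of scope. Power at
small `a` with n ≤ 1000 is poor (an estimator property, not a software
one), and the harness deliberately does not extrapolate beyond the factor
levels above.
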