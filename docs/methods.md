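# Methods

## Outcome model

A DAWOLS-type outcome is constructed from a complete daily-state table:
per patient, one state in `{home, hospital, life_support, dead}` for each
day 1..`max_days` after randomisation (1-based days, closed window). The
raw count is the number of days whose state lies in the configurable
*free-state* set — `{home, hospital}` for DAWOLS ("alive and not on life
support"), `{home}` for DAOH. Days after discharge and days between repeat
life-support episodes count; the day of death and every later day are
`dead` (death is absorbing), and any day with state `life_support` counts
as a supported day — the boundary convention for initiation/cessation days
is not standardised in the field, so we fix this one and state it.

Death handling is explicit and orthogonal to counting:

* `penalize_zero` — non-survivors get 0 days (the conventional "worst
  value" penalty);
* `penalize_minus_one` — non-survivors get −1, a category below every real
  value; only valid on the ordinal scale;
* `actual` — the raw count is kept regardless of death.

Survivors are unaffected by the rule, which gives the invariants used in
testing: outcome(`penalize_zero`) ≥ outcome(`penalize_minus_one`) with
equality exactly for survivors, and building with `actual` then penalising
equals building with the penalty directly.

Missing daily rows and non-absorbing death sequences are hard errors, not
imputation targets: the construction assumes complete follow-up, and
censoring/competing-risk handling is out of scope.

## Regression families

All four families support any number of arms and covariates; covariates
enter every sub-model by default (configurable per sub-model). Design
matrices are treatment-coded with the first declared arm level as control.

* **Linear**: y ~ N(xβ, σ²). σ is the MLE scale. No range restriction, so
  predictive draws can leave [0, max_days] in both directions.
* **Hurdle negative binomial** (days scale, deaths coded 0): a logistic
  sub-model for π = P(y = 0) and a zero-truncated NB for y ≥ 1 with log
  link for μ and dispersion φ (Var = μ + μ²/φ, so
  P(0) = (φ/(μ+φ))^φ). The likelihood contribution for positives divides
  by 1 − P(0); the truncated conditional mean is μ/(1 − P(0)).
* **Zero–one-inflated beta** (proportion scale y = days/max_days): the
  three-part factorisation P(boundary) → P(one | boundary) → interior
  Beta(μ_b φ_b, (1 − μ_b) φ_b), all logit-linked, precision φ_b > 0.
  Boundary membership must be decided on the integer day counts before
  rescaling; `to_proportion` guarantees exact 0.0/1.0 at the boundaries.
  The mixture mean is αγ + (1 − α)μ_b.
* **Cumulative logistic** (ordinal scale, death as −1): categories are the
  distinct observed values sorted ascending; P(Y ≤ k) = F(θ_k − xβ) with
  logistic F and strictly increasing cutpoints θ. A positive arm
  coefficient means better categories; exp(β_arm) is the cumulative odds
  ratio. The single β across cutpoints is the proportional-odds
  assumption.

### Fitting and uncertainty

Point estimates are maximum likelihood. Sub-models with separable
likelihoods (hurdle and ZOIB parts) are fitted separately: logistic parts
by Newton/IRLS, the zero-truncated NB and beta parts by L-BFGS-B with
analytic gradients, and the cumulative-logit model jointly. Positive
parameters (φ, φ_b, σ) are optimised on the log scale; cutpoints as
(first cutpoint, log successive differences), which keeps the ordering
constraint implicit. Starting values are moment-based (empirical logits,
mean of positives, method-of-moments dispersion, empirical cumulative
logits); gradient tolerance 1e−8, function tolerance 1e−13 (needed for the
exactness of saturated fits to ~1e−6 or better).

(Quasi-)complete separation in a logistic sub-model — e.g. an arm without
zeros — is detected by non-convergence or runaway coefficients and handled
by a Jeffreys-penalised (Firth) refit with a logged warning, never a crash
or a silently divergent estimate.

Uncertainty comes from a **parametric bootstrap** (default D = 1000
refits of data simulated from the fitted model, warm-started at the MLE).
With the flat/weakly-informative priors typical for these models the
posterior mode coincides with the MLE, so bootstrap draws serve the same
downstream contract as posterior samples: every derived quantity is
computed per draw and summarised by the median and the 2.5/97.5
percentiles. A pluggable sampler interface (`SamplerConfig`: 4 chains,
10,000 iterations, 2,500 warmup, Rhat ≤ 1.01) is defined for MCMC
backends; none is shipped. Degenerate bootstrap replicates (a sub-model
losing all its observations) keep the point estimate for that sub-model
and are flagged, as is any non-converged refit.

Quantiles use numpy's linear-interpolation rule throughout — the same rule
for parameter draws, estimands and diagnostic intervals.

## Estimands

Every family is reduced to the expected mean outcome on the days scale per
arm and draw: linear xβ; hurdle (1 − π)·μ/(1 − P(0)); ZOIB mixture mean ×
max_days; cumulative logit Σ_k v_k p_k over the category value map. The
death category −1 enters the cumulative-logit sum either replaced by 0
(`minus_one_as_zero`) or as-is (`minus_one_as_is`); both variants are
reported. Predictions are truncated to the valid space **at the patient
level before averaging** ([0, max_days], or [−1, max_days] for the as-is
variant); clamping is idempotent, and clamp-then-average is the
implemented order.

Group means are **marginal (standardised)** when covariates are present:
each arm's mean averages patient-level predictions over the pooled
analysis set with every patient's arm set to the target level, which
handles the non-collapsibility of the logit-linked sub-models. A
conditional mode (each arm's own patients at observed covariates) is
available behind a flag.

Mean difference and ratio of means are computed per draw
(intervention − control, intervention/control, one contrast per
non-control arm); draws with non-positive control means are excluded from
the ratio with a warning and are an error above 1% of draws. The
cumulative OR is exp of the arm coefficient per draw. Hypothesis-test
p-values are deliberately absent: the package reports estimates with
uncertainty.

## Diagnostics

RMSE and MAE compare **patient-level expected predictions** (clamped,
days scale) with the observed data, per draw: RMSE_d = √(mean_i
(pred_di − y_i)²), MAE_d = median_i |pred_di − y_i|. Expected-value
predictions (not predictive draws) are what make error measures nearly
identical across families whose predictive distributions differ — the
point of the comparison. MAE is the median over patients within a draw and
the reported summary is the median over draws (the mean-over-draws
alternative is a one-line change). Both cumulative-logit death-code
variants are evaluated against the deaths-coded-0 outcome vector, so the
as-is variant's RMSE can only be larger. Evaluation is in-sample by
design; pass a holdout table explicitly for out-of-sample errors.
Information-criterion comparison is deliberately omitted: the families use
different outcome transformations, so their likelihoods are not
comparable.

Predictive checks sample replicated outcome vectors (one parameter draw
per replicate), clamp them to the outcome space and round to the integer
day grid so continuous families are comparable with counts. The
discrepancy score is the total-variation distance between replicate and
observed value histograms; the calibration band is the central 95% of
replicate-vs-replicate distances, and per-replicate proportions at the
minimum and maximum support automated envelope assertions alongside the
plots.

The proportional-odds check is empirical: per cutpoint k,
log odds(Y ≤ k | control) − log odds(Y ≤ k | intervention) with the
Haldane–Anscombe 0.5 correction. A flat profile is consistent with
proportional odds; a sign change is the classic signature of a treatment
whose mortality effect opposes its survivor-days effect.

## Synthetic-data generator

Each arm is a three-component mixture chosen to emulate the shape of real
DAWOLS data: death with probability `p_death` (worst value under the
spec's penalty), the maximum with probability `p_max` among survivors
(patients never on support within follow-up), and otherwise free days from
a negative binomial (mean `interior_mean`, dispersion
`interior_dispersion`) truncated to {1..max_days − 1}. The interior is
negative-binomial so that the hurdle-NB family is correctly specified in
at least one scenario; proportional-odds-consistent ordinal data come from
a separate generator that shifts all cumulative logits by a single log-OR,
because the mixture deliberately violates proportional odds whenever arm
effects on mortality and survivor days differ.

The default conditions (`COVID_LIKE`) represent a two-arm ICU trial of 971
patients with 28-day follow-up: ~30% mortality (0.32 control / 0.28
intervention), a substantial maximum spike (p_max 0.25/0.28), and a
right-skewed interior (means 20/21 days, dispersion 3), giving true group
means of about 12.2 and 13.4 days. These values were fixed once as a
realistic severe-respiratory-failure profile and are the conditions under
which all package-level checks run.

Generator properties that real data need not share:

* non-survivors remain on life support until death, so their raw counts
  are 0 and the `actual` death-handling rule coincides with
  `penalize_zero` for them;
* survivors always have ≥ 1 free day, so minimum-inflation equals the
  death fraction;
* daily trajectories place the supported days as one leading block (then
  up to two hospital days, then home), so re-collapsing the daily table
  reproduces the sampled outcomes exactly; death days follow a
  geometric(0.15) distribution truncated to the window and affect only the
  daily expansion.

Consequently, passing tests demonstrate correct likelihoods, estimands and
calibration under these conditions — not robustness to covariate-dependent
missingness, readmission linkage, partial follow-up or interior shapes far
from negative binomial.

The RNG contract: one root seed, with per-arm child streams keyed by a
hash of the arm name, so adding an arm to a scenario never perturbs the
other arms' draws.

## Numerical choices and degenerate inputs

* Logistic CDF/expit throughout; linear predictors for μ clipped at ±30 on
  the log scale inside the truncated-NB objective to avoid overflow.
* Zero-truncated NB sampling is vectorised rejection with a floor at 1
  for the (practically unreachable) exhaustion case μ → 0.
* ZOIB interior bootstrap draws are clipped to [1e−9, 1 − 1e−9] so the
  boundary indicator stays identified on refits.
* Fewer than 3 distinct ordinal values is an error (use logistic
  regression); an all-zero hurdle response or an all-boundary ZOIB
  response is an error at the initial fit and a flagged
  keep-the-point-estimate event inside the bootstrap.
* Problem sizes in the test suite (n = 500–1000 per arm, D = 60–200
  draws, 100–200 replicates) were chosen as the smallest sizes at which
  the binomial/Monte-Carlo tolerances of the checks are meaningful.

## Known limitations

* The bootstrap engine approximates a flat-prior Bayesian analysis; with
  informative priors (which the multi-part models make hard to elicit in
  any case) an MCMC backend would be needed via the sampler interface.
* Marginal standardisation averages over the pooled analysis set; other
  standardisation populations require passing the target table explicitly.
* The generator's single optional prognostic covariate is binary with an
  additive interior-mean effect; covariate-dependent mortality or
  maximum-inflation is not generated.
* Partial proportional-odds, quantile, beta-binomial, ordinal-beta,
  time-to-event and state-transition alternatives are out of scope.
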