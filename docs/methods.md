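# Methods

This note documents the models, priors, numerical machinery and design
choices behind `brackish`, and what the synthetic-data layer does and
does not establish about real data.

## Meta-analysis model

Each extracted observation is a proportion surviving, `y_ij`, for study
`j` at salinity `s_ij` (ppt), within one life stage (egg, tadpole,
adult). Proportions are modelled with the mean–precision beta
distribution, `y ~ Beta(mu*phi, (1-mu)*phi)`, because extracted
survivorship typically lacks the sample sizes needed to reconstruct
counts; the mean follows a logistic dose–response with a study random
intercept:

    logit(mu_ij) = beta0 + beta1 * s_ij + u_j,  u_j ~ Normal(0, sigma_u^2).

**Priors.** `beta0, beta1 ~ Normal(0, variance 1000)`. Reports of this
protocol state a zero-mean Gaussian coefficient prior with the figure
0.001 attached, nominally as a standard deviation; we read that figure
as a *precision* of 0.001 (the conventional diffuse prior in JAGS-style
samplers, variance 1000) — a literal SD of 0.001 would pin every
coefficient at zero and is incompatible with any nonzero fit.
`sigma_u ~ Uniform(0, 10)` and
`phi ~ Gamma(0.01, 0.01)` are weakly informative defaults. All priors
are configurable.

**Boundary proportions.** The beta likelihood has open-interval support
while extracted data contain exact 0s and 1s. Only those boundary values
are compressed, with `(y*(n-1) + 0.5)/n` using the study's N (imputed as
10 when missing, which matters only for how far off the boundary the
value lands). Interior proportions enter untouched: applying the
compression to every observation shrinks the whole response toward 0.5
and visibly biases the slope, so the transform is reserved for the
values that need it. `compress_proportions` itself implements the full
transform, which is order-preserving for n ≥ 2 (at n = 1 it collapses to
0.5) and leaves 0.5 fixed.

**One observation = one extracted (study, salinity) mean.** Replicate
SDs are retained in the data model but not used as weights; exposure
duration is recorded but is not a covariate.

## LC50 and prediction

All derived quantities are computed per posterior draw at the typical
study (`u = 0`), keeping the LC50 closed-form: `LC50 = -beta0/beta1`,
the salinity where the survival curve crosses 0.5. Draws with
`beta1 >= 0` carry no decreasing dose–response and are excluded (the
estimate is refused if they are the majority); negative transformed
values are truncated to 0 ppt and flagged, which is what produces
intervals like "(0–x ppt)" for weakly informed stages. The point
estimate is the posterior median, intervals are central 95% quantiles.
Survival curves report the posterior mean and central 95% envelope of
`logit^-1(beta0 + beta1 s)`; predictions are conditional on `u = 0`
rather than marginalised over `sigma_u`.

## Common-garden models

Oviposition and hatching are two-stage (hurdle) analyses. The analysis
unit for the Bernoulli stages is the **cup** (any eggs laid / any
hatched), with bins nested in location as random intercepts; the
investment stage models eggs laid in the three freshwater cups out of
all eggs in the bin, with the bin's salt treatment as the covariate; the
conditional hatch stage models hatched out of laid per cup, excluding
cups with nothing laid (or hatched). All four share the linear
predictor

    logit(p) = g0 + g_s*s + g_L*[coastal] + g_sL*s*[coastal] + b_group,

with inland (salt-naïve) as the reference level. Tadpole survival over
the six-day acclimation ramp uses the conditional chain
`alive_t ~ Binomial(alive_{t-1}, p_t)` with
`logit(p_t) = d0 + d_s*s_t + d_L + d_sL*s_t + d_d*t + c_clutch`; the day
effect is linear on the logit scale (the functional form is otherwise
unspecified in the protocol). Days that begin with no survivors
contribute nothing, so an all-dead-on-day-1 series keeps the likelihood
defined. Six-day survival at a target is the product of daily
probabilities along the ramp schedule.

**Ramp schedule.** Day `d` of a ramp to target `T` is at `d * inc` ppt
with the protocol's printed increments (0.67, 1, 1.33, 2 ppt/day for
T = 4, 6, 8, 12); the 0.5 ppt control is constant. This convention
reproduces both the printed increments and the day-6 targets (within
0.02 ppt for the rounded 0.67/1.33 increments); starting every arm at
0.5 ppt and incrementing afterwards cannot reach 12 ppt by day 6 with a
2 ppt/day increment, so it was rejected.

**Informed priors.** Propagation from the meta-analysis posterior is by
moment matching: the garden intercept and salinity slope receive
Gaussian priors with the mean and SD of the `beta0` and `beta1`
marginals, times a configurable inflation factor (default 1, SD floored
at 0.01); location and interaction terms keep diffuse priors because the
meta-analysis contains no population contrast. A known limitation: a
well-estimated upstream posterior is a very dogmatic prior (with ~180
meta records the slope prior SD is ~0.01), and the meta intercept
describes *cumulative* survival while the tadpole model's intercept
describes *daily* survival — a scale mismatch no inflation factor truly
fixes. The mechanism is kept as designed and the shrinkage property
holds (informed priors never widen the targeted posteriors), but users
propagating across response scales should inflate substantially (the
pipeline example uses 10) or keep flat priors; the acceptance script
fits the garden models with flat priors so its reported quantities
measure recovery of the generator's own truth.

## Sampler

No general-purpose hierarchical MCMC library is part of the dependency
set, and the models are small, so inference uses a purpose-built
Metropolis scheme over the joint posterior:

- componentwise Gaussian random-walk updates for each fixed parameter on
  an unconstrained scale (log for `phi`, scaled-logit for the
  interval-bounded random-effect SDs), with scales adapted toward 0.44
  acceptance during burn-in only;
- one vectorised block update for all random intercepts per sweep (they
  are conditionally independent given the fixed effects);
- a joint adaptive proposal over the fixed effects using the running
  empirical covariance (Haario-style, frozen at the end of burn-in), for
  posteriors with strong coefficient correlation — e.g. the tadpole
  model, where day and salinity are nearly collinear along the ramp;
- likelihood-invariant "shift" moves: for any fixed effect whose
  covariate is constant within groups (value `x_g` in group `g`),
  proposing `coef += eps, u_g -= eps*x_g` leaves every linear predictor
  unchanged and is accepted on the prior ratio alone. These are the
  weakly identified ridges of hierarchical models — the intercept vs.
  the mean random effect with few groups (the three-study adult stage),
  or all four fixed effects in the investment model, whose covariates
  are bin-constant and whose ~1400-egg binomials make each bin's
  intercept nearly exact. Without these moves those fits do not mix.

Chains (default 3 × 5000 iterations, burn-in 2500; 4 × 50000, burn-in
25000 for the tadpole model) start from overdispersed positions whose
spread varies by an order of magnitude across chains. Convergence is
gated on the Gelman–Rubin statistic in its classic form,
`sqrt(((n-1)/n W + B/n)/W)`, computed for every parameter including the
random intercepts; a fit with max R̂ ≥ 1.1 is flagged non-converged, and
pipeline stages that would consume its posterior as a prior refuse to
run unless overridden. Correctness is cross-checked in the test suite
against closed-form conjugate posteriors, dense grid-search maximum
likelihood (single-study fits with `phi` fixed), and statsmodels GLM
estimates on heterogeneity-free data — never against the sampler itself.

## Salinity units

All salinities are converted to parts per thousand with fixed linear
factors: g/L ≡ ppt, mg/L ÷ 1000, % seawater × 0.35 (seawater = 35 ppt),
mol NaCl/L × 58.44 (molar mass), and mS/cm × 0.64 — a freshwater-range
linear approximation chosen for reproducibility; the conversions used
by the original compilers of such tables are not itemised anywhere, so
a single documented constant per unit is preferred over a nonlinear
practical-salinity conversion.

## Synthetic-data layer

The generators emulate the statistical structure of the three data
layers with known ground truth:

- **Meta tables**: per study, `u_j ~ N(0, sigma_u^2)`; per salinity, a
  Beta-distributed proportion around the logistic mean. Defaults: 30
  studies for egg and tadpole stages, 3 for adults (matching that
  stage's thin literature), `sigma_u = 0.3`, `phi = 20`, and per-stage
  coefficients whose implied LC50s sit at 4.15, 5.44 and 9.04 ppt — the
  published dose–response scales. These are documented generator
  defaults, not estimates.
- **Oviposition/hatching**: clutch sizes are rounded log-normal with
  mean 1363 eggs (log-SD 0.25, consistent with the printed 713–3039
  range); the investment model splits each clutch between salt and
  freshwater, the choice model opens or closes individual cups, and the
  two hatch models generate hatch counts. Eggs destined for a class
  whose cups are all closed spill into the other class, so at high
  salinity the realised freshwater share slightly exceeds the pure
  investment-model value — fits to generated data recover the combined
  process, not the investment coefficients alone.
- **Tadpole series**: day-by-day binomial thinning along the ramp with a
  clutch intercept (SD 0.17, the published parental-effect estimate)
  shared across a clutch's five groups. Default coefficients are
  anchored at the endpoints (six-day survival ≈ 0.98 in the control,
  ≈ 0.23 coastal / 0.08 inland at 12 ppt); a logit-linear daily model
  cannot also reproduce the threshold-like flatness observed at 6–8 ppt,
  so intermediate salinities sit below the published values by design.

One global seed fans out to per-component seeds via
`numpy.random.SeedSequence`, so layers regenerate independently and
deterministically.

What passing tests on these generators establishes: the estimators
recover the parameters of correctly specified data at realistic sizes,
the pipeline's plumbing (unit conversion, validation, prior propagation,
convergence gating, provenance) behaves as documented, and the derived
quantities (LC50s, survival grids, six-day survivals) follow from the
posteriors. What they do not establish: robustness to digitization
error, to non-logistic (threshold-shaped) dose–response, to reporting
heterogeneity across studies, or to the unmodelled features of the real
trials — the original common-garden data were never deposited, so the
published trial probabilities cannot be recomputed from data, only
emulated in structure.

## Numerical choices

- Logistic means are clipped to `[1e-9, 1 - 1e-9]` inside likelihoods.
- Informed-prior SDs are floored at 0.01.
- Credible intervals are clamped to bracket the posterior mean
  (`lo <= mean <= hi`), guarding against one-ulp percentile artifacts on
  degenerate draws.
- LC50 draws at `beta1 >= 0` are excluded and counted; estimates are
  refused when they exceed half the draws.
- Survival-table rows sort ascending in salinity regardless of input
  order; a missing stage yields a warning and an omitted column.
- Test-suite fits use 1.5k–4k iterations and the acceptance script uses
  the full protocol settings; both sizes are stated choices of this
  package and run the same code path.

## Known limitations

- Predictions condition on the typical study/bin/clutch (random effect
  0) rather than marginalising over the random-effect distribution.
- No phylogenetic correction and no meta-regression on exposure time,
  family or climate; duration is stored but unused.
- The conductivity conversion is a freshwater-range approximation.
- With a single study the study intercept is confounded with `beta0`;
  the fit warns and should be interpreted as that study's curve.
- Moment-matched informed priors transfer location *and* certainty;
  across response scales (cumulative vs. daily survival) they are
  best treated as a sensitivity analysis, not a default.
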