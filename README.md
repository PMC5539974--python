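# brackish

Bayesian inference of salinity tolerance across anuran life stages.

Freshwater wetlands along low-lying coasts are salinizing as sea level
rises, and amphibians — permeable-skinned osmoconformers with aquatic
eggs and larvae — are among the taxa most exposed. Because anurans have
a complex life cycle, the same salt stress hits eggs, tadpoles and
adults differently, and any assessment of persistence in brackish
habitat has to resolve tolerance *per life stage*. `brackish` implements
the statistical chain for that assessment:

1. **Dose–response meta-analysis.** Published survival-vs-salinity
   experiments (one extracted proportion per study × salinity level) are
   pooled per life stage with a Bayesian beta regression:

   ```
   y_ij ~ Beta(mu_ij * phi, (1 - mu_ij) * phi)
   logit(mu_ij) = beta0 + beta1 * s_ij + u_j,   u_j ~ Normal(0, sigma_u^2)
   ```

   with diffuse Normal(0, 1000) priors on `beta0`, `beta1`,
   `sigma_u ~ Uniform(0, 10)` and `phi ~ Gamma(0.01, 0.01)`. Study
   random intercepts `u_j` absorb between-study heterogeneity.

2. **LC50 and survival curves.** Per posterior draw, the salinity at
   which survival crosses 50% is `LC50 = -beta0 / beta1` (at the typical
   study, `u = 0`); survival curves `p(s) = logit^-1(beta0 + beta1 s)`
   carry central 95% credible envelopes.

3. **Common-garden models.** Oviposition site choice and egg hatching
   from binary-choice trials (3 freshwater + 3 salt cups per bin at
   4/6/8/12 ppt, coastal vs. inland source populations) are analysed as
   two-stage hurdle models — Bernoulli "any event" plus binomial
   "conditional proportion" — with salinity × location fixed effects and
   bin-within-location random intercepts. Tadpole survival over a
   six-day acclimation ramp is a chain of daily binomial survivals,
   `alive_t ~ Binomial(alive_{t-1}, p_t)`, with a logit-linear daily
   survival probability and clutch random intercepts. Priors for the
   downstream intercept and salinity slope can be propagated from the
   meta-analysis posterior as moment-matched Gaussians.

4. **Synthetic data with known truth.** Because the original trial data
   were never deposited, `brackish.simulate` generates all three data
   layers from documented ground-truth parameters anchored to the
   published scales, so every fitting stage is testable end to end.

Inference uses a built-in componentwise adaptive Metropolis sampler with
blocked random-intercept updates, an adaptive joint proposal, and
likelihood-invariant ridge moves; convergence is gated on the
Gelman–Rubin statistic (max R̂ < 1.1 across all parameters).

## Worked example

`examples/01_meta_analysis_lc50.py` simulates a literature table, fits
each life stage and prints:

```
simulated 384 study x salinity records

egg      LC50 =  3.74 ppt (95% BCI 3.20-4.26), truth 4.15, max R-hat 1.012
tadpole  LC50 =  5.47 ppt (95% BCI 4.88-5.98), truth 5.44, max R-hat 1.006
adult    LC50 = 10.94 ppt (95% BCI 0.00-38.82), truth 9.04, max R-hat 1.008

Predicted survivorship (mean, 95% BCI) at field salinities:
                       egg           tadpole             adult
salinity
3.9       0.49 (0.45-0.52)  0.60 (0.56-0.63)  0.64 (0.09-0.96)
8.3       0.22 (0.20-0.25)  0.33 (0.29-0.36)  0.56 (0.06-0.94)
11.0      0.12 (0.10-0.14)  0.20 (0.17-0.22)  0.50 (0.05-0.93)
16.8      0.03 (0.02-0.04)  0.05 (0.04-0.07)  0.39 (0.03-0.88)
23.4      0.00 (0.00-0.01)  0.01 (0.01-0.01)  0.27 (0.02-0.80)
```

Eggs are the most salt-sensitive stage and adults the least; the adult
interval is wide because that stage has only three studies, and its
lower LC50 bound is truncated at 0 ppt. The other examples cover the
oviposition hurdle models (`02`), the tadpole ramp (`03`) and the full
pipeline with CSV outputs and a provenance log (`04`). A thin CLI wraps
the same functions (`brackish --help`: `simulate`, `meta-fit`, `lc50`,
`predict`, `garden-fit`, `tadpole-fit`, `report`).

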