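"""Two-stage (hurdle) analysis of oviposition site choice.

Simulates the binary-choice experiment — bins with three freshwater and
three salt cups (4/6/8/12 ppt), coastal vs. inland pairs — then fits
(1) a Bernoulli model for whether any eggs are laid in a cup and
(2) a binomial model for the share of the clutch laid in freshwater,
both with salinity x location fixed effects and bin random intercepts.
"""

from brackish import McmcConfig, fit_bernoulli_stage, fit_binomial_stage, predict_response
from brackish.pipeline import garden_units_from_trials
from brackish.simulate import default_garden_truth, simulate_oviposition

truth = default_garden_truth()
trials, _ = simulate_oviposition(truth, n_replicates=4, seed=2)
choice_units, invest_units = garden_units_from_trials(trials)
print(f"{len(trials)} bins -> {len(choice_units)} cup-level choice units, "
      f"{len(invest_units)} bin-level investment units\n")

cfg = McmcConfig(n_chains=3, n_iter=3000, n_burn=1500, seed=7)
choice = fit_bernoulli_stage(choice_units, cfg=cfg)
invest = fit_binomial_stage(invest_units, cfg=cfg)

print("P(any eggs laid in a salt cup):")
for s in (4.0, 12.0):
    for loc in ("inland", "coastal"):
        m, lo, hi = predict_response(choice, s, loc)
        print(f"  {loc:8s} {s:4.0f} ppt: {m:.2f} ({lo:.2f}-{hi:.2f})")

print("\nProportion of the clutch laid in freshwater:")
for s in (4.0, 12.0):
    for loc in ("inland", "coastal"):
        m, lo, hi = predict_response(invest, s, loc)
        print(f"  {loc:8s} {s:4.0f} ppt: {m:.2f} ({lo:.2f}-{hi:.2f})")

print(
    "\nSalt-naive inland pairs abandon salt cups as salinity rises while\n"
    "chronically exposed coastal pairs keep using them — the interaction\n"
    "gamma_sL posterior mean is "
    f"{choice.draws.stacked('gamma_sL').mean():+.3f} "
    f"(truth {truth.choice.interaction:+.3f})."
)
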