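"""Daily tadpole survival over the six-day salinity acclimation ramp.

Groups of 50 tadpoles are ramped to a target salinity (0.5 control, or
4/6/8/12 ppt raised by 0.67/1/1.33/2 ppt per day); survival is modelled
day by day as alive_t ~ Binomial(alive_{t-1}, p_t) with a logit-linear
daily survival probability and clutch random intercepts.  Six-day
survival is the product of the daily probabilities along the ramp.
"""

from brackish import McmcConfig, fit_tadpole_survival, predict_response
from brackish.io import RAMP_TARGETS, ramp_schedule
from brackish.simulate import (
    default_garden_truth,
    expected_six_day_survival,
    simulate_tadpoles,
)

truth = default_garden_truth()
series = simulate_tadpoles(truth, n_clutches=8, seed=3)
print(f"simulated {len(series)} ramped series "
      f"({len(series) // 10} clutches per location x 5 targets)")
print("12 ppt ramp:", [s for _, s in ramp_schedule(12.0)], "\n")

fit = fit_tadpole_survival(series, cfg=McmcConfig(4, 5000, 2500, seed=9))
print(f"max R-hat {fit.max_rhat:.3f}; clutch random-effect sd "
      f"{fit.draws.stacked('sigma_clutch').mean():.2f}\n")

print("Six-day survival (posterior mean, 95% BCI | generator truth):")
for target in RAMP_TARGETS:
    row = []
    for loc in ("inland", "coastal"):
        m, lo, hi = predict_response(fit, target, loc)
        exp = expected_six_day_survival(truth.tadpole, target, loc)
        row.append(f"{loc} {m:.2f} ({lo:.2f}-{hi:.2f}) | {exp:.2f}")
    print(f"  {target:4.1f} ppt: " + "   ".join(row))

print(
    "\nCoastal tadpoles retain a survival advantage at high salinity —\n"
    "the population divergence the common-garden design is built to detect."
)
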