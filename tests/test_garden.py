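"""Common-garden hurdle models, informed priors and tadpole survival."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from brackish.garden import (
    GaussianPrior,
    HurdleFit,
    TadpoleFit,
    build_informed_prior,
    fit_bernoulli_stage,
    fit_binomial_stage,
    fit_tadpole_survival,
    informed_priors_from_meta,
    predict_response,
)
from brackish.mcmc import McmcConfig, PosteriorDraws
from brackish.simulate import GardenTruth, TadpoleCoef, simulate_tadpoles


class TestInformedPrior:
    def test_hand_computed_moments(self):
        p = build_informed_prior([1.0, 2.0, 3.0])
        assert (p.mean, p.sd) == (2.0, 1.0)

    def test_degenerate_draws_hit_sd_floor(self):
        p = build_informed_prior([0.5, 0.5, 0.5])
        assert (p.mean, p.sd) == (0.5, 0.01)

    def test_monte_carlo_moments(self):
        draws = np.random.default_rng(3).normal(size=10_000)
        p = build_informed_prior(draws)
        assert abs(p.mean) < 0.05 and abs(p.sd - 1.0) < 0.05

    def test_inflation_scales_sd(self):
        p = build_informed_prior([0.0, 2.0], inflation=3.0)
        assert p.sd == pytest.approx(3.0 * np.sqrt(2.0))

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="2 finite"):
            build_informed_prior([1.0])

    def test_mapping_from_meta_draws(self):
        draws = PosteriorDraws.from_arrays(
            {"beta0": np.full((2, 10), 1.5), "beta1": np.full((2, 10), -0.3)}
        )
        priors = informed_priors_from_meta(draws)
        assert priors["intercept"].mean == pytest.approx(1.5)
        assert priors["salinity"].mean == pytest.approx(-0.3)


def _degenerate_hurdle(**coef):
    values = {"gamma0": 0.0, "gamma_s": 0.0, "gamma_L": 0.0, "gamma_sL": 0.0,
              "sigma_b": 0.1}
    values.update(coef)
    draws = PosteriorDraws.degenerate(values, n_chains=2, n_draws=50)
    return HurdleFit("choice", draws, ["b1"], {k: 1.0 for k in values}, True)


class TestPredictResponse:
    def test_null_model_gives_half(self):
        fit = _degenerate_hurdle()
        for s in (0.0, 4.0, 12.0):
            mean, lo, hi = predict_response(fit, s, "inland")
            assert mean == pytest.approx(0.5)
            assert lo == pytest.approx(hi)

    def test_logit_zero_crossing(self):
        fit = _degenerate_hurdle(gamma0=2.0, gamma_s=-0.4)
        mean, _, _ = predict_response(fit, 5.0, "inland")
        assert mean == pytest.approx(0.5)

    def test_coastal_curve_monotone_when_total_slope_negative(self):
        rng = np.random.default_rng(4)
        n = 200
        draws = PosteriorDraws.from_arrays(
            {
                "gamma0": rng.normal(2.0, 0.2, (2, n)),
                "gamma_s": -rng.uniform(0.2, 0.5, (2, n)),
                "gamma_L": rng.normal(0.5, 0.2, (2, n)),
                "gamma_sL": rng.uniform(0.0, 0.1, (2, n)),
                "sigma_b": np.full((2, n), 0.2),
            }
        )
        fit = HurdleFit("choice", draws, ["b"], {k: 1.0 for k in draws.names}, True)
        means = [predict_response(fit, s, "coastal")[0] for s in np.linspace(0, 12, 7)]
        assert np.all(np.diff(means) < 0)

    def test_negative_salinity_rejected(self):
        with pytest.raises(ValueError):
            predict_response(_degenerate_hurdle(), -1.0, "inland")

    def test_probabilities_and_intervals_nested(self):
        fit = _degenerate_hurdle(gamma0=1.0, gamma_s=-0.2)
        mean, lo, hi = predict_response(fit, 3.0, "coastal")
        assert 0.0 <= lo <= mean <= hi <= 1.0


def _bernoulli_units(rng, truth, n_bins_per_loc, treatments=(4.0, 6.0, 8.0, 12.0)):
    rows = []
    for loc in ("inland", "coastal"):
        coastal = 1.0 if loc == "coastal" else 0.0
        for b in range(n_bins_per_loc):
            treat = treatments[b % len(treatments)]
            u = rng.normal(0.0, truth.re_sd)
            for ppt in (0.0, 0.0, 0.0, treat, treat, treat):
                p = float(expit(truth.eta(ppt, coastal) + u))
                rows.append(
                    {
                        "outcome": int(rng.uniform() < p),
                        "salinity": ppt,
                        "location": loc,
                        "group": f"{loc}-{b}",
                    }
                )
    return pd.DataFrame(rows)


class TestBernoulliStage:
    def test_saturated_outcomes_warn_and_predict_high(self, fast_cfg):
        units = pd.DataFrame(
            {
                "outcome": [1] * 16,
                "salinity": [0.0, 4.0] * 8,
                "location": ["inland"] * 8 + ["coastal"] * 8,
                "group": [f"b{i // 2}" for i in range(16)],
            }
        )
        with pytest.warns(UserWarning, match="constant within location"):
            fit = fit_bernoulli_stage(units, cfg=fast_cfg)
        assert fit.boundary_warning
        for s in (0.0, 4.0):
            assert predict_response(fit, s, "inland")[0] >= 0.95

    def test_matches_glm_without_heterogeneity(self, medium_cfg):
        sm = pytest.importorskip("statsmodels.api")
        from brackish.simulate import LogitCoef

        truth = LogitCoef(2.0, -0.25, -1.0, 0.2, re_sd=0.0)
        units = _bernoulli_units(np.random.default_rng(8), truth, 60)
        fit = fit_bernoulli_stage(units, cfg=medium_cfg)
        X = np.column_stack(
            [
                np.ones(len(units)),
                units["salinity"],
                (units["location"] == "coastal").astype(float),
                units["salinity"] * (units["location"] == "coastal"),
            ]
        )
        glm = sm.GLM(units["outcome"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        # Compare on the probability scale at the design's salinities.
        for s in (0.0, 4.0, 8.0, 12.0):
            for coastal in (0.0, 1.0):
                ours = predict_response(fit, s, "coastal" if coastal else "inland")[0]
                theirs = float(
                    expit(glm.params @ np.array([1.0, s, coastal, s * coastal]))
                )
                assert ours == pytest.approx(theirs, abs=0.05)

    def test_both_locations_required(self, fast_cfg):
        units = pd.DataFrame(
            {"outcome": [1, 0], "salinity": [0, 4], "location": ["inland"] * 2,
             "group": ["a", "a"]}
        )
        with pytest.raises(ValueError, match="both locations"):
            fit_bernoulli_stage(units, cfg=fast_cfg)


class TestBinomialStage:
    def test_successes_over_trials_fails_naming_unit(self, fast_cfg):
        units = pd.DataFrame(
            {
                "successes": [5, 30],
                "trials": [10, 20],
                "salinity": [4.0, 8.0],
                "location": ["inland", "coastal"],
                "group": ["a", "b"],
            }
        )
        with pytest.raises(ValueError, match="group='b'"):
            fit_binomial_stage(units, cfg=fast_cfg)

    def test_informed_prior_shrinks_posterior(self, fast_cfg):
        rng = np.random.default_rng(9)
        rows = []
        for loc in ("inland", "coastal"):
            for b, s in enumerate((4.0, 8.0)):
                n = 40
                k = int(rng.binomial(n, float(expit(2.0 - 0.3 * s))))
                rows.append(
                    {"successes": k, "trials": n, "salinity": s,
                     "location": loc, "group": f"{loc}{b}"}
                )
        units = pd.DataFrame(rows)
        flat = fit_binomial_stage(units, cfg=fast_cfg)
        informed = fit_binomial_stage(
            units,
            priors={"intercept": GaussianPrior(2.0, 0.2),
                    "salinity": GaussianPrior(-0.3, 0.05)},
            cfg=fast_cfg,
        )
        assert (
            informed.draws.stacked("gamma_s").std()
            < flat.draws.stacked("gamma_s").std()
        )

    def test_saturated_binomial_warns(self, fast_cfg):
        units = pd.DataFrame(
            {
                "successes": [20, 20, 20, 20],
                "trials": [20, 20, 20, 20],
                "salinity": [0.0, 4.0, 0.0, 4.0],
                "location": ["inland", "inland", "coastal", "coastal"],
                "group": ["a", "a", "b", "b"],
            }
        )
        with pytest.warns(UserWarning, match="saturated"):
            fit = fit_binomial_stage(units, cfg=fast_cfg)
        assert predict_response(fit, 0.0, "inland")[0] >= 0.95


class TestTadpoleSurvival:
    def test_no_deaths_boundary(self, fast_cfg):
        truth = GardenTruth(tadpole=TadpoleCoef(40.0, 0.0, 0.0, 0.0,
                                                re_sd=0.0, day=0.0))
        series = simulate_tadpoles(truth, 2, seed=1)
        with pytest.warns(UserWarning, match="no deaths"):
            fit = fit_tadpole_survival(series, cfg=fast_cfg)
        assert fit.boundary_warning
        mean, _, _ = predict_response(fit, 0.5, "inland")
        assert mean > 0.74  # daily survival mass above 0.95 -> 0.95^6

    def test_all_dead_day_one_remains_defined(self, fast_cfg):
        truth = GardenTruth(tadpole=TadpoleCoef(-40.0, 0.0, 0.0, 0.0,
                                                re_sd=0.0, day=0.0))
        series = simulate_tadpoles(truth, 2, seed=2)
        assert all(s.counts == [0] * 6 for s in series)
        fit = fit_tadpole_survival(series, cfg=fast_cfg)
        assert predict_response(fit, 0.5, "inland")[0] < 0.1

    def test_degenerate_draws_closed_form_product(self):
        p_daily = 0.99
        values = {"delta0": float(logit(p_daily)), "delta_s": 0.0, "delta_L": 0.0,
                  "delta_sL": 0.0, "delta_d": 0.0, "sigma_clutch": 0.1}
        draws = PosteriorDraws.degenerate(values, n_chains=2, n_draws=20)
        fit = TadpoleFit(draws, ["c1"], {k: 1.0 for k in values}, True)
        mean, lo, hi = predict_response(fit, 12.0, "inland")
        assert mean == pytest.approx(p_daily**6, abs=1e-12)
        assert lo == pytest.approx(hi)

    def test_off_ramp_target_rejected(self):
        values = {"delta0": 3.0, "delta_s": 0.0, "delta_L": 0.0,
                  "delta_sL": 0.0, "delta_d": 0.0, "sigma_clutch": 0.1}
        fit = TadpoleFit(
            PosteriorDraws.degenerate(values), ["c"], {k: 1.0 for k in values}, True
        )
        with pytest.raises(ValueError, match="ramp"):
            predict_response(fit, 5.0, "inland")
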