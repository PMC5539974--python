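"""Beta-regression meta-analysis: likelihood, fitting, LC50 and curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import beta as beta_dist

from brackish.io import LifeStage
from brackish.mcmc import McmcConfig, PosteriorDraws
from brackish.metaanalysis import (
    beta_loglik,
    compress_proportions,
    fit_beta_meta,
    lc50,
    predict_survival,
    survival_table,
)
from brackish.simulate import StageTruth, simulate_meta_dataset


class TestCompressProportions:
    @pytest.mark.parametrize(
        "y,n,expected",
        [(1.0, 50, 0.99), (0.0, 50, 0.01), (0.5, 7, 0.5), (0.5, 1000, 0.5)],
    )
    def test_formula(self, y, n, expected):
        assert compress_proportions(y, n) == pytest.approx(expected)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            compress_proportions(0.5, 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        ys=st.lists(st.floats(0, 1), min_size=2, max_size=10),
        n=st.integers(2, 500),
    )
    def test_order_preserving(self, ys, n):
        y = np.array(ys)
        out = compress_proportions(y, n)
        # no pair of observations ever swaps rank order
        dy = y[:, None] - y[None, :]
        dout = out[:, None] - out[None, :]
        assert np.all(dy * dout >= 0)
        assert np.all((out > 0) & (out < 1))


class TestBetaLoglik:
    def test_uniform_case(self):
        # Beta(1, 1) is the uniform density.
        assert beta_loglik(0.5, 0.5, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_beta22_closed_form(self):
        # Beta(2, 2) density 6 y (1-y) at 0.25 -> 1.125.
        assert beta_loglik(0.25, 0.5, 4.0) == pytest.approx(math.log(1.125))

    def test_matches_scipy_parameterization(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y, mu = rng.uniform(0.05, 0.95, 2)
            phi = rng.uniform(0.5, 80)
            assert beta_loglik(y, mu, phi) == pytest.approx(
                beta_dist.logpdf(y, mu * phi, (1 - mu) * phi), rel=1e-10
            )

    @pytest.mark.parametrize("mu,phi", [(0.3, 2.5), (0.5, 10.0), (0.85, 40.0)])
    def test_normalizes_to_one(self, mu, phi):
        integral, _ = quad(lambda y: math.exp(beta_loglik(y, mu, phi)), 0, 1)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError, match="compress"):
            beta_loglik(1.0, 0.5, 2.0)


def _point_posterior(b0, b1, n=400):
    return PosteriorDraws.from_arrays(
        {"beta0": np.full((2, n), b0), "beta1": np.full((2, n), b1)}
    )


class TestLc50:
    def test_degenerate_closed_form(self):
        est = lc50(_point_posterior(2.0, -0.4))
        assert (est.point, est.bci_low, est.bci_high) == (5.0, 5.0, 5.0)

    def test_zero_intercept(self):
        assert lc50(_point_posterior(0.0, -1.0)).point == 0.0

    def test_two_point_posterior_enumeration(self):
        b1 = np.array([[-0.9] * 500 + [-0.3] * 500] * 2)
        draws = PosteriorDraws.from_arrays(
            {"beta0": np.full_like(b1, 1.8), "beta1": b1}
        )
        est = lc50(draws)
        assert est.bci_low == pytest.approx(2.0)
        assert est.bci_high == pytest.approx(6.0)

    def test_negative_values_truncated(self):
        est = lc50(_point_posterior(-1.0, -0.5))
        assert est.point == 0.0 and est.truncated_at_zero

    def test_refused_when_survival_not_decreasing(self):
        b1 = np.array([[0.1] * 300 + [-0.2] * 100] * 2)
        draws = PosteriorDraws.from_arrays(
            {"beta0": np.full_like(b1, 1.0), "beta1": b1}
        )
        with pytest.raises(ValueError, match="non-decreasing"):
            lc50(draws)

    def test_matches_bisection_oracle_per_draw(self):
        rng = np.random.default_rng(1)
        b0 = rng.uniform(0.5, 3.0, 50)
        b1 = rng.uniform(-0.8, -0.05, 50)
        for i in range(50):
            root = brentq(
                lambda s: expit(b0[i] + b1[i] * s) - 0.5, 0, 1e4, xtol=1e-12
            )
            assert -b0[i] / b1[i] == pytest.approx(root, abs=1e-8)


class TestPredictSurvival:
    def test_closed_form_single_draw(self):
        post = _point_posterior(2.0, -0.4)
        curve = predict_survival(post, [0.0, 5.0])
        assert curve["mean"].iloc[1] == pytest.approx(0.5)
        assert curve["mean"].iloc[0] == pytest.approx(float(expit(2.0)))

    def test_empty_salinities(self):
        assert predict_survival(_point_posterior(2, -0.4), []).empty

    def test_negative_salinity_rejected(self):
        with pytest.raises(ValueError):
            predict_survival(_point_posterior(2, -0.4), [-1.0])

    def test_mean_monotone_when_slope_negative(self):
        rng = np.random.default_rng(2)
        draws = PosteriorDraws.from_arrays(
            {
                "beta0": rng.normal(1.5, 0.3, size=(2, 500)),
                "beta1": -rng.uniform(0.05, 0.5, size=(2, 500)),
            }
        )
        curve = predict_survival(draws, np.linspace(0, 30, 16))
        assert np.all(np.diff(curve["mean"]) < 0)
        assert np.all(curve["bci_low"] <= curve["mean"] + 1e-12)
        assert np.all(curve["mean"] <= curve["bci_high"] + 1e-12)


class TestFitBetaMeta:
    def test_single_seed_parameter_recovery(self, medium_cfg):
        truth = StageTruth(2.0, -0.45, 0.3, 20.0, n_studies=30,
                           salinities=(0.0, 1.0, 2.0, 4.0, 6.0, 8.0))
        recs = simulate_meta_dataset(truth, seed=12, stage="egg")
        fit = fit_beta_meta(recs, "egg", medium_cfg)
        assert fit.converged
        b0 = fit.draws.stacked("beta0")
        b1 = fit.draws.stacked("beta1")
        assert abs(b0.mean() - 2.0) / 2.0 < 0.2
        assert abs(b1.mean() - (-0.45)) / 0.45 < 0.2
        lo0, hi0 = np.percentile(b0, [2.5, 97.5])
        lo1, hi1 = np.percentile(b1, [2.5, 97.5])
        assert lo0 < 2.0 < hi0 and lo1 < -0.45 < hi1

    def test_grid_search_mle_oracle_single_study(self):
        # One study, no random effects, phi fixed: the posterior mean under
        # the diffuse prior must approach the brute-force grid MLE.
        phi = 50.0
        truth = StageTruth(1.6, -0.3, 0.0, phi, n_studies=1,
                           salinities=tuple(float(s) for s in range(12)))
        recs = simulate_meta_dataset(truth, seed=21, stage="egg")
        y = np.array([r.survival_prop for r in recs])
        s = np.array([r.salinity_ppt for r in recs])
        b0g = np.linspace(0.5, 2.5, 161)
        b1g = np.linspace(-0.6, -0.05, 161)
        B0, B1 = np.meshgrid(b0g, b1g, indexing="ij")
        ll = np.zeros_like(B0)
        for yi, si in zip(y, s):
            mu = expit(B0 + B1 * si)
            ll += beta_dist.logpdf(yi, mu * phi, (1 - mu) * phi)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        mle = (b0g[i], b1g[j])
        with pytest.warns(UserWarning, match="one study"):
            fit = fit_beta_meta(
                recs, "egg", McmcConfig(3, 6000, 2000, seed=5),
                include_study_effects=True, fix_phi=phi,
            )
        # refit without the confounded random effect for the oracle check
        fit = fit_beta_meta(
            recs, "egg", McmcConfig(3, 6000, 2000, seed=5),
            include_study_effects=False, fix_phi=phi,
        )
        assert fit.draws.stacked("beta0").mean() == pytest.approx(mle[0], abs=0.05)
        assert fit.draws.stacked("beta1").mean() == pytest.approx(mle[1], abs=0.05)

    def test_requires_stage_records(self, fast_cfg):
        truth = StageTruth(1.0, -0.2, 0.0, 20.0, 2, (0.0, 4.0))
        recs = simulate_meta_dataset(truth, seed=1, stage="egg")
        with pytest.raises(ValueError, match="adult"):
            fit_beta_meta(recs, "adult", fast_cfg)

    def test_posterior_contains_all_parameters(self, fast_cfg):
        truth = StageTruth(1.0, -0.2, 0.2, 20.0, 4, (0.0, 4.0, 8.0))
        recs = simulate_meta_dataset(truth, seed=2, stage="tadpole")
        fit = fit_beta_meta(recs, "tadpole", fast_cfg)
        names = set(fit.draws.names)
        assert {"beta0", "beta1", "sigma_u", "phi"} <= names
        assert sum(n.startswith("u[") for n in names) == 4


class TestSurvivalTable:
    def _posteriors(self):
        return {
            LifeStage.EGG: _point_posterior(1.12, -0.27),
            LifeStage.TADPOLE: _point_posterior(1.43, -0.263),
            LifeStage.ADULT: _point_posterior(0.75, -0.083),
        }

    def test_degenerate_cells_closed_form(self):
        table = survival_table(self._posteriors(), [3.9, 8.3])
        assert table.loc[3.9, ("egg", "mean")] == pytest.approx(
            float(expit(1.12 - 0.27 * 3.9))
        )
        assert table.loc[8.3, ("adult", "mean")] == pytest.approx(
            float(expit(0.75 - 0.083 * 8.3))
        )

    def test_rows_sorted_ascending(self):
        table = survival_table(self._posteriors(), [23.4, 3.9, 11.0])
        assert list(table.index) == [3.9, 11.0, 23.4]

    def test_missing_stage_column_omitted_with_warning(self):
        posts = self._posteriors()
        del posts[LifeStage.ADULT]
        with pytest.warns(UserWarning, match="adult"):
            table = survival_table(posts, [3.9])
        assert "adult" not in table.columns.get_level_values("stage")

    def test_formatted_cells(self):
        table = survival_table(self._posteriors(), [3.9], formatted=True)
        assert table.loc[3.9, "egg"] == "0.52 (0.52-0.52)"
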