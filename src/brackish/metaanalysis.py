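"""Beta-regression meta-analysis of survival vs. salinity, per life stage.

The model for observation i in study j is

    y_ij ~ Beta(mu_ij * phi, (1 - mu_ij) * phi)
    logit(mu_ij) = beta0 + beta1 * salinity_ij + u_j
    u_j ~ Normal(0, sigma_u^2)

with diffuse Gaussian priors (mean 0, variance 1000) on beta0 and beta1,
sigma_u ~ Uniform(0, 10) and phi ~ Gamma(0.01, 0.01).  The beta
distribution is used because extracted survivorship is a proportion,
often without the sample sizes needed to back-calculate counts; boundary
values (0 and 1) are pulled into the open interval with the standard
compression (y (n-1) + 0.5) / n before fitting.

Downstream quantities are computed per posterior draw at the typical
study (u = 0): the LC50 is the salinity where the survival curve crosses
0.5, i.e. -beta0 / beta1, and survival curves carry central 95% credible
envelopes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from brackish.io import LifeStage, SurvivalRecord
from brackish.mcmc import (
    DIFFUSE_PRIOR_VARIANCE,
    McmcConfig,
    ParamSpec,
    PosteriorDraws,
    gamma_prior,
    normal_prior,
    sample_posterior,
    uniform_prior,
)

logger = logging.getLogger(__name__)

__all__ = [
    "compress_proportions",
    "beta_loglik",
    "BetaMetaModel",
    "BetaMetaFit",
    "fit_beta_meta",
    "Lc50Estimate",
    "lc50",
    "predict_survival",
    "survival_table",
    "TABLE_SALINITIES",
    "RHAT_THRESHOLD",
    "DEFAULT_N_IMPUTE",
]

RHAT_THRESHOLD = 1.1
# Sample size assumed when a digitized study reports none; used only to
# compress boundary proportions into the open interval.
DEFAULT_N_IMPUTE = 10

TABLE_SALINITIES = (3.9, 8.3, 11.0, 16.8, 23.4)


def compress_proportions(survival_prop, n):
    """Pull a proportion off the [0, 1] boundary: (y (n-1) + 0.5) / n.

    The beta likelihood has open-interval support while extracted data
    include exact 0s and 1s.  The transform is strictly order-preserving
    and leaves 0.5 fixed for every n.
    """
    y = np.asarray(survival_prop, dtype=float)
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("n must be a positive integer")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("survival_prop must lie in [0, 1]")
    out = (y * (n - 1) + 0.5) / n
    return float(out) if out.ndim == 0 else out


def beta_loglik(y, mu, phi):
    """Log density of Beta(mu*phi, (1-mu)*phi) at y (mean-precision form).

    All of ``y`` and ``mu`` must be strictly inside (0, 1); boundary
    observations must be compressed first.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must be strictly inside (0, 1); compress boundaries first")
    if np.any((mu <= 0) | (mu >= 1)) or np.any(phi <= 0):
        raise ValueError("need mu in (0, 1) and phi > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (
        gammaln(phi)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Model + fitting
# ---------------------------------------------------------------------------

_MU_EPS = 1e-9


class BetaMetaModel:
    """Likelihood engine handed to the sampler.

    Parameter vector order: beta0, beta1, [sigma_u], [phi] (bracketed
    entries drop out when random effects are disabled or phi is fixed).
    """

    def __init__(
        self,
        y: np.ndarray,
        salinity: np.ndarray,
        study_labels: list[str],
        study_index: np.ndarray,
        include_study_effects: bool = True,
        fix_phi: float | None = None,
        priors: dict | None = None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.s = np.asarray(salinity, dtype=float)
        self.gidx = np.asarray(study_index, dtype=np.intp)
        self.group_labels = list(study_labels)
        self.n_groups = len(study_labels) if include_study_effects else 0
        self.re_sd_name = "sigma_u" if include_study_effects else None
        # Only the intercept is constant within studies (salinity varies),
        # so it is the single likelihood-invariant shift direction.
        self.group_covariates = (
            {"beta0": np.ones(self.n_groups)} if include_study_effects else {}
        )
        self.fix_phi = fix_phi
        priors = priors or {}

        def coef_prior(name):
            p = priors.get(name)
            if p is None:
                return normal_prior(0.0, DIFFUSE_PRIOR_VARIANCE**0.5)
            return normal_prior(p.mean, p.sd)

        specs = [
            ParamSpec("beta0", coef_prior("beta0"), init=1.0),
            ParamSpec("beta1", coef_prior("beta1"), init=-0.2),
        ]
        if include_study_effects:
            specs.append(
                ParamSpec(
                    "sigma_u", uniform_prior(0.0, 10.0), init=0.5,
                    transform=("interval", 0.0, 10.0),
                )
            )
        if fix_phi is None:
            specs.append(
                ParamSpec("phi", gamma_prior(0.01, 0.01), init=10.0, transform="log")
            )
        self.fixed_params = specs
        self._phi_pos = len(specs) - 1 if fix_phi is None else None
        # observations per study, for bincount-based group sums
        self._n_bins = max(len(study_labels), 1)

    def group_loglik(self, fixed: np.ndarray, u: np.ndarray) -> np.ndarray:
        beta0, beta1 = fixed[0], fixed[1]
        phi = self.fix_phi if self.fix_phi is not None else fixed[self._phi_pos]
        eta = beta0 + beta1 * self.s
        if self.n_groups:
            eta = eta + u[self.gidx]
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = (
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * np.log(self.y)
            + (b - 1.0) * np.log1p(-self.y)
        )
        if self.n_groups:
            return np.bincount(self.gidx, weights=ll, minlength=self._n_bins)
        return np.array([ll.sum()])


@dataclass
class BetaMetaFit:
    """Posterior of one life stage's meta-analysis."""

    life_stage: LifeStage
    draws: PosteriorDraws
    study_ids: list[str]
    rhat: dict[str, float]
    converged: bool
    n_records: int
    n_imputed: int  # records whose missing N was imputed for compression

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


def fit_beta_meta(
    records: list[SurvivalRecord],
    stage: LifeStage | str,
    cfg: McmcConfig | None = None,
    priors: dict | None = None,
    include_study_effects: bool = True,
    fix_phi: float | None = None,
) -> BetaMetaFit:
    """Fit the beta-regression meta-analysis for one life stage.

    Records of other stages are filtered out.  Raises if fewer than two
    records of the requested stage are available; warns when only one
    study is present (the study intercept is then confounded with beta0)
    and when the Gelman-Rubin gate (max R-hat < 1.1) fails.
    """
    stage = LifeStage(stage)
    cfg = cfg or McmcConfig()
    sub = [r for r in records if r.life_stage == stage]
    if len(sub) < 2:
        raise ValueError(
            f"need at least 2 records of stage {stage.value!r}, got {len(sub)}"
        )
    studies = list(dict.fromkeys(r.study_id for r in sub))
    if len(studies) == 1 and include_study_effects:
        warnings.warn(
            f"only one study for stage {stage.value!r}: the study intercept is "
            "confounded with beta0",
            UserWarning,
        )
    study_pos = {sid: k for k, sid in enumerate(studies)}
    n_imputed = sum(
        1 for r in sub if r.n_exposed is None and r.survival_prop in (0.0, 1.0)
    )
    if n_imputed:
        logger.info(
            "stage %s: %d boundary records lack N; using n=%d for compression",
            stage.value, n_imputed, DEFAULT_N_IMPUTE,
        )
    # Only exact 0s and 1s are compressed into the open interval; interior
    # proportions enter the likelihood untouched.
    y = np.array(
        [
            compress_proportions(
                r.survival_prop,
                r.n_exposed if r.n_exposed is not None else DEFAULT_N_IMPUTE,
            )
            if r.survival_prop in (0.0, 1.0)
            else r.survival_prop
            for r in sub
        ]
    )
    model = BetaMetaModel(
        y=np.atleast_1d(y),
        salinity=[r.salinity_ppt for r in sub],
        study_labels=studies,
        study_index=[study_pos[r.study_id] for r in sub],
        include_study_effects=include_study_effects,
        fix_phi=fix_phi,
        priors=priors,
    )
    draws = sample_posterior(model, cfg)
    rhat = {name: draws.rhat(name) for name in draws.names}
    converged = max(rhat.values()) < RHAT_THRESHOLD
    if not converged:
        warnings.warn(
            f"stage {stage.value!r} fit flagged non-converged: "
            f"max R-hat = {max(rhat.values()):.3f} >= {RHAT_THRESHOLD}",
            UserWarning,
        )
    return BetaMetaFit(
        life_stage=stage,
        draws=draws,
        study_ids=studies,
        rhat=rhat,
        converged=converged,
        n_records=len(sub),
        n_imputed=n_imputed,
    )


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lc50Estimate:
    """Posterior LC50: salinity imposing 50% mortality at the typical study."""

    life_stage: LifeStage | None
    point: float  # posterior median
    bci_low: float
    bci_high: float
    truncated_at_zero: bool  # any negative draws clipped to 0 ppt
    n_excluded: int  # draws with beta1 >= 0, dropped from the transform

    def __post_init__(self):
        if not self.bci_low <= self.point <= self.bci_high:
            raise ValueError("credible interval must bracket the point estimate")


def _coef_draws(posterior) -> PosteriorDraws:
    return posterior.draws if isinstance(posterior, BetaMetaFit) else posterior


def lc50(posterior, stage: LifeStage | None = None) -> Lc50Estimate:
    """Invert the posterior survival curve at 50%.

    Per draw, LC50 = -beta0 / beta1 (the salinity where the logistic mean
    crosses 0.5 at u = 0).  Draws with beta1 >= 0 carry no decreasing
    dose-response and are excluded; if they are the majority the estimate
    is refused.  Negative transformed values are truncated to 0 ppt.
    """
    draws = _coef_draws(posterior)
    if stage is None and isinstance(posterior, BetaMetaFit):
        stage = posterior.life_stage
    b0 = draws.stacked("beta0")
    b1 = draws.stacked("beta1")
    good = b1 < 0
    n_excluded = int((~good).sum())
    if n_excluded > 0.5 * b1.size:
        raise ValueError(
            "LC50 undefined: survival is non-decreasing in salinity for "
            f"{n_excluded}/{b1.size} draws"
        )
    vals = -b0[good] / b1[good]
    truncated = bool(np.any(vals < 0))
    vals = np.clip(vals, 0.0, None)
    lo, mid, hi = np.percentile(vals, [2.5, 50.0, 97.5])
    return Lc50Estimate(
        life_stage=stage,
        point=float(mid),
        bci_low=float(lo),
        bci_high=float(hi),
        truncated_at_zero=truncated,
        n_excluded=n_excluded,
    )


def predict_survival(posterior, salinities) -> pd.DataFrame:
    """Posterior survival curve at the typical study (u = 0).

    Returns a frame with columns ``salinity, mean, bci_low, bci_high``:
    per draw p(s) = logit^-1(beta0 + beta1 s), summarised by the mean and
    the central 95% interval over draws.
    """
    draws = _coef_draws(posterior)
    salinities = np.asarray(list(salinities), dtype=float)
    if salinities.size and np.any(salinities < 0):
        raise ValueError("salinities must be nonnegative")
    if salinities.size == 0:
        return pd.DataFrame(columns=["salinity", "mean", "bci_low", "bci_high"])
    b0 = draws.stacked("beta0")[:, None]
    b1 = draws.stacked("beta1")[:, None]
    p = expit(b0 + b1 * salinities[None, :])  # (n_draws, n_salinities)
    lo, hi = np.percentile(p, [2.5, 97.5], axis=0)
    mean = p.mean(axis=0)
    return pd.DataFrame(
        {
            "salinity": salinities,
            "mean": mean,
            "bci_low": np.minimum(lo, mean),
            "bci_high": np.maximum(hi, mean),
        }
    )


def survival_table(
    posteriors: dict,
    salinities=TABLE_SALINITIES,
    formatted: bool = False,
) -> pd.DataFrame:
    """Stage x salinity grid of predicted survivorship with 95% BCIs.

    ``posteriors`` maps life stage to a :class:`BetaMetaFit` or
    :class:`PosteriorDraws`.  Rows are sorted by salinity ascending; a
    missing stage's column is omitted with a warning.  With
    ``formatted=True`` cells become ``"mean (lo-hi)"`` strings.
    """
    salinities = sorted(float(s) for s in salinities)
    pieces = {}
    for stage in LifeStage:
        if stage not in posteriors and stage.value not in posteriors:
            warnings.warn(f"no posterior for stage {stage.value!r}; column omitted")
            continue
        post = posteriors.get(stage, posteriors.get(stage.value))
        pieces[stage.value] = predict_survival(post, salinities).set_index("salinity")
    cols = {}
    for stage_name, frame in pieces.items():
        cols[(stage_name, "mean")] = frame["mean"]
        cols[(stage_name, "bci_low")] = frame["bci_low"]
        cols[(stage_name, "bci_high")] = frame["bci_high"]
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["stage", "stat"])
    if formatted:
        out = {}
        for stage_name in pieces:
            out[stage_name] = [
                f"{m:.2f} ({lo:.2f}-{hi:.2f})"
                for m, lo, hi in zip(
                    table[(stage_name, "mean")],
                    table[(stage_name, "bci_low")],
                    table[(stage_name, "bci_high")],
                )
            ]
        return pd.DataFrame(out, index=table.index)
    return table
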