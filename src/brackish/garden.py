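"""Hierarchical models for the common-garden experiments.

Oviposition site choice and egg hatching are analysed as two-stage
(hurdle) tests: a Bernoulli model for whether any eggs were laid (or any
hatched) in a cup, and a binomial model for the conditional proportion,
each with salinity, source location (coastal vs. inland) and their
interaction as fixed effects and a bin-within-location random intercept.
Tadpole survival over the six-day acclimation ramp is a chain of daily
binomial survivals with clutch random intercepts.

Priors on the intercept and salinity slope can be propagated from the
life-stage meta-analysis posterior as moment-matched Gaussians
(:func:`build_informed_prior`); the location and interaction terms keep
diffuse priors, since the meta-analysis carries no population contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from brackish.io import RAMP_TARGETS, TadpoleSeries, ramp_schedule
from brackish.mcmc import (
    DIFFUSE_PRIOR_VARIANCE,
    McmcConfig,
    ParamSpec,
    PosteriorDraws,
    normal_prior,
    sample_posterior,
    uniform_prior,
)
from brackish.metaanalysis import RHAT_THRESHOLD, BetaMetaFit

__all__ = [
    "GaussianPrior",
    "build_informed_prior",
    "informed_priors_from_meta",
    "HurdleFit",
    "TadpoleFit",
    "fit_bernoulli_stage",
    "fit_binomial_stage",
    "fit_tadpole_survival",
    "predict_response",
]

PRIOR_SD_FLOOR = 0.01


@dataclass(frozen=True)
class GaussianPrior:
    """A Normal(mean, sd) prior for one coefficient."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < PRIOR_SD_FLOOR:
            object.__setattr__(self, "sd", PRIOR_SD_FLOOR)


def build_informed_prior(coef_draws, inflation: float = 1.0) -> GaussianPrior:
    """Moment-match a Gaussian prior to posterior draws of a coefficient.

    ``mean`` is the sample mean and ``sd`` the sample SD times the
    ``inflation`` factor (floored at 0.01).  Inflation > 1 discounts the
    upstream posterior's information.
    """
    draws = np.asarray(coef_draws, dtype=float)
    draws = draws[np.isfinite(draws)]
    if draws.size < 2:
        raise ValueError("need at least 2 finite draws to build a prior")
    if inflation <= 0:
        raise ValueError("inflation must be positive")
    return GaussianPrior(float(draws.mean()), float(inflation * draws.std(ddof=1)))


def informed_priors_from_meta(
    meta_fit: BetaMetaFit | PosteriorDraws, inflation: float = 1.0
) -> dict[str, GaussianPrior]:
    """Priors for a garden model's intercept and salinity slope from a
    meta-analysis posterior (beta0 -> intercept, beta1 -> slope)."""
    draws = meta_fit.draws if isinstance(meta_fit, BetaMetaFit) else meta_fit
    return {
        "intercept": build_informed_prior(draws.stacked("beta0"), inflation),
        "salinity": build_informed_prior(draws.stacked("beta1"), inflation),
    }


# ---------------------------------------------------------------------------
# Shared binomial mixed model
# ---------------------------------------------------------------------------

_P_EPS = 1e-9


class _BinomialMixedModel:
    """successes ~ Binomial(trials, logit^-1(X @ coef + u[group]))."""

    def __init__(self, coef_names, X, k, n, group_idx, group_labels, priors,
                 re_sd_name="sigma_b"):
        self.X = np.asarray(X, dtype=float)
        self.k = np.asarray(k, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.gidx = np.asarray(group_idx, dtype=np.intp)
        self.group_labels = list(group_labels)
        self.n_groups = len(self.group_labels)
        self.re_sd_name = re_sd_name
        # Covariates constant within groups (e.g. a bin's treatment and
        # location) are confounded with the random intercepts; expose them
        # as likelihood-invariant shift directions for the sampler.
        self.group_covariates = {}
        for j, name in enumerate(coef_names):
            col = self.X[:, j]
            lo = np.full(self.n_groups, np.inf)
            hi = np.full(self.n_groups, -np.inf)
            np.minimum.at(lo, self.gidx, col)
            np.maximum.at(hi, self.gidx, col)
            if np.all(hi - lo == 0):
                self.group_covariates[name] = lo
        priors = priors or {}
        diffuse_sd = DIFFUSE_PRIOR_VARIANCE**0.5
        specs = []
        for name in coef_names:
            p = priors.get(name)
            prior = normal_prior(p.mean, p.sd) if p else normal_prior(0.0, diffuse_sd)
            specs.append(ParamSpec(name, prior, init=(p.mean if p else 0.0)))
        specs.append(
            ParamSpec(re_sd_name, uniform_prior(0.0, 10.0), init=0.3,
                      transform=("interval", 0.0, 10.0))
        )
        self.fixed_params = specs
        self.n_coef = len(coef_names)

    def group_loglik(self, fixed: np.ndarray, u: np.ndarray) -> np.ndarray:
        eta = self.X @ fixed[: self.n_coef]
        if self.n_groups:
            eta = eta + u[self.gidx]
        p = np.clip(expit(eta), _P_EPS, 1.0 - _P_EPS)
        ll = self.k * np.log(p) + (self.n - self.k) * np.log1p(-p)
        return np.bincount(self.gidx, weights=ll, minlength=self.n_groups)


@dataclass
class HurdleFit:
    """Posterior of one hurdle stage (choice/investment/hatch models).

    Fixed effects: ``gamma0`` (intercept, inland at 0 ppt), ``gamma_s``
    (salinity slope), ``gamma_L`` (coastal offset), ``gamma_sL``
    (salinity x coastal interaction); ``sigma_b`` is the bin-within-
    location random-intercept SD.
    """

    stage_label: str  # choice | investment | hatch_any | hatch_prop | custom
    draws: PosteriorDraws
    group_labels: list[str]
    rhat: dict[str, float]
    converged: bool
    boundary_warning: bool = False

    coef_names = ("gamma0", "gamma_s", "gamma_L", "gamma_sL")

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


@dataclass
class TadpoleFit:
    """Posterior of the daily tadpole-survival model.

    Fixed effects ``delta0, delta_s, delta_L, delta_sL, delta_d`` act on
    the logit of the probability of surviving one day; ``sigma_clutch``
    is the clutch random-intercept SD.  Six-day survival at a target
    salinity is the product of the daily probabilities along the ramp.
    """

    draws: PosteriorDraws
    group_labels: list[str]
    rhat: dict[str, float]
    converged: bool
    boundary_warning: bool = False

    coef_names = ("delta0", "delta_s", "delta_L", "delta_sL", "delta_d")

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


def _as_frame(units, cols):
    if isinstance(units, pd.DataFrame):
        df = units.copy()
    else:
        df = pd.DataFrame(list(units), columns=cols)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"units missing column(s): {', '.join(missing)}")
    return df


def _check_locations(df):
    locs = set(df["location"])
    bad = locs - {"coastal", "inland"}
    if bad:
        raise ValueError(f"unknown location label(s): {sorted(bad)}")
    if locs != {"coastal", "inland"}:
        raise ValueError("both locations (coastal and inland) must be present")


def _design(df):
    coastal = (df["location"] == "coastal").to_numpy(dtype=float)
    s = df["salinity"].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), s, coastal, s * coastal])


def _prior_map(priors):
    """Map the generic {'intercept','salinity'} prior keys onto gamma names."""
    if not priors:
        return {}
    out = dict(priors)
    if "intercept" in out:
        out.setdefault("gamma0", out.pop("intercept"))
    if "salinity" in out:
        out.setdefault("gamma_s", out.pop("salinity"))
    return out


def _finalize(draws, label, group_labels, boundary, cls=HurdleFit):
    rhat = {name: draws.rhat(name) for name in draws.names}
    converged = max(rhat.values()) < RHAT_THRESHOLD
    if not converged:
        warnings.warn(
            f"{label} fit flagged non-converged: max R-hat = "
            f"{max(rhat.values()):.3f}",
            UserWarning,
        )
    if cls is HurdleFit:
        return HurdleFit(label, draws, group_labels, rhat, converged, boundary)
    return TadpoleFit(draws, group_labels, rhat, converged, boundary)


def fit_bernoulli_stage(
    units,
    priors: dict | None = None,
    cfg: McmcConfig | None = None,
    stage_label: str = "choice",
) -> HurdleFit:
    """Bernoulli hurdle stage: P(any event) vs. salinity x location.

    ``units`` is a frame (or list of tuples) with columns ``outcome``
    (0/1), ``salinity``, ``location`` (coastal/inland) and ``group``
    (bin id).  The linear predictor is
    gamma0 + gamma_s s + gamma_L [coastal] + gamma_sL s [coastal] + b_bin.
    """
    df = _as_frame(units, ["outcome", "salinity", "location", "group"])
    _check_locations(df)
    y = df["outcome"].to_numpy(dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary (0/1)")
    boundary = False
    for loc, grp in df.groupby("location"):
        if grp["outcome"].nunique() == 1:
            boundary = True
            warnings.warn(
                f"outcome is constant within location {loc!r}; estimates sit "
                "on the boundary",
                UserWarning,
            )
    labels = list(dict.fromkeys(df["group"]))
    pos = {g: i for i, g in enumerate(labels)}
    model = _BinomialMixedModel(
        HurdleFit.coef_names,
        _design(df),
        k=y,
        n=np.ones(len(df)),
        group_idx=[pos[g] for g in df["group"]],
        group_labels=labels,
        priors=_prior_map(priors),
    )
    draws = sample_posterior(model, cfg or McmcConfig())
    return _finalize(draws, stage_label, labels, boundary)


def fit_binomial_stage(
    units,
    priors: dict | None = None,
    cfg: McmcConfig | None = None,
    stage_label: str = "investment",
) -> HurdleFit:
    """Binomial hurdle stage: conditional proportion vs. salinity x location.

    ``units`` has columns ``successes, trials, salinity, location,
    group``; zero-trial units (cups with no eggs laid/hatched) must be
    excluded upstream.
    """
    df = _as_frame(units, ["successes", "trials", "salinity", "location", "group"])
    _check_locations(df)
    k = df["successes"].to_numpy(dtype=float)
    n = df["trials"].to_numpy(dtype=float)
    if np.any(n < 1):
        raise ValueError("trials must be >= 1; drop zero-trial units upstream")
    over = np.nonzero(k > n)[0]
    if over.size:
        unit = df.iloc[over[0]]
        raise ValueError(
            f"successes > trials for unit (group={unit['group']!r}, "
            f"salinity={unit['salinity']})"
        )
    boundary = bool(np.all(k == n) or np.all(k == 0))
    if boundary:
        warnings.warn(
            "all units saturated (successes equal trials or all zero); "
            "estimates sit on the boundary",
            UserWarning,
        )
    labels = list(dict.fromkeys(df["group"]))
    pos = {g: i for i, g in enumerate(labels)}
    model = _BinomialMixedModel(
        HurdleFit.coef_names,
        _design(df),
        k=k,
        n=n,
        group_idx=[pos[g] for g in df["group"]],
        group_labels=labels,
        priors=_prior_map(priors),
    )
    draws = sample_posterior(model, cfg or McmcConfig())
    return _finalize(draws, stage_label, labels, boundary)


TADPOLE_CFG = McmcConfig(n_chains=4, n_iter=50000, n_burn=25000)


def fit_tadpole_survival(
    series: list[TadpoleSeries],
    priors: dict | None = None,
    cfg: McmcConfig | None = None,
) -> TadpoleFit:
    """Daily-survival model for the ramped tadpole trials.

    The chain likelihood is alive_t ~ Binomial(alive_{t-1}, p_t) with
    logit(p_t) = delta0 + delta_s s_t + delta_L [coastal] +
    delta_sL s_t [coastal] + delta_d t + c_clutch.  Days starting with no
    survivors contribute no information and are dropped, so an
    all-dead-on-day-1 series keeps the likelihood defined.  Default
    chains for this model are 4 x 50000 with a 25000 burn-in.
    """
    if not series:
        raise ValueError("no tadpole series supplied")
    rows_X, rows_k, rows_n, gidx = [], [], [], []
    labels = list(dict.fromkeys(s.clutch_id for s in series))
    pos = {c: i for i, c in enumerate(labels)}
    total_deaths = 0
    for s in series:
        coastal = 1.0 if s.location == "coastal" else 0.0
        prev = s.start_n
        for (day, sal), (_, alive) in zip(s.schedule, s.alive):
            if prev > 0:
                rows_X.append([1.0, sal, coastal, sal * coastal, float(day)])
                rows_k.append(alive)
                rows_n.append(prev)
                gidx.append(pos[s.clutch_id])
                total_deaths += prev - alive
            prev = alive
    boundary = total_deaths == 0
    if boundary:
        warnings.warn(
            "no deaths observed in any series; daily survival sits on the "
            "boundary",
            UserWarning,
        )
    pm = _prior_map(priors)
    pm = {("delta0" if k == "gamma0" else "delta_s" if k == "gamma_s" else k): v
          for k, v in pm.items()}
    model = _BinomialMixedModel(
        TadpoleFit.coef_names,
        np.asarray(rows_X),
        k=rows_k,
        n=rows_n,
        group_idx=gidx,
        group_labels=labels,
        priors=pm,
        re_sd_name="sigma_clutch",
    )
    draws = sample_posterior(model, cfg or TADPOLE_CFG)
    return _finalize(draws, "tadpole_survival", labels, boundary, cls=TadpoleFit)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _hurdle_prob_draws(fit: HurdleFit, salinity: float, location: str) -> np.ndarray:
    coastal = 1.0 if location == "coastal" else 0.0
    d = fit.draws
    eta = (
        d.stacked("gamma0")
        + d.stacked("gamma_s") * salinity
        + coastal * (d.stacked("gamma_L") + d.stacked("gamma_sL") * salinity)
    )
    return expit(eta)


def _tadpole_survival_draws(fit: TadpoleFit, target: float, location: str) -> np.ndarray:
    if float(target) not in RAMP_TARGETS:
        raise ValueError(
            f"tadpole predictions follow the acclimation ramp; target must be "
            f"one of {RAMP_TARGETS}, got {target}"
        )
    coastal = 1.0 if location == "coastal" else 0.0
    d = fit.draws
    d0 = d.stacked("delta0")
    ds = d.stacked("delta_s")
    dL = d.stacked("delta_L")
    dsL = d.stacked("delta_sL")
    dd = d.stacked("delta_d")
    surv = np.ones_like(d0)
    for day, sal in ramp_schedule(target):
        eta = d0 + ds * sal + coastal * (dL + dsL * sal) + dd * day
        surv = surv * expit(eta)
    return surv


def predict_response(
    fit: HurdleFit | TadpoleFit, salinity: float, location: str = "inland"
) -> tuple[float, float, float]:
    """Posterior predicted probability at group effect 0.

    For a :class:`HurdleFit` this is the per-draw logistic probability at
    the given salinity and location; for a :class:`TadpoleFit` it is the
    six-day product survival along the acclimation ramp to the target.
    Returns ``(mean, bci_low, bci_high)``.
    """
    if salinity < 0:
        raise ValueError("salinity must be nonnegative")
    if location not in ("coastal", "inland"):
        raise ValueError(f"location must be coastal or inland, got {location!r}")
    if not fit.converged:
        warnings.warn("predicting from a fit flagged non-converged", UserWarning)
    if isinstance(fit, TadpoleFit):
        p = _tadpole_survival_draws(fit, salinity, location)
    else:
        p = _hurdle_prob_draws(fit, salinity, location)
    lo, hi = np.percentile(p, [2.5, 97.5])
    mean = float(p.mean())
    return mean, min(float(lo), mean), max(float(hi), mean)
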