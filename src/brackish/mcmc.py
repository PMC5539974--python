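"""Generic MCMC machinery for small hierarchical regression models.

The sampler is a componentwise adaptive random-walk Metropolis scheme:
each fixed effect (on an unconstrained scale) is updated in turn against
the full posterior, and all group-level random intercepts are updated in
one vectorised block (they are conditionally independent given the fixed
effects).  Proposal scales adapt toward a 0.44 acceptance rate during
burn-in only, so the retained draws come from a fixed transition kernel.

A model is any object exposing

- ``fixed_params``: a sequence of :class:`ParamSpec` (name, prior on the
  natural scale, transform, initial value),
- ``n_groups`` and ``group_labels``: the random-intercept structure,
- ``re_sd_name``: the fixed parameter acting as the random-effect SD
  (or ``None`` for no random effects),
- ``group_loglik(fixed, u)``: per-group log-likelihood sums, vectorised.

Chains are launched from overdispersed starting points whose spread
varies by an order of magnitude across chains, and convergence is judged
with the Gelman–Rubin potential scale reduction factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ParamSpec",
    "McmcConfig",
    "PosteriorDraws",
    "gelman_rubin",
    "sample_posterior",
    "normal_prior",
    "gamma_prior",
    "uniform_prior",
    "DIFFUSE_PRIOR_VARIANCE",
]

# "Uninformative (relatively flat)" Gaussian prior on regression
# coefficients: precision 0.001, i.e. variance 1000.
DIFFUSE_PRIOR_VARIANCE = 1000.0


# ---------------------------------------------------------------------------
# Priors and transforms
# ---------------------------------------------------------------------------


def normal_prior(mean: float, sd: float) -> Callable[[float], float]:
    """Gaussian log-prior density on the natural scale."""
    if sd <= 0:
        raise ValueError("prior sd must be positive")
    const = -0.5 * math.log(2.0 * math.pi) - math.log(sd)

    def logpdf(x: float) -> float:
        z = (x - mean) / sd
        return const - 0.5 * z * z

    return logpdf


def gamma_prior(shape: float, rate: float) -> Callable[[float], float]:
    """Gamma(shape, rate) log-prior density for a positive parameter."""
    const = shape * math.log(rate) - math.lgamma(shape)

    def logpdf(x: float) -> float:
        if x <= 0:
            return -np.inf
        return const + (shape - 1.0) * math.log(x) - rate * x

    return logpdf


def uniform_prior(lo: float, hi: float) -> Callable[[float], float]:
    """Uniform(lo, hi) log-prior density."""
    const = -math.log(hi - lo)

    def logpdf(x: float) -> float:
        return const if lo <= x <= hi else -np.inf

    return logpdf


class _Identity:
    def to_natural(self, z: float) -> float:
        return z

    def to_unconstrained(self, x: float) -> float:
        return x

    def log_jacobian(self, z: float) -> float:
        return 0.0


class _Log:
    """Unconstrained z -> positive x = exp(z)."""

    def to_natural(self, z: float) -> float:
        return math.exp(z)

    def to_unconstrained(self, x: float) -> float:
        return math.log(x)

    def log_jacobian(self, z: float) -> float:
        return z


class _Interval:
    """Unconstrained z -> x in (lo, hi) via a scaled logistic."""

    def __init__(self, lo: float, hi: float):
        self.lo, self.hi = lo, hi

    def to_natural(self, z: float) -> float:
        return self.lo + (self.hi - self.lo) * expit(z)

    def to_unconstrained(self, x: float) -> float:
        p = (x - self.lo) / (self.hi - self.lo)
        p = min(max(p, 1e-12), 1 - 1e-12)
        return math.log(p / (1 - p))

    def log_jacobian(self, z: float) -> float:
        # d/dz [lo + (hi-lo) sigmoid(z)] = (hi-lo) sigmoid(z)(1-sigmoid(z))
        s = expit(z)
        s = min(max(s, 1e-300), 1 - 1e-16)
        return math.log(self.hi - self.lo) + math.log(s) + math.log1p(-s)


_TRANSFORMS = {"identity": _Identity, "log": _Log}


def _make_transform(spec):
    if isinstance(spec, str):
        return _TRANSFORMS[spec]()
    if isinstance(spec, tuple) and spec[0] == "interval":
        return _Interval(spec[1], spec[2])
    return spec


@dataclass
class ParamSpec:
    """One fixed parameter of a model: prior, support and starting value."""

    name: str
    prior: Callable[[float], float]
    init: float = 0.0
    transform: object = "identity"  # "identity" | "log" | ("interval", lo, hi)

    def __post_init__(self):
        self.transform = _make_transform(self.transform)


# ---------------------------------------------------------------------------
# Configuration and draws container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings.

    Defaults follow the study protocol: three chains of 5000 iterations
    with a 2500-iteration burn-in and starting values spread over an
    order of magnitude.  Retained draws = ``n_chains * (n_iter - n_burn)``.
    """

    n_chains: int = 3
    n_iter: int = 5000
    n_burn: int = 2500
    seed: int = 0
    init_spread: float = 0.5

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (convergence diagnostics)")
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("need 0 <= n_burn < n_iter")

    @property
    def n_kept(self) -> int:
        return self.n_chains * (self.n_iter - self.n_burn)


class PosteriorDraws:
    """Labelled per-chain MCMC draws; the currency between pipeline stages."""

    def __init__(self, names: Sequence[str], draws: np.ndarray):
        draws = np.asarray(draws, dtype=float)
        if draws.ndim != 3 or draws.shape[2] != len(names):
            raise ValueError(
                "draws must have shape (n_chains, n_draws, n_params) matching names"
            )
        if not np.all(np.isfinite(draws)):
            raise ValueError("draws must be finite")
        self.names = list(names)
        self.draws = draws
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Per-chain draws of one parameter, shape (n_chains, n_draws)."""
        return self.draws[:, :, self._index[name]]

    def stacked(self, name: str) -> np.ndarray:
        """All draws of one parameter pooled across chains."""
        return self.get(name).reshape(-1)

    def rhat(self, name: str) -> float:
        return gelman_rubin(self.get(name))

    def max_rhat(self, names: Sequence[str] | None = None) -> float:
        return max(self.rhat(n) for n in (names or self.names))

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: chain, iteration, parameter, value."""
        n_c, n_d, n_p = self.draws.shape
        chain = np.repeat(np.arange(n_c), n_d * n_p)
        iteration = np.tile(np.repeat(np.arange(n_d), n_p), n_c)
        parameter = np.tile(self.names, n_c * n_d)
        return pd.DataFrame(
            {
                "chain": chain,
                "iteration": iteration,
                "parameter": parameter,
                "value": self.draws.reshape(-1),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorDraws":
        names = list(dict.fromkeys(df["parameter"]))
        n_c = df["chain"].nunique()
        n_d = df["iteration"].nunique()
        wide = df.pivot_table(
            index=["chain", "iteration"], columns="parameter", values="value", sort=False
        )[names]
        return cls(names, wide.to_numpy().reshape(n_c, n_d, len(names)))

    @classmethod
    def from_arrays(cls, mapping: dict[str, np.ndarray]) -> "PosteriorDraws":
        """Build from a dict of per-chain (n_chains, n_draws) arrays."""
        names = list(mapping)
        stacked = np.stack([np.asarray(mapping[n], dtype=float) for n in names], axis=-1)
        return cls(names, stacked)

    @classmethod
    def degenerate(cls, values: dict[str, float], n_chains: int = 2, n_draws: int = 2):
        """A point-mass posterior — handy for closed-form checks."""
        arr = np.tile(
            np.array([values[n] for n in values], dtype=float), (n_chains, n_draws, 1)
        )
        return cls(list(values), arr)


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat for one parameter.

    ``chains`` has shape (n_chains, n); with W the mean within-chain
    variance and B = n * variance of the chain means,

        R-hat = sqrt( ((n-1)/n * W + B/n) / W ).

    Values near 1 indicate the chains have mixed; > 1.1 is flagged as
    non-convergence.  A single chain is rejected (diagnostic undefined).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n)")
    m, n = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if n < 2:
        raise ValueError("Gelman-Rubin requires chains of length >= 2")
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

_TARGET_ACC = 0.44  # componentwise RWM optimum
_ADAPT_BATCH = 25


def _u_logprior(u: np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5 * (u / sd) ** 2


def sample_posterior(model, cfg: McmcConfig) -> PosteriorDraws:
    """Draw from a hierarchical model's posterior.

    Returns draws for every fixed parameter (natural scale) and one
    ``u[label]`` series per random-intercept group.
    """
    specs = list(model.fixed_params)
    n_fixed = len(specs)
    n_groups = int(getattr(model, "n_groups", 0))
    labels = (
        list(getattr(model, "group_labels", [str(j) for j in range(n_groups)]))
        if n_groups
        else []
    )
    re_sd_name = getattr(model, "re_sd_name", None)
    sd_idx = None
    if n_groups and re_sd_name is not None:
        sd_idx = [s.name for s in specs].index(re_sd_name)
    # Likelihood-invariant shift moves: for a fixed effect whose covariate
    # is constant within every group (value x_g for group g), the transform
    # (coef + eps, u_g - eps * x_g) leaves every linear predictor untouched,
    # so the move is judged on the priors alone.  These directions are the
    # weakly identified ridges of hierarchical models (the intercept vs. the
    # mean random effect being the canonical case) and are where plain
    # Metropolis mixing stalls.  Models advertise them via
    # ``group_covariates``: {fixed-param name: per-group covariate values}.
    shift_moves: list[tuple[int, np.ndarray]] = []
    if n_groups:
        names_order = [s.name for s in specs]
        for pname, xg in getattr(model, "group_covariates", {}).items():
            idx = names_order.index(pname)
            if isinstance(specs[idx].transform, _Identity):
                shift_moves.append((idx, np.asarray(xg, dtype=float)))

    names = [s.name for s in specs] + [f"u[{lab}]" for lab in labels]
    n_kept = cfg.n_iter - cfg.n_burn
    out = np.empty((cfg.n_chains, n_kept, n_fixed + n_groups))

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    center = np.array([s.transform.to_unconstrained(s.init) for s in specs])

    for c in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[c])
        # Overdispersed starts: per-chain spread spans an order of magnitude.
        frac = c / (cfg.n_chains - 1) if cfg.n_chains > 1 else 0.5
        spread = cfg.init_spread * 10.0 ** (frac - 0.5)
        z = center + rng.normal(size=n_fixed) * spread
        u = rng.normal(size=n_groups) * 0.1 if n_groups else np.zeros(0)

        natural = np.array([s.transform.to_natural(z[i]) for i, s in enumerate(specs)])
        re_sd = natural[sd_idx] if sd_idx is not None else 1.0

        def fixed_logp(zvec, nat):
            lp = 0.0
            for i, s in enumerate(specs):
                lp += s.prior(nat[i]) + s.transform.log_jacobian(zvec[i])
            return lp

        gl = np.asarray(model.group_loglik(natural, u), dtype=float)
        cur_ll = gl.sum()
        cur_fixed_lp = fixed_logp(z, natural)
        cur_u_lp = _u_logprior(u, re_sd).sum() if n_groups else 0.0

        scales = np.full(n_fixed, 0.2)
        u_scales = np.full(n_groups, 0.3)
        acc = np.zeros(n_fixed)
        u_acc = np.zeros(n_groups)

        # Running moments of z for the joint (Haario-style) proposal, which
        # handles correlated fixed effects that componentwise moves mix
        # through slowly.  The covariance freezes at the end of burn-in.
        hist_n = 0
        hist_mean = np.zeros(n_fixed)
        hist_m2 = np.zeros((n_fixed, n_fixed))
        joint_chol = None
        joint_scale = 1.0
        joint_acc = 0.0
        shift_scales = np.full(len(shift_moves), 0.5)
        shift_accs = np.zeros(len(shift_moves))

        for it in range(cfg.n_iter):
            # --- componentwise fixed-effect updates -----------------------
            for i, s in enumerate(specs):
                z_prop = z.copy()
                z_prop[i] += rng.normal() * scales[i]
                nat_prop = natural.copy()
                nat_prop[i] = s.transform.to_natural(z_prop[i])
                prop_fixed_lp = fixed_logp(z_prop, nat_prop)
                if not np.isfinite(prop_fixed_lp):
                    continue
                gl_prop = np.asarray(model.group_loglik(nat_prop, u), dtype=float)
                prop_ll = gl_prop.sum()
                sd_prop = nat_prop[sd_idx] if sd_idx is not None else 1.0
                prop_u_lp = _u_logprior(u, sd_prop).sum() if n_groups else 0.0
                log_alpha = (
                    prop_ll + prop_fixed_lp + prop_u_lp - cur_ll - cur_fixed_lp - cur_u_lp
                )
                if np.isfinite(log_alpha) and math.log(rng.uniform()) < log_alpha:
                    z, natural, gl = z_prop, nat_prop, gl_prop
                    cur_ll, cur_fixed_lp, cur_u_lp = prop_ll, prop_fixed_lp, prop_u_lp
                    re_sd = sd_prop
                    acc[i] += 1

            # --- joint fixed-effect update (adaptive covariance) ----------
            if it < cfg.n_burn:
                hist_n += 1
                delta_mean = z - hist_mean
                hist_mean += delta_mean / hist_n
                hist_m2 += np.outer(delta_mean, z - hist_mean)
                if hist_n >= 50 * n_fixed and (it + 1) % (10 * _ADAPT_BATCH) == 0:
                    cov = hist_m2 / (hist_n - 1)
                    cov = 5.66 / n_fixed * cov + 1e-9 * np.eye(n_fixed)
                    try:
                        joint_chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        joint_chol = None
            if joint_chol is not None:
                z_prop = z + joint_scale * (joint_chol @ rng.normal(size=n_fixed))
                nat_prop = np.array(
                    [s.transform.to_natural(z_prop[i]) for i, s in enumerate(specs)]
                )
                prop_fixed_lp = fixed_logp(z_prop, nat_prop)
                if np.isfinite(prop_fixed_lp):
                    gl_prop = np.asarray(model.group_loglik(nat_prop, u), dtype=float)
                    prop_ll = gl_prop.sum()
                    sd_prop = nat_prop[sd_idx] if sd_idx is not None else 1.0
                    prop_u_lp = _u_logprior(u, sd_prop).sum() if n_groups else 0.0
                    log_alpha = (
                        prop_ll + prop_fixed_lp + prop_u_lp
                        - cur_ll - cur_fixed_lp - cur_u_lp
                    )
                    if np.isfinite(log_alpha) and math.log(rng.uniform()) < log_alpha:
                        z, natural, gl = z_prop, nat_prop, gl_prop
                        cur_ll, cur_fixed_lp, cur_u_lp = (
                            prop_ll, prop_fixed_lp, prop_u_lp,
                        )
                        re_sd = sd_prop
                        joint_acc += 1

            # --- blocked random-intercept update (vectorised) -------------
            if n_groups:
                u_prop = u + rng.normal(size=n_groups) * u_scales
                gl_prop = np.asarray(model.group_loglik(natural, u_prop), dtype=float)
                delta = (
                    gl_prop
                    - gl
                    + _u_logprior(u_prop, re_sd)
                    - _u_logprior(u, re_sd)
                )
                accept = np.log(rng.uniform(size=n_groups)) < delta
                if accept.any():
                    u = np.where(accept, u_prop, u)
                    gl = np.where(accept, gl_prop, gl)
                    cur_ll = gl.sum()
                    cur_u_lp = _u_logprior(u, re_sd).sum()
                u_acc += accept

            # --- fixed-effect/random-effect shift moves -------------------
            for m, (idx, xg) in enumerate(shift_moves):
                eps = rng.normal() * shift_scales[m]
                coef_prop = natural[idx] + eps
                u_prop = u - eps * xg
                log_alpha = (
                    specs[idx].prior(coef_prop)
                    - specs[idx].prior(natural[idx])
                    + (_u_logprior(u_prop, re_sd) - _u_logprior(u, re_sd)).sum()
                )
                if np.isfinite(log_alpha) and math.log(rng.uniform()) < log_alpha:
                    z[idx] = coef_prop
                    natural[idx] = coef_prop
                    u = u_prop
                    cur_fixed_lp = fixed_logp(z, natural)
                    cur_u_lp = _u_logprior(u, re_sd).sum()
                    shift_accs[m] += 1

            # --- adaptation during burn-in only ---------------------------
            if it < cfg.n_burn and (it + 1) % _ADAPT_BATCH == 0:
                step = min(0.5, 2.0 / math.sqrt((it + 1) / _ADAPT_BATCH))
                scales *= np.exp(step * (acc / _ADAPT_BATCH - _TARGET_ACC))
                acc[:] = 0
                if n_groups:
                    u_scales *= np.exp(step * (u_acc / _ADAPT_BATCH - _TARGET_ACC))
                    u_acc[:] = 0
                if joint_chol is not None:
                    joint_scale *= math.exp(step * (joint_acc / _ADAPT_BATCH - 0.25))
                    joint_acc = 0.0
                if shift_moves:
                    shift_scales *= np.exp(
                        step * (shift_accs / _ADAPT_BATCH - _TARGET_ACC)
                    )
                    shift_accs[:] = 0

            if it >= cfg.n_burn:
                k = it - cfg.n_burn
                out[c, k, :n_fixed] = natural
                if n_groups:
                    out[c, k, n_fixed:] = u

    return PosteriorDraws(names, out)
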