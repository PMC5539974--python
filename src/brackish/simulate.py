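"""Synthetic-data generators with known ground truth.

Three generators emulate the statistical structure of the three data
layers — the literature meta-analysis table, the binary-choice
oviposition/hatching trials, and the ramped tadpole survival series — so
every fitting stage can be tested end to end without the original data.

Default parameter values are anchored to the scale of the study system:
per-stage dose-response coefficients whose implied LC50s sit near 4.15,
5.5 and 9 ppt for eggs, tadpoles and adults; clutch sizes averaging 1363
eggs; a 3-freshwater + 3-salt cup choice design at 4/6/8/12 ppt; and
six-day ramps to 0.5/4/6/8/12 ppt with logit-linear daily survival.
These are documented defaults of the generator, not estimates.

A single global seed fans out to per-component seeds through
``numpy.random.SeedSequence`` so each layer can be regenerated
independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from brackish.io import (
    RAMP_DAYS,
    RAMP_TARGETS,
    TADPOLE_START_N,
    VALID_TREATMENTS,
    CupRecord,
    HatchRecord,
    LifeStage,
    OvipositionTrial,
    SurvivalRecord,
    TadpoleSeries,
    ramp_schedule,
)

__all__ = [
    "StageTruth",
    "MetaTruth",
    "LogitCoef",
    "TadpoleCoef",
    "GardenTruth",
    "default_meta_truth",
    "default_garden_truth",
    "simulate_meta_dataset",
    "simulate_oviposition",
    "simulate_tadpoles",
    "realized_study_effects",
    "true_survival",
    "true_lc50",
    "expected_six_day_survival",
]


# ---------------------------------------------------------------------------
# Ground-truth parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageTruth:
    """Beta-regression truth for one life stage.

    ``beta0``/``beta1`` are the logit-scale intercept and salinity slope,
    ``sigma_u`` the between-study SD and ``phi`` the beta precision.
    """

    beta0: float
    beta1: float
    sigma_u: float
    phi: float
    n_studies: int
    salinities: tuple[float, ...]
    n_per_obs: int = 20  # exposed animals behind each extracted proportion

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be nonnegative")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")


@dataclass(frozen=True)
class MetaTruth:
    """Per-stage truth for the whole meta-analysis layer."""

    stages: dict

    def __post_init__(self):
        object.__setattr__(
            self, "stages", {LifeStage(k): v for k, v in self.stages.items()}
        )


def default_meta_truth() -> MetaTruth:
    """Defaults emulating the published per-stage dose-response scales.

    Egg: LC50 4.15 ppt; tadpole: 5.44 ppt; adult: 9.04 ppt (the least
    studied stage, with only three studies).  sigma_u = 0.3 and phi = 20
    give moderate between-study heterogeneity and replicate noise.
    """
    return MetaTruth(
        {
            LifeStage.EGG: StageTruth(
                beta0=1.12, beta1=-0.27, sigma_u=0.3, phi=20.0,
                n_studies=30, salinities=(0.0, 2.0, 4.0, 6.0, 8.0, 12.0),
            ),
            LifeStage.TADPOLE: StageTruth(
                beta0=1.43, beta1=-0.263, sigma_u=0.3, phi=20.0,
                n_studies=30, salinities=(0.0, 2.0, 4.0, 6.0, 8.0, 12.0),
            ),
            LifeStage.ADULT: StageTruth(
                beta0=0.75, beta1=-0.083, sigma_u=0.3, phi=20.0,
                n_studies=3, salinities=(0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0),
            ),
        }
    )


@dataclass(frozen=True)
class LogitCoef:
    """Logit-linear coefficients for one garden stage.

    ``intercept + salinity*s + location*[coastal] + interaction*s*[coastal]``
    plus a group random intercept with SD ``re_sd``.
    """

    intercept: float
    salinity: float
    location: float
    interaction: float
    re_sd: float = 0.3

    def eta(self, s, coastal):
        return (
            self.intercept
            + self.salinity * s
            + coastal * (self.location + self.interaction * s)
        )


@dataclass(frozen=True)
class TadpoleCoef(LogitCoef):
    """Daily-survival coefficients; adds a linear day effect."""

    day: float = 0.0

    def eta(self, s, coastal, day=0.0):
        return super().eta(s, coastal) + self.day * day


@dataclass(frozen=True)
class GardenTruth:
    """Ground truth for the common-garden layer.

    ``choice`` drives cup-level any-eggs-laid; ``investment`` the
    proportion of the clutch laid in freshwater; ``hatch_any`` and
    ``hatch_prop`` the two hatching stages; ``tadpole`` the daily ramp
    survival.  Clutch sizes are rounded log-normal with mean
    ``clutch_mean``.
    """

    choice: LogitCoef = LogitCoef(2.8, -0.23, -1.5, 0.31, re_sd=0.3)
    investment: LogitCoef = LogitCoef(0.8, 0.16, 0.0, -0.09, re_sd=0.3)
    hatch_any: LogitCoef = LogitCoef(1.26, -0.52, 1.13, -0.04, re_sd=0.3)
    hatch_prop: LogitCoef = LogitCoef(2.0, -0.9, -0.5, 0.36, re_sd=0.3)
    tadpole: TadpoleCoef = TadpoleCoef(6.0, -0.6, -0.04, 0.08, re_sd=0.17, day=0.0)
    clutch_mean: float = 1363.0
    clutch_log_sd: float = 0.25

    def __post_init__(self):
        if self.clutch_mean <= 0:
            raise ValueError("clutch_mean must be positive")


def default_garden_truth() -> GardenTruth:
    """Defaults anchored to the printed common-garden scales: coastal
    pairs keep laying in salt while inland pairs avoid it, hatching
    collapses above ~8 ppt, and six-day tadpole survival falls from
    ~0.98 in freshwater to ~0.23 (coastal) / ~0.08 (inland) at 12 ppt."""
    return GardenTruth()


# Closed-form helpers (oracles for tests and calibration checks).


def true_survival(truth: StageTruth, salinity) -> np.ndarray | float:
    """Mean survival at a salinity for a typical study (u = 0)."""
    return expit(truth.beta0 + truth.beta1 * np.asarray(salinity, dtype=float))


def true_lc50(truth: StageTruth) -> float:
    """The salinity where the true mean survival crosses 0.5."""
    if truth.beta1 >= 0:
        raise ValueError("LC50 undefined for non-decreasing survival")
    return -truth.beta0 / truth.beta1


def expected_six_day_survival(
    coef: TadpoleCoef, target: float, location: str = "inland"
) -> float:
    """Product of daily survival probabilities along the ramp (clutch
    effect at 0)."""
    coastal = 1.0 if location == "coastal" else 0.0
    p = 1.0
    for day, sal in ramp_schedule(target):
        p *= float(expit(coef.eta(sal, coastal, day)))
    return p


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def simulate_meta_dataset(
    truth: MetaTruth | StageTruth,
    seed: int | np.random.SeedSequence = 0,
    stage: LifeStage | str | None = None,
) -> list[SurvivalRecord]:
    """Draw a synthetic meta-analysis table.

    For each study j, u_j ~ N(0, sigma_u^2); at each salinity s the
    extracted proportion is Beta(mu*phi, (1-mu)*phi) with
    logit(mu) = beta0 + beta1*s + u_j.  Passing a :class:`StageTruth`
    (plus ``stage``) simulates a single stage; a :class:`MetaTruth`
    simulates every stage it holds, fanning the seed out per stage.
    """
    if isinstance(truth, StageTruth):
        if stage is None:
            raise ValueError("stage must be given with a StageTruth")
        return _simulate_stage(truth, LifeStage(stage), np.random.default_rng(seed))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(truth.stages))
    records: list[SurvivalRecord] = []
    for child, (stg, st) in zip(children, truth.stages.items()):
        records.extend(_simulate_stage(st, stg, np.random.default_rng(child)))
    return records


def _simulate_stage(st: StageTruth, stage: LifeStage, rng) -> list[SurvivalRecord]:
    records = []
    u = rng.normal(0.0, st.sigma_u, size=st.n_studies) if st.sigma_u > 0 else np.zeros(
        st.n_studies
    )
    for j in range(st.n_studies):
        study_id = f"{stage.value}-study-{j + 1:03d}"
        for s in st.salinities:
            mu = float(expit(st.beta0 + st.beta1 * s + u[j]))
            mu = min(max(mu, 1e-9), 1 - 1e-9)
            y = float(rng.beta(mu * st.phi, (1.0 - mu) * st.phi))
            records.append(
                SurvivalRecord(
                    study_id=study_id,
                    life_stage=stage,
                    salinity_ppt=float(s),
                    survival_prop=y,
                    species=f"synthetic sp. {j % 7 + 1}",
                    family="synthetic",
                    n_exposed=st.n_per_obs,
                    exposure_hours=96.0,
                    location="synthetic",
                )
            )
    return records


def realized_study_effects(
    truth: MetaTruth, seed: int | np.random.SeedSequence = 0
) -> dict[LifeStage, np.ndarray]:
    """The u_j actually drawn by :func:`simulate_meta_dataset` for a seed.

    With few studies the estimable dose-response is the one conditional
    on the realised study effects, -(beta0 + mean u_j)/beta1 for the
    LC50; this helper reproduces the generator's random-effect draws so
    oracles can target that quantity.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(truth.stages))
    out = {}
    for child, (stg, st) in zip(children, truth.stages.items()):
        rng = np.random.default_rng(child)
        out[stg] = (
            rng.normal(0.0, st.sigma_u, size=st.n_studies)
            if st.sigma_u > 0
            else np.zeros(st.n_studies)
        )
    return out


def _round_lognormal(rng, mean: float, log_sd: float) -> int:
    mu = np.log(mean) - 0.5 * log_sd**2
    return max(1, int(round(rng.lognormal(mu, log_sd))))


def simulate_oviposition(
    truth: GardenTruth,
    n_replicates: int = 4,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[OvipositionTrial], list[HatchRecord]]:
    """Draw one oviposition + hatching experiment.

    Per location and replicate, one bin per salt treatment (4/6/8/12
    ppt), each with three freshwater and three salt cups.  The clutch
    size is rounded log-normal; the investment model splits eggs between
    salt and freshwater; the choice model opens/closes individual cups
    (any-laid); the two hatch models generate hatch counts per cup with
    eggs.  Deterministic given the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    trials: list[OvipositionTrial] = []
    hatches: list[HatchRecord] = []
    for location in ("inland", "coastal"):
        coastal = 1.0 if location == "coastal" else 0.0
        for rep in range(1, n_replicates + 1):
            for treat in VALID_TREATMENTS:
                bin_id = f"{location}-r{rep}-t{int(treat)}"
                b_choice = rng.normal(0.0, truth.choice.re_sd)
                b_inv = rng.normal(0.0, truth.investment.re_sd)
                b_hany = rng.normal(0.0, truth.hatch_any.re_sd)
                b_hprop = rng.normal(0.0, truth.hatch_prop.re_sd)

                clutch = _round_lognormal(rng, truth.clutch_mean, truth.clutch_log_sd)
                cup_ppts = [0.0, 0.0, 0.0, treat, treat, treat]
                open_cup = [
                    rng.uniform() < expit(truth.choice.eta(ppt, coastal) + b_choice)
                    for ppt in cup_ppts
                ]
                p_fresh = float(expit(truth.investment.eta(treat, coastal) + b_inv))
                n_salt = int(rng.binomial(clutch, 1.0 - p_fresh))
                n_fresh = clutch - n_salt

                open_fresh = [i for i in range(3) if open_cup[i]]
                open_salt = [i for i in range(3, 6) if open_cup[i]]
                eggs = [0] * 6
                # Eggs destined for a class with no open cup spill into the
                # other class; a bin with no open cups lays nothing.
                if not open_salt and open_fresh:
                    n_fresh, n_salt = clutch, 0
                if not open_fresh and open_salt:
                    n_salt, n_fresh = clutch, 0
                if open_fresh and n_fresh:
                    counts = rng.multinomial(
                        n_fresh, [1 / len(open_fresh)] * len(open_fresh)
                    )
                    for i, c in zip(open_fresh, counts):
                        eggs[i] = int(c)
                if open_salt and n_salt:
                    counts = rng.multinomial(
                        n_salt, [1 / len(open_salt)] * len(open_salt)
                    )
                    for i, c in zip(open_salt, counts):
                        eggs[i] = int(c)

                cups = tuple(
                    CupRecord(f"{bin_id}-c{i + 1}", float(cup_ppts[i]), eggs[i])
                    for i in range(6)
                )
                trials.append(
                    OvipositionTrial(
                        bin_id=bin_id,
                        location=location,
                        replicate_block=f"{location}-r{rep}",
                        salt_treatment_ppt=float(treat),
                        cups=cups,
                    )
                )
                for cup in cups:
                    if cup.eggs_laid == 0:
                        continue
                    p_any = float(
                        expit(truth.hatch_any.eta(cup.cup_salinity_ppt, coastal) + b_hany)
                    )
                    if rng.uniform() >= p_any:
                        hatched = 0
                    else:
                        p_h = float(
                            expit(
                                truth.hatch_prop.eta(cup.cup_salinity_ppt, coastal)
                                + b_hprop
                            )
                        )
                        hatched = max(1, int(rng.binomial(cup.eggs_laid, p_h)))
                    hatches.append(
                        HatchRecord(
                            cup_id=cup.cup_id,
                            bin_id=bin_id,
                            location=location,
                            cup_salinity_ppt=cup.cup_salinity_ppt,
                            eggs_laid=cup.eggs_laid,
                            hatched=hatched,
                        )
                    )
    return trials, hatches


def simulate_tadpoles(
    truth: GardenTruth,
    n_clutches: int = 8,
    seed: int | np.random.SeedSequence = 0,
) -> list[TadpoleSeries]:
    """Draw ramped tadpole-survival series.

    Per location and clutch, five groups of 50 tadpoles are assigned to
    the five ramp targets; each day alive_t ~ Binomial(alive_{t-1}, p_t)
    with p_t from the daily-survival model at that day's ramp salinity.
    The clutch random effect is shared across a clutch's five groups.
    """
    if n_clutches < 1:
        raise ValueError("n_clutches must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    series: list[TadpoleSeries] = []
    for location in ("inland", "coastal"):
        coastal = 1.0 if location == "coastal" else 0.0
        for c in range(1, n_clutches + 1):
            clutch_id = f"{location}-clutch-{c:02d}"
            c_eff = rng.normal(0.0, truth.tadpole.re_sd)
            for target in RAMP_TARGETS:
                sched = ramp_schedule(target)
                alive = []
                prev = TADPOLE_START_N
                for day, sal in sched:
                    p = float(expit(truth.tadpole.eta(sal, coastal, day) + c_eff))
                    prev = int(rng.binomial(prev, p)) if prev > 0 else 0
                    alive.append((day, prev))
                series.append(
                    TadpoleSeries(
                        clutch_id=clutch_id,
                        location=location,
                        target_salinity_ppt=float(target),
                        schedule=tuple(sched),
                        alive=tuple(alive),
                    )
                )
    return series
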