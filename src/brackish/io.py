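"""Domain types, salinity unit conversion and CSV ingestion.

Three data layers share this module: the literature meta-analysis table
(one row per study x salinity level), and the common-garden trial tables
(oviposition cups, hatch counts, daily tadpole counts).  Validation is
strict: rows violating a type invariant are rejected and logged with the
row number and reason; structurally broken files fail hard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LifeStage",
    "SurvivalRecord",
    "CupRecord",
    "OvipositionTrial",
    "HatchRecord",
    "TadpoleSeries",
    "convert_salinity",
    "SALINITY_UNITS",
    "ramp_schedule",
    "RAMP_TARGETS",
    "read_survival_csv",
    "read_garden_csv",
    "write_survival_csv",
    "write_garden_csv",
]


class LifeStage(str, Enum):
    """Anuran life stage distinguished by the meta-analysis."""

    EGG = "egg"
    TADPOLE = "tadpole"
    ADULT = "adult"


# Free-text stage labels seen in extracted tables, mapped onto the enum.
_STAGE_SYNONYMS = {
    "egg": LifeStage.EGG,
    "eggs": LifeStage.EGG,
    "embryo": LifeStage.EGG,
    "embryos": LifeStage.EGG,
    "tadpole": LifeStage.TADPOLE,
    "tadpoles": LifeStage.TADPOLE,
    "larva": LifeStage.TADPOLE,
    "larvae": LifeStage.TADPOLE,
    "larval": LifeStage.TADPOLE,
    "adult": LifeStage.ADULT,
    "adults": LifeStage.ADULT,
    "frog": LifeStage.ADULT,
}


def parse_life_stage(label: str) -> LifeStage:
    """Normalize a free-text stage label (case-insensitive, synonym-aware)."""
    key = str(label).strip().lower()
    try:
        return _STAGE_SYNONYMS[key]
    except KeyError:
        raise ValueError(
            f"unrecognized life stage {label!r}; expected one of "
            f"{sorted(set(_STAGE_SYNONYMS))}"
        ) from None


# ---------------------------------------------------------------------------
# Salinity unit conversion
# ---------------------------------------------------------------------------

# Multiplicative factors to parts per thousand (~ g NaCl per litre).
# Seawater is 35 ppt, hence percent_seawater * 0.35.  Conductivity uses a
# fixed freshwater-range linear approximation of 0.64 g/L per mS/cm.
SALINITY_UNITS = {
    "ppt": 1.0,
    "g_per_L": 1.0,
    "mg_per_L": 1e-3,
    "percent_seawater": 0.35,
    "mol_NaCl_per_L": 58.44,  # molar mass of NaCl, g/mol
    "mS_per_cm": 0.64,
}


def convert_salinity(value: float, unit: str = "ppt") -> float:
    """Convert a salinity measurement to parts per thousand (ppt).

    Parameters
    ----------
    value
        Nonnegative measurement in the given unit.
    unit
        One of ``ppt``, ``g_per_L``, ``mg_per_L``, ``percent_seawater``,
        ``mol_NaCl_per_L`` or ``mS_per_cm``.

    Returns
    -------
    float
        The salinity in ppt.
    """
    if unit not in SALINITY_UNITS:
        raise ValueError(
            f"unknown salinity unit {unit!r}; supported units: "
            f"{sorted(SALINITY_UNITS)}"
        )
    value = float(value)
    if value < 0:
        raise ValueError(f"salinity must be nonnegative, got {value}")
    return value * SALINITY_UNITS[unit]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalRecord:
    """One study x salinity observation for the meta-analysis.

    ``survival_prop`` is the proportion surviving the exposure (possibly
    digitized from a published figure); ``n_exposed`` and ``survival_sd``
    are frequently missing in extracted tables and are therefore optional.
    """

    study_id: str
    life_stage: LifeStage
    salinity_ppt: float
    survival_prop: float
    species: str = ""
    family: str = ""
    n_exposed: int | None = None
    survival_sd: float | None = None
    exposure_hours: float | None = None
    location: str = ""

    def __post_init__(self):
        if not str(self.study_id):
            raise ValueError("study_id must be nonempty")
        if not isinstance(self.life_stage, LifeStage):
            object.__setattr__(self, "life_stage", parse_life_stage(self.life_stage))
        if self.salinity_ppt < 0:
            raise ValueError(f"salinity_ppt must be >= 0, got {self.salinity_ppt}")
        if not 0.0 <= self.survival_prop <= 1.0:
            raise ValueError(
                f"survival_prop must be in [0, 1], got {self.survival_prop}"
            )
        if self.n_exposed is not None and self.n_exposed < 1:
            raise ValueError(f"n_exposed must be positive, got {self.n_exposed}")
        if self.survival_sd is not None and self.survival_sd < 0:
            raise ValueError(f"survival_sd must be >= 0, got {self.survival_sd}")
        if self.exposure_hours is not None and self.exposure_hours <= 0:
            raise ValueError(
                f"exposure_hours must be positive, got {self.exposure_hours}"
            )


@dataclass(frozen=True)
class CupRecord:
    """A single pint cup inside an oviposition bin."""

    cup_id: str
    cup_salinity_ppt: float
    eggs_laid: int

    def __post_init__(self):
        if self.cup_salinity_ppt < 0:
            raise ValueError("cup_salinity_ppt must be >= 0")
        if self.eggs_laid < 0:
            raise ValueError("eggs_laid must be >= 0")


VALID_TREATMENTS = (4.0, 6.0, 8.0, 12.0)


@dataclass(frozen=True)
class OvipositionTrial:
    """One bin of the binary-choice oviposition design.

    Each bin holds six cups: three freshwater (0 ppt) and three at the
    bin's salt treatment (4, 6, 8 or 12 ppt); an amplexed pair chooses
    where to lay.
    """

    bin_id: str
    location: str  # "coastal" | "inland"
    replicate_block: str
    salt_treatment_ppt: float
    cups: tuple[CupRecord, ...]

    def __post_init__(self):
        if self.location not in ("coastal", "inland"):
            raise ValueError(f"location must be coastal or inland, got {self.location}")
        if float(self.salt_treatment_ppt) not in VALID_TREATMENTS:
            raise ValueError(
                f"salt_treatment_ppt must be one of {VALID_TREATMENTS}, "
                f"got {self.salt_treatment_ppt}"
            )
        if len(self.cups) != 6:
            raise ValueError(f"a bin must hold exactly 6 cups, got {len(self.cups)}")
        n_fresh = sum(1 for c in self.cups if c.cup_salinity_ppt == 0)
        if n_fresh != 3:
            raise ValueError(
                f"a bin must hold 3 freshwater and 3 salt cups, got {n_fresh} freshwater"
            )

    @property
    def total_eggs(self) -> int:
        return sum(c.eggs_laid for c in self.cups)

    @property
    def freshwater_eggs(self) -> int:
        return sum(c.eggs_laid for c in self.cups if c.cup_salinity_ppt == 0)


@dataclass(frozen=True)
class HatchRecord:
    """Hatch outcome of one cup in which eggs were laid."""

    cup_id: str
    bin_id: str
    location: str
    cup_salinity_ppt: float
    eggs_laid: int
    hatched: int

    def __post_init__(self):
        if self.eggs_laid < 1:
            raise ValueError("eggs_laid must be positive for a hatch record")
        if not 0 <= self.hatched <= self.eggs_laid:
            raise ValueError(
                f"hatched must be in [0, eggs_laid], got {self.hatched} of "
                f"{self.eggs_laid} in cup {self.cup_id}"
            )
        if self.cup_salinity_ppt < 0:
            raise ValueError("cup_salinity_ppt must be >= 0")


RAMP_TARGETS = (0.5, 4.0, 6.0, 8.0, 12.0)

# Daily increments printed for the acclimation design, ppt/day.
_RAMP_INCREMENTS = {4.0: 0.67, 6.0: 1.0, 8.0: 1.33, 12.0: 2.0}

TADPOLE_START_N = 50
RAMP_DAYS = 6


def ramp_schedule(target_ppt: float) -> list[tuple[int, float]]:
    """Six-day salinity acclimation schedule for a tadpole treatment.

    Treatments are raised by a fixed daily increment (0.67, 1, 1.33 or
    2 ppt/day for the 4, 6, 8 and 12 ppt targets) so that day 6 reaches
    the target; the salinity on day ``d`` is ``d`` times the increment.
    The 0.5 ppt freshwater control is held at 0.5 ppt throughout.
    """
    target = float(target_ppt)
    if target not in RAMP_TARGETS:
        raise ValueError(
            f"target_ppt must be one of {RAMP_TARGETS}, got {target_ppt}"
        )
    if target == 0.5:
        return [(day, 0.5) for day in range(1, RAMP_DAYS + 1)]
    inc = _RAMP_INCREMENTS[target]
    return [(day, round(day * inc, 2)) for day in range(1, RAMP_DAYS + 1)]


@dataclass(frozen=True)
class TadpoleSeries:
    """Daily alive counts for one group of 50 tadpoles on a salinity ramp."""

    clutch_id: str
    location: str
    target_salinity_ppt: float
    schedule: tuple[tuple[int, float], ...]
    alive: tuple[tuple[int, int], ...]
    start_n: int = TADPOLE_START_N

    def __post_init__(self):
        if self.location not in ("coastal", "inland"):
            raise ValueError(f"location must be coastal or inland, got {self.location}")
        expected = ramp_schedule(self.target_salinity_ppt)
        sched = [(int(d), float(s)) for d, s in self.schedule]
        if sched != expected:
            raise ValueError(
                f"schedule for target {self.target_salinity_ppt} ppt does not "
                f"match the acclimation ramp"
            )
        days = [d for d, _ in self.alive]
        counts = [c for _, c in self.alive]
        if days != list(range(1, RAMP_DAYS + 1)):
            raise ValueError("alive counts must cover days 1..6 in order")
        if any(c < 0 or c > self.start_n for c in counts):
            raise ValueError(f"alive counts must be within [0, {self.start_n}]")
        if any(b > a for a, b in zip([self.start_n] + counts[:-1], counts)):
            raise ValueError(
                f"alive counts must be nonincreasing (clutch {self.clutch_id})"
            )

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.alive]

    @property
    def salinities(self) -> list[float]:
        return [s for _, s in self.schedule]


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

_META_REQUIRED = ("study", "stage", "salinity", "survival")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def _opt(row, col, cast):
    if col not in row.index:
        return None
    v = row[col]
    if pd.isna(v) or v == "":
        return None
    return cast(v)


def read_survival_csv(path) -> list[SurvivalRecord]:
    """Read a meta-analysis table into validated :class:`SurvivalRecord` s.

    Expected columns: ``study,species,family,stage,salinity,unit,n,
    survival,sd,hours,location`` — only ``study,stage,salinity,survival``
    are required.  When a ``unit`` column is present, salinity is converted
    to ppt row by row.  Invalid rows are dropped and logged with their row
    number and the reason; a missing required column is a hard failure.
    """
    df = pd.read_csv(path)
    _require_columns(df, _META_REQUIRED, path)
    records: list[SurvivalRecord] = []
    for i, row in df.iterrows():
        try:
            unit = _opt(row, "unit", str) or "ppt"
            rec = SurvivalRecord(
                study_id=str(row["study"]),
                life_stage=parse_life_stage(row["stage"]),
                salinity_ppt=convert_salinity(float(row["salinity"]), unit),
                survival_prop=float(row["survival"]),
                species=_opt(row, "species", str) or "",
                family=_opt(row, "family", str) or "",
                n_exposed=_opt(row, "n", lambda v: int(float(v))),
                survival_sd=_opt(row, "sd", float),
                exposure_hours=_opt(row, "hours", float),
                location=_opt(row, "location", str) or "",
            )
        except (ValueError, TypeError) as exc:
            logger.warning("%s: row %d rejected: %s", path, i + 2, exc)
            continue
        records.append(rec)
    return records


def write_survival_csv(records: Iterable[SurvivalRecord], path) -> None:
    """Write survival records in the dialect :func:`read_survival_csv` reads."""
    rows = [
        {
            "study": r.study_id,
            "species": r.species,
            "family": r.family,
            "stage": r.life_stage.value,
            "salinity": r.salinity_ppt,
            "unit": "ppt",
            "n": r.n_exposed,
            "survival": r.survival_prop,
            "sd": r.survival_sd,
            "hours": r.exposure_hours,
            "location": r.location,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _read_oviposition(df: pd.DataFrame, path) -> list[OvipositionTrial]:
    _require_columns(
        df, ("bin", "location", "block", "treatment_ppt", "cup", "cup_ppt", "eggs"), path
    )
    trials = []
    for bin_id, grp in df.groupby("bin", sort=False):
        try:
            cups = tuple(
                CupRecord(str(r["cup"]), float(r["cup_ppt"]), int(r["eggs"]))
                for _, r in grp.iterrows()
            )
            trials.append(
                OvipositionTrial(
                    bin_id=str(bin_id),
                    location=str(grp["location"].iloc[0]),
                    replicate_block=str(grp["block"].iloc[0]),
                    salt_treatment_ppt=float(grp["treatment_ppt"].iloc[0]),
                    cups=cups,
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("%s: bin %r rejected: %s", path, bin_id, exc)
    return trials


def _read_hatch(df: pd.DataFrame, path) -> list[HatchRecord]:
    _require_columns(df, ("cup", "bin", "location", "cup_ppt", "laid", "hatched"), path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                HatchRecord(
                    cup_id=str(row["cup"]),
                    bin_id=str(row["bin"]),
                    location=str(row["location"]),
                    cup_salinity_ppt=float(row["cup_ppt"]),
                    eggs_laid=int(row["laid"]),
                    hatched=int(row["hatched"]),
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("%s: row %d rejected: %s", path, i + 2, exc)
    return records


def _read_tadpole(df: pd.DataFrame, path) -> list[TadpoleSeries]:
    _require_columns(df, ("clutch", "location", "target_ppt", "day", "ppt", "alive"), path)
    series = []
    for (clutch, target), grp in df.groupby(["clutch", "target_ppt"], sort=False):
        grp = grp.sort_values("day")
        try:
            series.append(
                TadpoleSeries(
                    clutch_id=str(clutch),
                    location=str(grp["location"].iloc[0]),
                    target_salinity_ppt=float(target),
                    schedule=tuple(
                        (int(r["day"]), float(r["ppt"])) for _, r in grp.iterrows()
                    ),
                    alive=tuple(
                        (int(r["day"]), int(r["alive"])) for _, r in grp.iterrows()
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning(
                "%s: series (clutch %r, %s ppt) rejected: %s", path, clutch, target, exc
            )
    return series


def read_garden_csv(path, kind: str):
    """Read a common-garden table of the given ``kind``.

    ``kind`` is one of ``oviposition`` (returns :class:`OvipositionTrial`
    list), ``hatch`` (:class:`HatchRecord` list) or ``tadpole``
    (:class:`TadpoleSeries` list).  Units failing their invariants (a bin
    without exactly 3+3 cups, hatched > laid, increasing alive counts, a
    schedule off the ramp) are rejected with a logged reason.
    """
    readers = {
        "oviposition": _read_oviposition,
        "hatch": _read_hatch,
        "tadpole": _read_tadpole,
    }
    if kind not in readers:
        raise ValueError(f"kind must be one of {sorted(readers)}, got {kind!r}")
    return readers[kind](pd.read_csv(path), path)


def write_garden_csv(items, kind: str, path) -> None:
    """Write garden records in the dialect :func:`read_garden_csv` reads."""
    if kind == "oviposition":
        rows = [
            {
                "bin": t.bin_id,
                "location": t.location,
                "block": t.replicate_block,
                "treatment_ppt": t.salt_treatment_ppt,
                "cup": c.cup_id,
                "cup_ppt": c.cup_salinity_ppt,
                "eggs": c.eggs_laid,
            }
            for t in items
            for c in t.cups
        ]
    elif kind == "hatch":
        rows = [
            {
                "cup": h.cup_id,
                "bin": h.bin_id,
                "location": h.location,
                "cup_ppt": h.cup_salinity_ppt,
                "laid": h.eggs_laid,
                "hatched": h.hatched,
            }
            for h in items
        ]
    elif kind == "tadpole":
        rows = [
            {
                "clutch": s.clutch_id,
                "location": s.location,
                "target_ppt": s.target_salinity_ppt,
                "day": day,
                "ppt": ppt,
                "alive": alive,
            }
            for s in items
            for (day, ppt), (_, alive) in zip(s.schedule, s.alive)
        ]
    else:
        raise ValueError(f"kind must be oviposition, hatch or tadpole, got {kind!r}")
    pd.DataFrame(rows).to_csv(path, index=False)
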