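"""Cohort data structures, long-format I/O, age scales and the exclusion cascade.

A cohort is a list of :class:`ChildTrajectory` objects, one per child, each
holding an ordered list of :class:`VisitRecord`. Ages are postnatal days;
gestational age (GA) at birth is stored in days, with preterm defined as
GA < 259 days (37 completed weeks). The GA-corrected age scale subtracts the
"missing" gestation time (280 − GA days) from every postnatal age of a
preterm child, so that preterm trajectories are compared against reference
children of the same postmenstrual maturity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical follow-up schedule tags, in chronological order
VISIT_TAGS = ("birth", "m3", "m12", "m24", "m48", "y6", "y11")

DAYS_PER_MONTH = 365.25 / 12.0
FULL_TERM_GA_DAYS = 280.0
PRETERM_GA_DAYS = 259.0  # < 37 completed weeks

INDICES = ("HAZ", "WAZ", "BMIZ")


class CohortFormatError(ValueError):
    """Malformed long-format cohort table."""


class MissingBaselineError(ValueError):
    """Birth z-score missing, so the trajectory cannot be baseline-centered."""


@dataclass
class VisitRecord:
    visit_tag: str
    age_days: float
    weight: float | None = None          # kg
    length_height: float | None = None   # cm
    z: dict[str, float] = field(default_factory=dict)

    @property
    def bmi(self) -> float | None:
        """kg/m², derived when both weight and length/height are present."""
        if self.weight is None or self.length_height is None:
            return None
        return self.weight / (self.length_height / 100.0) ** 2

    def measurement(self, measure: str) -> float | None:
        if measure == "weight":
            return self.weight
        if measure == "length_height":
            return self.length_height
        if measure == "bmi":
            return self.bmi
        raise KeyError(measure)


@dataclass
class ChildTrajectory:
    child_id: str
    sex: str  # "F" | "M"
    ga_days: float | None
    visits: list[VisitRecord] = field(default_factory=list)
    ga_conflict: bool = False

    @property
    def preterm(self) -> bool:
        return self.ga_days is not None and self.ga_days < PRETERM_GA_DAYS

    def visit(self, tag: str) -> VisitRecord | None:
        for v in self.visits:
            if v.visit_tag == tag:
                return v
        return None

    def z_series(self, index: str) -> np.ndarray:
        """Per-visit z-scores for one index, NaN where missing."""
        return np.array(
            [v.z.get(index, math.nan) for v in self.visits], dtype=float
        )

    def set_z_series(self, index: str, values: Sequence[float]) -> None:
        for v, val in zip(self.visits, values, strict=True):
            v.z[index] = float(val)


COHORT_COLUMNS = (
    "child_id",
    "sex",
    "ga_weeks",
    "visit_tag",
    "age_days",
    "weight_kg",
    "length_cm",
)


def read_cohort_long(path: str | Path) -> list[ChildTrajectory]:
    """Read a long-format cohort CSV (one row per child per visit).

    Blank cells are missing. Duplicate (child_id, visit_tag) pairs and
    unknown visit tags are errors. A child whose rows disagree on GA is kept
    with ``ga_conflict=True`` (the exclusion cascade removes it as
    discordant).
    """
    df = pd.read_csv(path, dtype={"child_id": str, "sex": str, "visit_tag": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortFormatError(f"missing columns: {sorted(missing)}")
    bad_tags = set(df["visit_tag"].unique()) - set(VISIT_TAGS)
    if bad_tags:
        raise CohortFormatError(f"unknown visit_tag values: {sorted(bad_tags)}")
    dup = df.duplicated(subset=["child_id", "visit_tag"])
    if dup.any():
        rows = df.loc[dup, ["child_id", "visit_tag"]].iloc[0]
        raise CohortFormatError(
            f"duplicate visit: child {rows['child_id']} tag {rows['visit_tag']}"
        )

    order = {t: i for i, t in enumerate(VISIT_TAGS)}
    cohort: list[ChildTrajectory] = []
    for child_id, grp in df.groupby("child_id", sort=True):
        grp = grp.sort_values("visit_tag", key=lambda s: s.map(order))
        ga_vals = grp["ga_weeks"].dropna().unique()
        conflict = len(ga_vals) > 1
        ga_days = float(ga_vals[0]) * 7.0 if len(ga_vals) == 1 else None
        visits = []
        for _, row in grp.iterrows():
            visits.append(
                VisitRecord(
                    visit_tag=row["visit_tag"],
                    age_days=float(row["age_days"]),
                    weight=None if pd.isna(row["weight_kg"]) else float(row["weight_kg"]),
                    length_height=None if pd.isna(row["length_cm"]) else float(row["length_cm"]),
                )
            )
        ages = [v.age_days for v in visits]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise CohortFormatError(f"child {child_id}: visit ages not strictly increasing")
        cohort.append(
            ChildTrajectory(
                child_id=str(child_id),
                sex=str(grp["sex"].iloc[0]),
                ga_days=ga_days,
                visits=visits,
                ga_conflict=conflict,
            )
        )
    return cohort


def cohort_to_frame(cohort: Iterable[ChildTrajectory]) -> pd.DataFrame:
    rows = []
    for child in cohort:
        ga_weeks = "" if child.ga_days is None else child.ga_days / 7.0
        for v in child.visits:
            rows.append(
                {
                    "child_id": child.child_id,
                    "sex": child.sex,
                    "ga_weeks": ga_weeks,
                    "visit_tag": v.visit_tag,
                    "age_days": v.age_days,
                    "weight_kg": "" if v.weight is None else v.weight,
                    "length_cm": "" if v.length_height is None else v.length_height,
                }
            )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort_long(cohort: Iterable[ChildTrajectory], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False, float_format="%.6g")


def ga_corrected_age(
    age_days: float, ga_days: float, apply_to_term: bool = False
) -> float:
    """GA-corrected age = postnatal age − (280 − GA at birth), preterm only.

    Term children (GA ≥ 259 d) are returned unchanged unless
    ``apply_to_term``. The corrected age may be negative very close to
    birth; the caller decides how to handle that.
    """
    if ga_days is None or not np.isfinite(ga_days):
        return age_days
    if ga_days >= PRETERM_GA_DAYS and not apply_to_term:
        return age_days
    return age_days - (FULL_TERM_GA_DAYS - ga_days)


@dataclass(frozen=True)
class CenteringConfig:
    """Baseline centering: subtract ``factor`` times the birth z-score.

    The default factor 1.002 (rather than exactly 1) leaves a residual of
    (1 − factor)·z_birth ≈ 0 at birth; distances here tolerate exact zeros,
    but the near-unit default is kept as the canonical configuration.
    """

    factor: float = 1.002
    enabled: bool = True

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("centering factor must be positive")


def baseline_center(
    z_series: Sequence[float], cfg: CenteringConfig = CenteringConfig()
) -> np.ndarray:
    """Subtract factor·(birth z) from every value of a per-visit z-series.

    The first element is the birth value. All pairwise differences between
    visits are preserved exactly, so the trajectory's shape is untouched.

    Raises :class:`MissingBaselineError` when the birth value is missing.
    """
    z = np.asarray(z_series, dtype=float)
    if not cfg.enabled:
        return z.copy()
    if z.size == 0 or not np.isfinite(z[0]):
        raise MissingBaselineError("birth z-score missing; cannot center")
    return z - cfg.factor * z[0]


EXCLUSION_REASONS = (
    "missing_discordant_ga",
    "implausible_birth_anthro",
    "single_followup",
    "under3_observations",
)


@dataclass
class ExclusionReport:
    counts: dict[str, int]
    retained: int
    excluded_ids: dict[str, list[str]]

    @property
    def total(self) -> int:
        return self.retained + sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": r, "n": self.counts[r]} for r in EXCLUSION_REASONS]
        rows.append({"reason": "retained", "n": self.retained})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExclusionConfig:
    min_obs: int = 3
    ga_bounds_days: tuple[float, float] = (154.0, 315.0)  # 22–45 weeks
    birth_weight_bounds_kg: tuple[float, float] = (0.3, 6.5)
    birth_length_bounds_cm: tuple[float, float] = (25.0, 60.0)


def _visit_attended(v: VisitRecord) -> bool:
    return v.weight is not None or v.length_height is not None


def exclusion_cascade(
    cohort: Sequence[ChildTrajectory],
    cfg: ExclusionConfig = ExclusionConfig(),
) -> tuple[list[ChildTrajectory], ExclusionReport]:
    """Apply the four exclusion rules in order; each child counts once.

    1. missing or discordant GA (outside the plausibility envelope, or
       conflicting duplicate values);
    2. missing or implausible birth weight/length;
    3. exactly one post-birth visit attended;
    4. fewer than ``min_obs`` non-missing z-score observations (birth
       included) in any of HAZ/WAZ/BMIZ — requires z-scores to have been
       computed and cleaned beforehand.
    """
    kept: list[ChildTrajectory] = []
    counts = {r: 0 for r in EXCLUSION_REASONS}
    excluded: dict[str, list[str]] = {r: [] for r in EXCLUSION_REASONS}
    lo_ga, hi_ga = cfg.ga_bounds_days
    lo_w, hi_w = cfg.birth_weight_bounds_kg
    lo_l, hi_l = cfg.birth_length_bounds_cm

    for child in cohort:
        reason = None
        ga = child.ga_days
        birth = child.visit("birth")
        if child.ga_conflict or ga is None or not (lo_ga <= ga <= hi_ga):
            reason = "missing_discordant_ga"
        elif (
            birth is None
            or birth.weight is None
            or birth.length_height is None
            or not (lo_w <= birth.weight <= hi_w)
            or not (lo_l <= birth.length_height <= hi_l)
        ):
            reason = "implausible_birth_anthro"
        elif sum(_visit_attended(v) for v in child.visits if v.visit_tag != "birth") == 1:
            reason = "single_followup"
        else:
            for index in INDICES:
                if int(np.isfinite(child.z_series(index)).sum()) < cfg.min_obs:
                    reason = "under3_observations"
                    break
        if reason is None:
            kept.append(child)
        else:
            counts[reason] += 1
            excluded[reason].append(child.child_id)

    return kept, ExclusionReport(counts=counts, retained=len(kept), excluded_ids=excluded)
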