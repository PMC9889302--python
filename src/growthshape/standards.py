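"""LMS growth-standard z-scores, standard selection, and plausibility cleaning.

The LMS method summarises a reference distribution at each age by a
Box–Cox power L, a median M and a coefficient of variation S; the z-score
of a measurement x is

    z = ((x/M)**L − 1) / (L·S)   for L ≠ 0
    z = ln(x/M) / S              for L = 0.

Reference tables are CSVs with one row per (standard, sex, measure, age);
lookups interpolate L, M and S linearly in age between bracketing rows.
Four standard segments are recognised: a newborn standard keyed by
gestational age at birth, an infant postnatal standard used at the 3-month
visit, and under-5 / over-5 references for the later visits.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ChildTrajectory, ga_corrected_age

STANDARDS = ("newborn_by_ga", "infant_postnatal", "under5", "over5")
SEXES = ("F", "M")
MEASURES = ("weight", "length_height", "bmi")
INDICES = ("HAZ", "WAZ", "BMIZ")
INDEX_TO_MEASURE = {"WAZ": "weight", "HAZ": "length_height", "BMIZ": "bmi"}

#: postnatal age (days) up to and including which the under-5 reference applies
UNDER5_MAX_AGE_DAYS = 1826  # floor(5 * 365.25)

_L_ZERO_TOL = 1e-12

LMS_COLUMNS = ("standard", "sex", "measure", "age_days", "L", "M", "S")


class LMSValidationError(ValueError):
    """Reference table violates the LMS schema."""


def zscore_lms(x, L, M, S):
    """LMS z-score of measurement(s) x; NaN propagates, x ≤ 0 is an error."""
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0):
        raise ValueError("measurement must be positive")
    near_zero = np.abs(L) < _L_ZERO_TOL
    L_safe = np.where(near_zero, 1.0, L)
    # expm1 form of ((x/M)**L - 1)/(L*S): well-conditioned as L -> 0
    with np.errstate(invalid="ignore"):
        z = np.where(
            near_zero,
            np.log(x / M) / S,
            np.expm1(L_safe * np.log(x / M)) / (L_safe * S),
        )
    return float(z) if z.ndim == 0 else z


def inverse_zscore_lms(z, L, M, S):
    """Measurement whose LMS z-score is z; exact inverse of :func:`zscore_lms`."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    near_zero = np.abs(L) < _L_ZERO_TOL
    lsz = L * S * z
    if np.any(~near_zero & (1.0 + lsz <= 0)):
        raise ValueError("z out of the representable range for these L, S")
    L_safe = np.where(near_zero, 1.0, L)
    lsz_safe = np.where(near_zero | np.isnan(lsz), 0.0, lsz)
    # log1p form of M*(1 + L*S*z)**(1/L): well-conditioned as L -> 0
    x = np.where(
        near_zero,
        M * np.exp(S * z),
        M * np.exp(np.log1p(lsz_safe) / L_safe),
    )
    x = np.where(np.isnan(z), np.nan, x)
    return float(x) if x.ndim == 0 else x


@dataclass
class LMSReference:
    """Validated, sorted LMS table with linear age interpolation."""

    table: pd.DataFrame
    _groups: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LMSReference":
        missing = set(LMS_COLUMNS) - set(df.columns)
        if missing:
            raise LMSValidationError(f"missing columns: {sorted(missing)}")
        df = df.loc[:, list(LMS_COLUMNS)].copy()
        for col, allowed in (("standard", STANDARDS), ("sex", SEXES), ("measure", MEASURES)):
            bad = set(df[col].unique()) - set(allowed)
            if bad:
                raise LMSValidationError(f"unknown {col} values: {sorted(bad)}")
        bad = df[(df["M"] <= 0) | (df["S"] <= 0)]
        if len(bad):
            row = bad.iloc[0]
            raise LMSValidationError(
                f"non-positive M or S at standard={row['standard']} sex={row['sex']} "
                f"measure={row['measure']} age_days={row['age_days']}"
            )
        df = df.sort_values(["standard", "sex", "measure", "age_days"], kind="mergesort")
        groups = {}
        for key, grp in df.groupby(["standard", "sex", "measure"], sort=False):
            ages = grp["age_days"].to_numpy(float)
            if np.any(np.diff(ages) <= 0):
                i = int(np.flatnonzero(np.diff(ages) <= 0)[0])
                raise LMSValidationError(
                    f"ages not strictly increasing for {key} near age_days={ages[i + 1]}"
                )
            groups[key] = {
                "age": ages,
                "L": grp["L"].to_numpy(float),
                "M": grp["M"].to_numpy(float),
                "S": grp["S"].to_numpy(float),
            }
        ref = cls(table=df.reset_index(drop=True))
        ref._groups = groups
        return ref

    def lookup(self, standard: str, sex: str, measure: str, age_days):
        """(L, M, S) at the given age(s), linearly interpolated.

        NaN ages yield NaN parameters; finite ages outside the tabulated
        range raise ``LookupError``.
        """
        try:
            grp = self._groups[(standard, sex, measure)]
        except KeyError:
            raise LookupError(f"no rows for ({standard}, {sex}, {measure})") from None
        age = np.asarray(age_days, dtype=float)
        flat = np.atleast_1d(age)
        finite = np.isfinite(flat)
        lo, hi = grp["age"][0], grp["age"][-1]
        if np.any((flat[finite] < lo) | (flat[finite] > hi)):
            raise LookupError(
                f"age outside table range [{lo}, {hi}] for ({standard}, {sex}, {measure})"
            )
        out = tuple(np.interp(age, grp["age"], grp[k]) for k in ("L", "M", "S"))
        if age.ndim == 0:
            return tuple(float(v) for v in out)
        return out

    def zscore(self, standard, sex, measure, age_days, x):
        L, M, S = self.lookup(standard, sex, measure, age_days)
        return zscore_lms(x, L, M, S)

    def inverse_zscore(self, standard, sex, measure, age_days, z):
        L, M, S = self.lookup(standard, sex, measure, age_days)
        return inverse_zscore_lms(z, L, M, S)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.8g")


def load_lms_table(path: str | Path) -> LMSReference:
    """Load and validate an LMS reference CSV."""
    return LMSReference.from_frame(pd.read_csv(path))


def select_standard(age_days: float, visit_tag: str) -> str:
    """Standard segment for a visit: newborn at birth, infant at 3 months,
    then under-5 / over-5 references split at 5 years of age."""
    if visit_tag == "birth":
        return "newborn_by_ga"
    if visit_tag == "m3":
        return "infant_postnatal"
    return "under5" if age_days <= UNDER5_MAX_AGE_DAYS else "over5"


def scoring_axis_age(
    visit_tag: str,
    age_days: float,
    ga_days: float | None,
    ga_corrected: bool = False,
    preterm_m3_corrected: bool = True,
) -> float:
    """Age on the reference table's axis for one visit.

    Birth is scored on the GA-keyed newborn standard (NaN when GA is
    missing). The 3-month visit of a preterm child uses the GA-corrected
    (postmenstrual-equivalent) age by default; later visits use the
    chronological postnatal age unless the GA-corrected scale is active.
    Corrected ages are clamped at 0 so they stay on the table.
    """
    if visit_tag == "birth":
        return float("nan") if ga_days is None else float(ga_days)
    if ga_corrected or (visit_tag == "m3" and preterm_m3_corrected):
        return max(0.0, ga_corrected_age(age_days, ga_days))
    return float(age_days)


DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "WAZ": (-6.0, 5.0),
    "HAZ": (-6.0, 6.0),
    "BMIZ": (-5.0, 5.0),
}


@dataclass(frozen=True)
class PlausibilityLimits:
    """Hard z-score bounds per index plus a between-visit jump threshold."""

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    max_step: float = 4.0

    def __post_init__(self):
        for index, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise ValueError(f"{index}: lower bound must be below upper bound")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")


def flag_series(
    z: Sequence[float], index: str, limits: PlausibilityLimits = PlausibilityLimits()
) -> dict[int, set[str]]:
    """Per-visit flag reasons for one z-score series (NaN = missing).

    A visit is flagged when its z falls outside the hard bounds, or when the
    jump to/from the nearest non-missing neighbouring visit exceeds
    ``max_step``.
    """
    z = np.asarray(z, dtype=float)
    lo, hi = limits.bounds[index]
    flags: dict[int, set[str]] = defaultdict(set)
    obs = np.flatnonzero(np.isfinite(z))
    for i in obs:
        if z[i] < lo:
            flags[int(i)].add("below_bound")
        elif z[i] > hi:
            flags[int(i)].add("above_bound")
    for a, b in zip(obs[:-1], obs[1:]):
        if abs(z[b] - z[a]) > limits.max_step:
            flags[int(a)].add("step_to_next")
            flags[int(b)].add("step_from_previous")
    return dict(flags)


def clean_series(
    z: Sequence[float], index: str, limits: PlausibilityLimits = PlausibilityLimits()
) -> tuple[np.ndarray, list[dict]]:
    """Set implausible values of a z-series to missing; return (series, actions).

    Hard-bound violations are removed unconditionally. A step-flagged value
    is removed only when it deviates by more than ``max_step`` from *both*
    its nearest preceding and nearest following non-missing neighbours;
    a value with a lone neighbour (series edge) is removed when it deviates
    from that neighbour, but only once no two-sided outlier is left — the
    interior context decides first, so a spike next to the edge is removed
    rather than the edge point it distorted. Remaining flags become
    warnings. Removal is iterated to a fixpoint, so cleaning is idempotent.
    """
    z = np.array(z, dtype=float)
    actions: list[dict] = []

    def neighbours(i: int) -> list[int]:
        obs = np.flatnonzero(np.isfinite(z))
        prev = obs[obs < i]
        nxt = obs[obs > i]
        out = []
        if prev.size:
            out.append(int(prev[-1]))
        if nxt.size:
            out.append(int(nxt[0]))
        return out

    warned: dict[int, set[str]] = {}
    while True:
        flags = flag_series(z, index, limits)
        for i, reasons in flags.items():
            warned.setdefault(i, set()).update(reasons)
        to_remove: list[tuple[int, str]] = []
        edge_remove: list[tuple[int, str]] = []
        for i, reasons in flags.items():
            if reasons & {"below_bound", "above_bound"}:
                to_remove.append((i, "hard_bound"))
            elif reasons & {"step_to_next", "step_from_previous"}:
                nb = neighbours(i)
                if nb and all(abs(z[i] - z[j]) > limits.max_step for j in nb):
                    (to_remove if len(nb) == 2 else edge_remove).append(
                        (i, "step_outlier")
                    )
        if not to_remove:
            to_remove = edge_remove
        if not to_remove:
            break
        for i, reason in to_remove:
            actions.append(
                {"visit": i, "index": index, "raw_z": float(z[i]),
                 "flag_reason": reason, "action": "set_missing"}
            )
            z[i] = math.nan

    for i, reasons in sorted(warned.items()):
        if np.isfinite(z[i]):
            actions.append(
                {"visit": i, "index": index, "raw_z": float(z[i]),
                 "flag_reason": "|".join(sorted(reasons)), "action": "retained_warning"}
            )
    return z, actions


def flag_implausible(
    traj: ChildTrajectory, limits: PlausibilityLimits = PlausibilityLimits()
) -> dict[str, dict[int, set[str]]]:
    """Flag every z-scored index of a trajectory; see :func:`flag_series`."""
    return {
        index: flag_series(traj.z_series(index), index, limits)
        for index in INDICES
        if np.isfinite(traj.z_series(index)).any()
    }


def clean_trajectory(
    traj: ChildTrajectory, limits: PlausibilityLimits = PlausibilityLimits()
) -> list[dict]:
    """Clean all z-scored indices of a trajectory in place; return the report
    rows (child_id, visit, index, raw_z, flag_reason, action)."""
    report: list[dict] = []
    for index in INDICES:
        series = traj.z_series(index)
        if not np.isfinite(series).any():
            continue
        cleaned, actions = clean_series(series, index, limits)
        traj.set_z_series(index, cleaned)
        for a in actions:
            a = dict(a)
            a["child_id"] = traj.child_id
            a["visit"] = traj.visits[a["visit"]].visit_tag
            report.append(a)
    return report
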