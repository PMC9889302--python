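"""Synthetic birth-cohort generator with known latent trajectory structure.

The generator emulates a prospective birth cohort followed at birth,
3, 12, 24 and 48 months and at 6 and 11 years: three latent growth classes
(High / Middle / Low, roughly a quarter / half / quarter of children),
about 12% preterm births, jittered visit ages, visit-level missingness,
and anthropometry obtained by inverting the LMS reference so that
re-scoring the measurements recovers the latent z-trajectories.

Each child's latent z-trajectory is

    z(t) = b0 + b1·t + A·exp(−t/τ) + ε_visit,

with per-class intercept/slope distributions, a class-specific early
"catch-up" amplitude A that decays over the first two years (τ = 8 months
by default), and iid visit noise. Height and weight z's share the latent
curve up to a child-level offset, so the three anthropometric indices are
correlated but not identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    DAYS_PER_MONTH,
    FULL_TERM_GA_DAYS,
    ChildTrajectory,
    VisitRecord,
    ga_corrected_age,
    write_cohort_long,
)
from .standards import LMSReference, scoring_axis_age, select_standard

#: (tag, mean age in months, jitter SD in months) — birth is exact
VISIT_SCHEDULE = (
    ("birth", 0.0, 0.0),
    ("m3", 3.0, 0.1),
    ("m12", 11.9, 0.2),
    ("m24", 23.9, 0.4),
    ("m48", 49.5, 1.7),
    ("y6", 81.6, 3.6),
    ("y11", 132.0, 3.6),
)


@dataclass(frozen=True)
class ClassParams:
    name: str
    intercept_mean: float
    intercept_sd: float
    slope_mean: float   # z per month
    slope_sd: float
    catchup: float      # amplitude of the decaying early-growth component


DEFAULT_CLASSES = (
    ClassParams("High", 0.64, 0.30, 0.004, 0.0015, 0.40),
    ClassParams("Middle", -0.55, 0.30, 0.0005, 0.0015, 0.0),
    ClassParams("Low", -1.85, 0.35, -0.003, 0.0015, -0.30),
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_children: int = 600
    preterm_fraction: float = 0.117
    female_fraction: float = 0.482
    class_probs: tuple[float, ...] = (0.25, 0.50, 0.25)
    classes: tuple[ClassParams, ...] = DEFAULT_CLASSES
    noise_sd: float = 0.25
    index_offset_sd: float = 0.15   # child-level HAZ/WAZ divergence
    catchup_tau_months: float = 8.0
    term_ga_mean: float = 276.5     # days; truncated to [259, 315]
    preterm_ga_mean: float = 246.0  # days; truncated to [154, 258]
    ga_sd: float = 14.0
    visit_schedule: tuple = VISIT_SCHEDULE
    missingness: float = 0.10       # per post-birth visit
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if any(p < 0 for p in self.class_probs):
            raise ValueError("class_probs must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def well_separated(cls, n_children: int = 600, seed: int = 0) -> "GeneratorConfig":
        """Three bands with class separation ten times the visit noise —
        the regime in which latent classes should be recovered essentially
        perfectly."""
        noise = 0.15
        classes = (
            ClassParams("High", 10 * noise, 0.10, 0.0, 0.0005, 0.30),
            ClassParams("Middle", 0.0, 0.10, 0.0, 0.0005, 0.0),
            ClassParams("Low", -10 * noise, 0.10, 0.0, 0.0005, -0.30),
        )
        return cls(
            n_children=n_children,
            classes=classes,
            noise_sd=noise,
            index_offset_sd=0.05,
            missingness=0.05,
            seed=seed,
        )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, size=int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def generate_cohort(
    cfg: GeneratorConfig = GeneratorConfig(),
    ref: LMSReference | None = None,
) -> tuple[list[ChildTrajectory], pd.DataFrame]:
    """Simulate a cohort; returns (children, truth table).

    The truth table is long-format: child_id, latent_class, ga_days,
    preterm, visit_tag, age_days, true HAZ and WAZ at each attended visit.
    Measurements are the LMS-inverse of the true z's, so re-scoring them
    against the same reference (chronological age scale) reproduces the
    truth exactly when ``noise_sd`` is the only randomness left.
    """
    if ref is None:
        ref = generate_lms_reference()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_children

    sex = np.where(rng.random(n) < cfg.female_fraction, "F", "M")
    preterm = rng.random(n) < cfg.preterm_fraction
    ga = np.where(
        preterm,
        _truncated_normal(rng, cfg.preterm_ga_mean, cfg.ga_sd, 154.0, 258.0, n),
        _truncated_normal(rng, cfg.term_ga_mean, cfg.ga_sd, 259.0, 315.0, n),
    )
    classes = rng.choice(len(cfg.classes), size=n, p=cfg.class_probs)

    cohort: list[ChildTrajectory] = []
    truth_rows = []
    for i in range(n):
        cls = cfg.classes[classes[i]]
        b0 = rng.normal(cls.intercept_mean, cls.intercept_sd)
        b1 = rng.normal(cls.slope_mean, cls.slope_sd)
        d_haz = rng.normal(0.0, cfg.index_offset_sd)
        d_waz = rng.normal(0.0, cfg.index_offset_sd)
        child_id = f"c{i:05d}"
        visits = []
        for tag, mean_mo, sd_mo in cfg.visit_schedule:
            if tag != "birth" and rng.random() < cfg.missingness:
                rng.normal(size=3)  # keep the stream aligned across patterns
                continue
            age_days = 0.0 if tag == "birth" else max(
                1.0, round((mean_mo + sd_mo * rng.normal()) * DAYS_PER_MONTH)
            )
            t_mo = age_days / DAYS_PER_MONTH
            latent = (
                b0 + b1 * t_mo + cls.catchup * np.exp(-t_mo / cfg.catchup_tau_months)
            )
            z_haz = latent + d_haz + cfg.noise_sd * rng.normal()
            z_waz = latent + d_waz + cfg.noise_sd * rng.normal()
            ax = scoring_axis_age(tag, age_days, float(ga[i]))
            standard = select_standard(ax, tag)
            length = ref.inverse_zscore(standard, sex[i], "length_height", ax, z_haz)
            weight = ref.inverse_zscore(standard, sex[i], "weight", ax, z_waz)
            visits.append(
                VisitRecord(tag, float(age_days), weight=float(weight),
                            length_height=float(length))
            )
            truth_rows.append(
                {"child_id": child_id, "latent_class": cls.name,
                 "ga_days": float(ga[i]), "preterm": bool(preterm[i]),
                 "visit_tag": tag, "age_days": float(age_days),
                 "true_haz": float(z_haz), "true_waz": float(z_waz)}
            )
        cohort.append(
            ChildTrajectory(child_id=child_id, sex=str(sex[i]),
                            ga_days=float(ga[i]), visits=visits)
        )
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


# ---------------------------------------------------------------------------
# synthetic LMS reference

_MEASURE_SHAPE = {  # L and S per measure: (L, S postnatal, S newborn)
    "weight": (0.3, 0.13, 0.15),
    "length_height": (1.0, 0.037, 0.045),
    "bmi": (-0.5, 0.085, 0.10),
}

_SEX_FACTOR = {"M": {"weight": 1.035, "length_height": 1.010, "bmi": 1.015},
               "F": {"weight": 1.0, "length_height": 1.0, "bmi": 1.0}}


def _weight_median(t_months: np.ndarray) -> np.ndarray:
    return 3.4 + 5.5 * (1.0 - np.exp(-t_months / 3.0)) + 0.205 * t_months


def _height_median(t_months: np.ndarray) -> np.ndarray:
    return 49.9 + 26.0 * (1.0 - np.exp(-t_months / 7.0)) + 0.52 * t_months


def _newborn_weight_median(ga_days: np.ndarray) -> np.ndarray:
    return 3.35 - 0.0238 * (FULL_TERM_GA_DAYS - ga_days)


def _newborn_length_median(ga_days: np.ndarray) -> np.ndarray:
    return 49.9 - 0.13 * (FULL_TERM_GA_DAYS - ga_days)


def _postnatal_median(measure: str, age_days: np.ndarray) -> np.ndarray:
    t = np.asarray(age_days, float) / DAYS_PER_MONTH
    if measure == "weight":
        return _weight_median(t)
    if measure == "length_height":
        return _height_median(t)
    return _weight_median(t) / (_height_median(t) / 100.0) ** 2


def _newborn_median(measure: str, ga_days: np.ndarray) -> np.ndarray:
    ga = np.asarray(ga_days, float)
    if measure == "weight":
        return _newborn_weight_median(ga)
    if measure == "length_height":
        return _newborn_length_median(ga)
    return _newborn_weight_median(ga) / (_newborn_length_median(ga) / 100.0) ** 2


_STANDARD_GRIDS = {
    "newborn_by_ga": np.arange(154.0, 316.0, 7.0),
    "infant_postnatal": np.arange(0.0, 501.0, 20.0),
    "under5": np.arange(0.0, 1901.0, 50.0),
    "over5": np.arange(1700.0, 4901.0, 100.0),
}


def generate_lms_reference() -> LMSReference:
    """Smooth synthetic LMS tables for all four standard segments.

    Median curves follow saturating-exponential-plus-linear growth in
    weight and height (BMI derived from the two); L and S are plausible
    constants per measure. Postnatal segments share the same curves, so
    z-scores are continuous across the under-5/over-5 boundary. These are
    stand-ins with the schema of real WHO/INTERGROWTH-style tables, not
    published coefficients.
    """
    rows = []
    for standard, grid in _STANDARD_GRIDS.items():
        newborn = standard == "newborn_by_ga"
        for sex in ("F", "M"):
            for measure, (L, s_post, s_newborn) in _MEASURE_SHAPE.items():
                M = (_newborn_median if newborn else _postnatal_median)(measure, grid)
                M = M * _SEX_FACTOR[sex][measure]
                S = s_newborn if newborn else s_post
                for age, m in zip(grid, M):
                    rows.append(
                        {"standard": standard, "sex": sex, "measure": measure,
                         "age_days": float(age), "L": L, "M": float(m), "S": S}
                    )
    return LMSReference.from_frame(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# exclusion-cascade fixture

FIXTURE_TOTAL = 4231
FIXTURE_DEFECTS = {
    "missing_discordant_ga": 41,
    "implausible_birth_anthro": 47,
    "single_followup": 105,
    "under3_observations": 93,
}


def generate_exclusion_fixture(
    seed: int = 2004,
) -> tuple[list[ChildTrajectory], LMSReference, pd.DataFrame]:
    """Cohort of 4231 children engineered so the exclusion cascade removes
    exactly 41 / 47 / 105 / 93 children for the four reasons (in cascade
    order, groups disjoint) and retains 3945.
    """
    ref = generate_lms_reference()
    cfg = GeneratorConfig(n_children=FIXTURE_TOTAL, missingness=0.0, seed=seed)
    cohort, truth = generate_cohort(cfg, ref)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(FIXTURE_TOTAL)

    pos = 0
    ga_ids = order[pos : pos + FIXTURE_DEFECTS["missing_discordant_ga"]]
    pos += len(ga_ids)
    anthro_ids = order[pos : pos + FIXTURE_DEFECTS["implausible_birth_anthro"]]
    pos += len(anthro_ids)
    single_ids = order[pos : pos + FIXTURE_DEFECTS["single_followup"]]
    pos += len(single_ids)
    sparse_ids = order[pos : pos + FIXTURE_DEFECTS["under3_observations"]]

    for j, i in enumerate(ga_ids):
        # half missing GA, half discordant (20 weeks, outside 22–45 wk)
        cohort[i].ga_days = None if j % 2 == 0 else 140.0
    for j, i in enumerate(anthro_ids):
        birth = cohort[i].visit("birth")
        if j % 2 == 0:
            birth.weight = 0.05  # below any plausible birth weight
        else:
            birth.length_height = 20.0
    for i in single_ids:
        # birth plus exactly one follow-up
        cohort[i].visits = [v for v in cohort[i].visits if v.visit_tag in ("birth", "m12")]
    for i in sparse_ids:
        # two follow-ups but length missing at both: HAZ (and BMIZ) observed
        # only at birth, while WAZ keeps 3 observations
        cohort[i].visits = [v for v in cohort[i].visits if v.visit_tag in ("birth", "m3", "m12")]
        for v in cohort[i].visits:
            if v.visit_tag != "birth":
                v.length_height = None
    return cohort, ref, truth


def write_bundle(
    out_dir: str | Path,
    cohort: Sequence[ChildTrajectory],
    ref: LMSReference,
    truth: pd.DataFrame,
    seed: int,
) -> dict:
    """Write cohort/reference/truth CSVs plus a JSON manifest; returns the
    manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_long(cohort, out / "cohort.csv")
    ref.to_csv(out / "lms_reference.csv")
    truth.to_csv(out / "truth.csv", index=False, float_format="%.6g")
    manifest = {
        "seed": seed,
        "n_children": len(cohort),
        "files": {"cohort": "cohort.csv", "lms": "lms_reference.csv", "truth": "truth.csv"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
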