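"""End-to-end orchestration of the 2×2 analytical approaches.

The pipeline z-scores a long-format cohort against an LMS reference,
cleans implausible values, applies the exclusion cascade, and then runs,
for each anthropometric index, the four analytical approaches formed by
crossing GA-correction of the age scale with baseline centering of the
trajectories — 12 clustering result sets in total. Centered approaches
cluster on centered series but report mean patterns and features on the
un-transformed z-scores.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    DAYS_PER_MONTH,
    CenteringConfig,
    ChildTrajectory,
    ExclusionConfig,
    ExclusionReport,
    MissingBaselineError,
    baseline_center,
    exclusion_cascade,
    ga_corrected_age,
    read_cohort_long,
)
from .clustering import ClusterResult, default_grid, kmeans_shape, label_patterns, mean_pattern
from .features import (
    MalnutritionCutoffs,
    features_table,
    malnutrition_by_pattern,
    malnutrition_table,
    mobility,
)
from .frechet import ShapeDistanceConfig
from .standards import (
    INDEX_TO_MEASURE,
    INDICES,
    LMSReference,
    PlausibilityLimits,
    clean_trajectory,
    load_lms_table,
    scoring_axis_age,
    select_standard,
)

log = logging.getLogger("growthshape")

DEFAULT_CONFIG: dict = {
    "k": 3,
    "indices": list(INDICES),
    "approaches": "all",  # or list of [ga_corrected, centered] pairs
    "centering_factor": 1.002,
    "time_scale": 0.1,
    "aggregation": "max",
    "lowess_span": 0.5,
    "min_obs": 3,
    "max_step": 4.0,
    "preterm_m3_corrected": True,
}


def load_config(path: str | Path | None) -> dict:
    """Defaults overridden by a YAML or JSON mapping."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    return cfg


@dataclass(frozen=True)
class ApproachSpec:
    ga_corrected: bool
    centered: bool
    index: str
    k: int = 3
    seed: int = 0

    @property
    def name(self) -> str:
        age = "corr" if self.ga_corrected else "ncorr"
        cent = "cent" if self.centered else "ncent"
        return f"{self.index}_{age}_{cent}"


def attach_zscores(
    cohort: Sequence[ChildTrajectory],
    ref: LMSReference,
    ga_corrected: bool = False,
    preterm_m3_corrected: bool = True,
) -> list[ChildTrajectory]:
    """Deep-copied cohort with HAZ/WAZ/BMIZ filled at every visit.

    Age on the reference axis: GA at birth for the newborn standard; at
    later visits the chronological — or, for preterm children under the
    GA-corrected scale, the corrected — postnatal age (clamped at 0, the
    caller's guard against rare negative corrected ages near birth).
    Missing measurements and missing GA at birth give missing z.
    """
    out = copy.deepcopy(list(cohort))
    for child in out:
        for v in child.visits:
            axis_age = scoring_axis_age(
                v.visit_tag, v.age_days, child.ga_days,
                ga_corrected=ga_corrected,
                preterm_m3_corrected=preterm_m3_corrected,
            )
            select_age = axis_age if np.isfinite(axis_age) else v.age_days
            standard = select_standard(select_age, v.visit_tag)
            for index in INDICES:
                x = v.measurement(INDEX_TO_MEASURE[index])
                if x is None or not np.isfinite(axis_age):
                    v.z[index] = float("nan")
                    continue
                try:
                    v.z[index] = float(
                        ref.zscore(standard, child.sex, INDEX_TO_MEASURE[index], axis_age, x)
                    )
                except LookupError:
                    v.z[index] = float("nan")
    return out


def clean_cohort(
    cohort: Sequence[ChildTrajectory], limits: PlausibilityLimits = PlausibilityLimits()
) -> pd.DataFrame:
    """Clean all children in place; return the full cleaning report."""
    rows: list[dict] = []
    for child in cohort:
        rows.extend(clean_trajectory(child, limits))
    return pd.DataFrame(
        rows, columns=["child_id", "visit", "index", "raw_z", "flag_reason", "action"]
    )


def trajectory_points(
    child: ChildTrajectory, index: str, ga_corrected: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """(ages in months, z) over non-missing visits, on the requested age scale."""
    ages, zs = [], []
    for v in child.visits:
        z = v.z.get(index, float("nan"))
        if not np.isfinite(z):
            continue
        age = v.age_days
        if ga_corrected and child.ga_days is not None:
            age = ga_corrected_age(age, child.ga_days)
        ages.append(age / DAYS_PER_MONTH)
        zs.append(z)
    return np.asarray(ages), np.asarray(zs)


@dataclass
class ApproachResult:
    spec: ApproachSpec
    cluster: ClusterResult
    labels: dict[str, str]           # child_id -> pattern name
    features: pd.DataFrame
    mean_patterns_raw: np.ndarray    # on un-transformed z-scores
    excluded_no_baseline: list[str] = field(default_factory=list)


def run_approach(
    cohort: Sequence[ChildTrajectory],
    spec: ApproachSpec,
    config: Mapping = DEFAULT_CONFIG,
) -> ApproachResult:
    """Cluster one index under one approach and derive per-child features.

    Clustering uses centered series when the approach is centered (children
    without a birth z for the index are excluded and reported); pattern
    means and features always use the original z-scores on the approach's
    age scale.
    """
    dist_cfg = ShapeDistanceConfig(
        time_scale=config["time_scale"], aggregation=config["aggregation"]
    )
    centering = CenteringConfig(factor=config["centering_factor"])
    raw: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    clustered: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    excluded: list[str] = []
    for child in cohort:
        t, z = trajectory_points(child, spec.index, spec.ga_corrected)
        if t.size == 0:
            continue
        raw[child.child_id] = (t, z)
        if spec.centered:
            birth = child.visit("birth")
            zb = birth.z.get(spec.index, float("nan")) if birth else float("nan")
            if not np.isfinite(zb):
                excluded.append(child.child_id)
                log.info("%s: missing birth %s, excluded from centered clustering",
                         child.child_id, spec.index)
                continue
            clustered[child.child_id] = (t, z - centering.factor * zb)
        else:
            clustered[child.child_id] = (t, z)

    ids = list(clustered)
    grid = default_grid()
    result = kmeans_shape(
        [clustered[i] for i in ids],
        spec.k,
        dist_cfg,
        seed=spec.seed,
        ids=ids,
        grid=grid,
        span=config["lowess_span"],
    )
    # name patterns on the un-transformed z-scale so High/Middle/Low refer
    # to actual attained growth, not centered shape
    raw_patterns = np.vstack([
        mean_pattern(
            [raw[i] for i in ids if result.labels[i] == c], grid,
            span=config["lowess_span"],
        )
        for c in range(spec.k)
    ])
    named = ClusterResult(
        k=result.k, labels=result.labels, mean_patterns=raw_patterns,
        grid=grid, iterations=result.iterations, converged=result.converged,
        seed=result.seed, inertia_history=result.inertia_history,
    )
    label_patterns(named)
    labels = named.named_labels()
    feats = features_table({i: raw[i] for i in ids}, labels)
    return ApproachResult(
        spec=spec, cluster=named, labels=labels, features=feats,
        mean_patterns_raw=raw_patterns, excluded_no_baseline=excluded,
    )


@dataclass
class PipelineResult:
    cohort: list[ChildTrajectory]
    exclusion: ExclusionReport
    cleaning_report: pd.DataFrame
    approaches: dict[str, ApproachResult]
    mobility_tables: dict[str, pd.DataFrame]
    manifest: dict


def _file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(dict(config), sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(
    cohort_path: str | Path,
    lms_path: str | Path,
    out_dir: str | Path | None = None,
    config: Mapping | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Execute the full pipeline; optionally write all artifacts to ``out_dir``.

    Stage order: z-scoring (both age scales) → cleaning → exclusion cascade
    (on chronological-age z-scores, applied once so every approach sees the
    same children) → per approach: clustering, pattern naming, features →
    malnutrition tables → cross-approach mobility. Reruns with identical
    inputs and seed produce identical label files.
    """
    config = {**DEFAULT_CONFIG, **(config or {})}
    raw_cohort = read_cohort_long(cohort_path)
    ref = load_lms_table(lms_path)
    limits = PlausibilityLimits(max_step=config["max_step"])

    scored = {}
    for ga_corr in (False, True):
        cohort_z = attach_zscores(
            raw_cohort, ref, ga_corrected=ga_corr,
            preterm_m3_corrected=config["preterm_m3_corrected"],
        )
        report = clean_cohort(cohort_z, limits)
        scored[ga_corr] = (cohort_z, report)

    base_cohort, cleaning_report = scored[False]
    kept, exclusion = exclusion_cascade(
        base_cohort, ExclusionConfig(min_obs=config["min_obs"])
    )
    kept_ids = {c.child_id for c in kept}
    cohorts = {
        ga: [c for c in cohort_z if c.child_id in kept_ids]
        for ga, (cohort_z, _) in scored.items()
    }

    if config["approaches"] == "all":
        combos = [(g, c) for g, c in product((False, True), (False, True))]
    else:
        combos = [tuple(bool(x) for x in pair) for pair in config["approaches"]]

    approaches: dict[str, ApproachResult] = {}
    for index in config["indices"]:
        for ga_corr, centered in combos:
            spec = ApproachSpec(
                ga_corrected=ga_corr, centered=centered, index=index,
                k=config["k"], seed=seed,
            )
            approaches[spec.name] = run_approach(cohorts[ga_corr], spec, config)

    mobility_tables: dict[str, pd.DataFrame] = {}
    for index in config["indices"]:
        rows = []
        names = [a for a in approaches if a.startswith(f"{index}_")]
        for a, b in combinations(names, 2):
            m = mobility(approaches[a].labels, approaches[b].labels)
            rows.append(
                {"approach_a": a, "approach_b": b, "n_common": m.n_common,
                 "movers": m.movers, "movers_fraction": m.movers_fraction,
                 "ari": m.ari}
            )
        mobility_tables[index] = pd.DataFrame(rows)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": dict(config),
        "config_sha256": config_hash(config),
        "inputs": {
            "cohort": str(cohort_path),
            "cohort_sha256": _file_sha256(cohort_path),
            "lms": str(lms_path),
            "lms_sha256": _file_sha256(lms_path),
        },
        "n_input": exclusion.total,
        "n_retained": exclusion.retained,
    }

    result = PipelineResult(
        cohort=kept, exclusion=exclusion, cleaning_report=cleaning_report,
        approaches=approaches, mobility_tables=mobility_tables, manifest=manifest,
    )
    if out_dir is not None:
        write_pipeline_outputs(result, out_dir, cohorts)
    return result


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path, cohorts) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.exclusion.to_frame().to_csv(out / "exclusion_report.csv", index=False)
    result.cleaning_report.to_csv(out / "cleaning_report.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    for name, ap in result.approaches.items():
        adir = out / name
        adir.mkdir(exist_ok=True)
        pd.DataFrame(
            [{"child_id": cid, "pattern": pat} for cid, pat in sorted(ap.labels.items())]
        ).to_csv(adir / "labels.csv", index=False)
        ap.features.to_csv(adir / "features.csv", index=False, float_format="%.6g")
        pd.DataFrame(
            ap.mean_patterns_raw.T,
            columns=[ap.cluster.pattern_names[c] for c in range(ap.cluster.k)],
        ).assign(age_months=ap.cluster.grid).to_csv(
            adir / "mean_patterns.csv", index=False, float_format="%.6g"
        )
        meta = {
            "approach": name, "k": ap.cluster.k, "seed": ap.cluster.seed,
            "iterations": ap.cluster.iterations, "converged": ap.cluster.converged,
            "excluded_no_baseline": ap.excluded_no_baseline,
        }
        (adir / "metadata.json").write_text(json.dumps(meta, indent=2))
        # malnutrition tables on the approach's z-scores
        cohort = cohorts[ap.spec.ga_corrected]
        flags = malnutrition_table(cohort, MalnutritionCutoffs())
        mal = malnutrition_by_pattern(flags, ap.labels)
        mal.to_csv(adir / "malnutrition_by_pattern.csv", index=False, float_format="%.6g")
    for index, table in result.mobility_tables.items():
        table.to_csv(out / f"mobility_{index}.csv", index=False, float_format="%.6g")


def verify_manifest(manifest: Mapping, cohort_path, lms_path, config: Mapping) -> bool:
    """True when the recorded input/config hashes match the given inputs."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    return (
        manifest["inputs"]["cohort_sha256"] == _file_sha256(cohort_path)
        and manifest["inputs"]["lms_sha256"] == _file_sha256(lms_path)
        and manifest["config_sha256"] == config_hash(cfg)
    )
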