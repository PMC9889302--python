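"""Per-child linear growth features, between-pattern tests, malnutrition
classification and cross-approach mobility.

Features come from an ordinary least-squares line fitted to a child's
observed (age, z) points: the intercept (z at age 0), the slope (z per
month, the overall growth rate) and the tempo — the time-average of the
fitted line from birth to the child's last observed age T, i.e. the area
under the line divided by T, which for a line closes to
intercept + slope·T/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class FeatureSet:
    intercept: float  # z at age 0
    slope: float      # z per month
    tempo: float      # time-average of the fitted line over [0, T]


def linear_features(t, z) -> FeatureSet:
    """OLS line over the observed points of one trajectory.

    Requires at least 2 non-missing points; with exactly 2 the line passes
    through both.
    """
    t = np.asarray(t, float)
    z = np.asarray(z, float)
    keep = np.isfinite(t) & np.isfinite(z)
    t, z = t[keep], z[keep]
    if t.size < 2:
        raise ValueError("need at least 2 observed points for linear features")
    slope, intercept = np.polyfit(t, z, 1)
    T = float(t.max())
    tempo = intercept + slope * T / 2.0
    return FeatureSet(intercept=float(intercept), slope=float(slope), tempo=float(tempo))


def features_table(
    trajs: Mapping[str, tuple], labels: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Feature rows for many children; children with <2 points are skipped
    (their ids recorded in ``df.attrs['skipped']``)."""
    rows, skipped = [], []
    for cid, (t, z) in trajs.items():
        try:
            f = linear_features(t, z)
        except ValueError:
            skipped.append(cid)
            continue
        row = {"child_id": cid, "intercept": f.intercept, "slope": f.slope, "tempo": f.tempo}
        if labels is not None:
            row["pattern"] = labels.get(cid)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    return df


def dunn_test(groups: Sequence[np.ndarray], p_adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − ΣT/(12(N−1))]·(1/n_i + 1/n_j)),
    ΣT = Σ(t³ − t) over tied groups; two-sided normal p-values, adjusted
    with Holm by default ("bonferroni" and "none" also accepted).
    """
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)

    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_factor * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        zval = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(zval))
        rows.append({"group_a": i, "group_b": j, "z": zval, "p_raw": p})
    df = pd.DataFrame(rows)
    if p_adjust == "none" or df.empty:
        df["p_adj"] = df.get("p_raw")
    else:
        df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method=p_adjust)[1]
    return df


def compare_features(
    features: pd.DataFrame,
    label_col: str = "pattern",
    feature_cols: Sequence[str] = ("intercept", "slope", "tempo"),
    p_adjust: str = "holm",
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Kruskal–Wallis omnibus + Dunn's pairwise tests per feature.

    Groups with fewer than 2 members are dropped from the comparison and
    listed under ``"skipped_groups"``.
    """
    out: dict[str, dict] = {}
    sizes = features[label_col].value_counts()
    valid = sorted(sizes[sizes >= 2].index)
    skipped = sorted(sizes[sizes < 2].index)
    if len(valid) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    for feat in feature_cols:
        groups = [
            features.loc[features[label_col] == g, feat].dropna().to_numpy()
            for g in valid
        ]
        H, p = stats.kruskal(*groups)
        dunn = dunn_test(groups, p_adjust=p_adjust)
        dunn["group_a"] = dunn["group_a"].map(dict(enumerate(valid)))
        dunn["group_b"] = dunn["group_b"].map(dict(enumerate(valid)))
        dunn["significant"] = dunn["p_adj"] < alpha
        out[feat] = {
            "kw_h": float(H),
            "kw_p": float(p),
            "significant": bool(p < alpha),
            "dunn": dunn,
            "skipped_groups": skipped,
        }
    return out


@dataclass(frozen=True)
class MalnutritionCutoffs:
    """Strict-inequality cutoffs on z-scores."""

    stunting: float = -2.0      # HAZ below
    underweight: float = -2.0   # WAZ below
    wasting: float = -2.0       # BMIZ below
    overweight: float = 2.0     # BMIZ above
    obesity: float = 3.0        # BMIZ above


def malnutrition_flags(
    z: Mapping[str, float], cutoffs: MalnutritionCutoffs = MalnutritionCutoffs()
) -> set[str]:
    """Categories for one visit's z-scores (NaN/absent index → no flag).

    Overweight and obesity are reported as mutually exclusive tiers:
    BMIZ > 3 is 'obesity', 2 < BMIZ ≤ 3 is 'overweight'.
    """
    flags: set[str] = set()
    haz = z.get("HAZ", np.nan)
    waz = z.get("WAZ", np.nan)
    bmiz = z.get("BMIZ", np.nan)
    if np.isfinite(haz) and haz < cutoffs.stunting:
        flags.add("stunted")
    if np.isfinite(waz) and waz < cutoffs.underweight:
        flags.add("underweight")
    if np.isfinite(bmiz):
        if bmiz < cutoffs.wasting:
            flags.add("wasted")
        elif bmiz > cutoffs.obesity:
            flags.add("obesity")
        elif bmiz > cutoffs.overweight:
            flags.add("overweight")
    return flags


CATEGORIES = ("stunted", "underweight", "wasted", "overweight", "obesity")


def malnutrition_table(
    cohort, cutoffs: MalnutritionCutoffs = MalnutritionCutoffs(), include_birth: bool = False
) -> pd.DataFrame:
    """Long table (child_id, visit_tag, category flags); prevalence is
    reported from the 3-month visit onward unless ``include_birth``."""
    rows = []
    for child in cohort:
        for v in child.visits:
            if v.visit_tag == "birth" and not include_birth:
                continue
            flags = malnutrition_flags(v.z, cutoffs)
            rows.append(
                {"child_id": child.child_id, "visit_tag": v.visit_tag,
                 **{c: c in flags for c in CATEGORIES}}
            )
    return pd.DataFrame(rows)


def chi2_by_pattern(flagged: pd.Series, patterns: pd.Series, warn: bool = True) -> dict:
    """Pearson chi-squared (uncorrected) of a pattern × flagged contingency."""
    table = pd.crosstab(patterns, flagged)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return {"table": table, "chi2": np.nan, "p": np.nan, "low_expected": True}
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    low = bool((expected < 5).any())
    if low and warn:
        warnings.warn("chi-squared expected cell count below 5", stacklevel=2)
    return {"table": table, "chi2": float(chi2), "p": float(p), "low_expected": low}


def malnutrition_by_pattern(
    flags: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per visit and category: pattern-wise counts and the chi-squared test
    of category proportion across patterns. Children without a pattern
    label are excluded (with a warning)."""
    flags = flags.copy()
    flags["pattern"] = flags["child_id"].map(labels)
    unlabeled = flags["pattern"].isna()
    if unlabeled.any():
        warnings.warn(f"{unlabeled.sum()} visit rows without a pattern label excluded")
        flags = flags[~unlabeled]
    rows = []
    n_low = 0
    for visit, sub in flags.groupby("visit_tag", sort=False):
        for cat in CATEGORIES:
            res = chi2_by_pattern(sub[cat], sub["pattern"], warn=False)
            n_low += res["low_expected"]
            counts = sub.groupby("pattern")[cat].sum().to_dict()
            rows.append(
                {"visit_tag": visit, "category": cat, "chi2": res["chi2"],
                 "p": res["p"], "low_expected": res["low_expected"],
                 **{f"n_{k}": int(v) for k, v in counts.items()}}
            )
    if n_low:
        warnings.warn(
            f"{n_low} visit×category chi-squared tests have expected cells below 5",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


@dataclass
class MobilityTable:
    contingency: pd.DataFrame
    movers: int | None
    movers_fraction: float | None
    ari: float
    n_common: int


def mobility(labels_a: Mapping[str, str], labels_b: Mapping[str, str]) -> MobilityTable:
    """Cross-approach pattern mobility over the common children.

    Pattern names are aligned by name (High↔High, …); movers are the
    off-diagonal counts. When the two labelings use different name sets
    only the adjusted Rand index is reported.
    """
    common = sorted(set(labels_a) & set(labels_b))
    if not common:
        raise ValueError("no overlapping children between the two labelings")
    a = pd.Series([labels_a[c] for c in common], index=common, name="a")
    b = pd.Series([labels_b[c] for c in common], index=common, name="b")
    table = pd.crosstab(a, b)
    ari = float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
    if set(a.unique()) == set(b.unique()):
        names = sorted(set(a.unique()))
        table = table.reindex(index=names, columns=names, fill_value=0)
        movers = int(table.to_numpy().sum() - np.trace(table.to_numpy()))
        frac = movers / len(common)
    else:
        movers, frac = None, None
    return MobilityTable(
        contingency=table, movers=movers, movers_fraction=frac, ari=ari,
        n_common=len(common),
    )
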