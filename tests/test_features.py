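"""Linear trajectory features, rank tests, malnutrition flags and mobility."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from growthshape.features import (
    MalnutritionCutoffs,
    chi2_by_pattern,
    compare_features,
    dunn_test,
    features_table,
    linear_features,
    malnutrition_flags,
    mobility,
)


def ols_oracle(t, z):
    """Independent least-squares solve via the normal equations."""
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ z)
    return beta  # (intercept, slope)


class TestLinearFeatures:
    def test_constant_trajectory(self):
        f = linear_features([0, 6, 12], [0.7, 0.7, 0.7])
        assert (f.intercept, f.slope, f.tempo) == (
            pytest.approx(0.7), pytest.approx(0.0, abs=1e-12), pytest.approx(0.7))

    def test_exact_line(self):
        t = np.array([0.0, 5.0, 10.0])
        f = linear_features(t, 1.0 + 0.1 * t)
        assert f.intercept == pytest.approx(1.0)
        assert f.slope == pytest.approx(0.1)
        assert f.tempo == pytest.approx(1.5)  # mean of the line over [0, 10]

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 132, 7))
        z = 0.3 - 0.004 * t + rng.normal(0, 0.2, 7)
        f = linear_features(t, z)
        b0, b1 = ols_oracle(t, z)
        assert f.intercept == pytest.approx(b0, abs=1e-10)
        assert f.slope == pytest.approx(b1, abs=1e-10)

    def test_tempo_equals_trapezoid_of_fitted_line(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 132, 7))
        z = rng.normal(size=7)
        f = linear_features(t, z)
        grid = np.linspace(0, t.max(), 100001)
        auc = np.trapezoid(f.intercept + f.slope * grid, grid) / t.max()
        assert f.tempo == pytest.approx(auc, abs=1e-12)

    def test_two_points_fit_passes_through_both(self):
        f = linear_features([2.0, 10.0], [0.5, -0.3])
        assert f.intercept + f.slope * 2.0 == pytest.approx(0.5)
        assert f.intercept + f.slope * 10.0 == pytest.approx(-0.3)

    def test_missing_points_dropped_and_minimum_enforced(self):
        with pytest.raises(ValueError):
            linear_features([0, 3, 12], [0.1, np.nan, np.nan])

    def test_features_table_skips_short_trajectories(self):
        trajs = {"a": ([0, 3, 12], [0, 0.1, 0.2]), "b": ([0], [0.5])}
        df = features_table(trajs)
        assert list(df["child_id"]) == ["a"]
        assert df.attrs["skipped"] == ["b"]


class TestCompareFeatures:
    @staticmethod
    def frame(groups):
        rows = []
        for name, values in groups.items():
            rows += [{"pattern": name, "intercept": v, "slope": v, "tempo": v}
                     for v in values]
        return pd.DataFrame(rows)

    def test_identical_groups_dunn_z_zero(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = dunn_test([g, g.copy()])
        assert res["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(0)
        a, b, c = rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(3, 1, 30)
        out = compare_features(self.frame({"High": c, "Middle": a, "Low": b}))
        assert out["intercept"]["kw_p"] < 1e-6
        dunn = out["intercept"]["dunn"]
        hm = dunn[(dunn["group_a"] == "High") | (dunn["group_b"] == "High")]
        assert (hm["p_adj"] < 0.05).all()

    def test_small_groups_skipped(self):
        rng = np.random.default_rng(1)
        out = compare_features(self.frame({
            "High": rng.normal(size=10), "Middle": rng.normal(size=10), "Low": [1.0],
        }))
        assert out["slope"]["skipped_groups"] == ["Low"]
        assert {"High", "Middle"} == set(
            out["slope"]["dunn"][["group_a", "group_b"]].to_numpy().ravel())

    def test_dunn_consistent_with_kruskal_under_null(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=25) for _ in range(3)]
        res = dunn_test(groups, p_adjust="none")
        _, kw_p = stats.kruskal(*groups)
        # no pairwise difference should be wildly more significant than the omnibus
        assert res["p_raw"].min() > kw_p / 50


class TestMalnutrition:
    def test_boundary_is_strict(self):
        assert malnutrition_flags({"HAZ": -2.0}) == set()
        assert malnutrition_flags({"HAZ": -2.5}) == {"stunted"}

    def test_overweight_obesity_tiering(self):
        assert malnutrition_flags({"BMIZ": 3.5}) == {"obesity"}
        assert malnutrition_flags({"BMIZ": 2.5}) == {"overweight"}
        assert malnutrition_flags({"BMIZ": 3.0}) == {"overweight"}

    def test_all_categories(self):
        flags = malnutrition_flags({"HAZ": -2.1, "WAZ": -2.2, "BMIZ": -2.3})
        assert flags == {"stunted", "underweight", "wasted"}

    def test_missing_index_never_flags(self):
        assert malnutrition_flags({"HAZ": float("nan")}) == set()


class TestChiSquared:
    def test_two_by_two_closed_form(self):
        # table (10, 20 / 30, 40): Pearson statistic 4*(1/12+1/18+1/28+1/42)
        flagged = pd.Series([True] * 10 + [False] * 20 + [True] * 30 + [False] * 40)
        patterns = pd.Series(["A"] * 30 + ["B"] * 70)
        res = chi2_by_pattern(flagged, patterns)
        assert res["chi2"] == pytest.approx(0.7936508, abs=1e-6)
        # with Yates continuity correction the same table gives 0.4464
        chi2_yates = stats.chi2_contingency(
            res["table"].to_numpy(), correction=True)[0]
        assert chi2_yates == pytest.approx(0.4464286, abs=1e-6)

    def test_uniform_proportions_p_near_one(self):
        flagged = pd.Series([True, False] * 50)
        patterns = pd.Series(["A"] * 50 + ["B"] * 50)
        assert chi2_by_pattern(flagged, patterns)["p"] == pytest.approx(1.0)

    def test_low_expected_cell_warns(self):
        flagged = pd.Series([True] * 2 + [False] * 48 + [False] * 50)
        patterns = pd.Series(["A"] * 50 + ["B"] * 50)
        with pytest.warns(UserWarning, match="expected cell"):
            res = chi2_by_pattern(flagged, patterns)
        assert res["low_expected"]

    def test_invariant_to_category_permutation(self):
        rng = np.random.default_rng(0)
        flagged = pd.Series(rng.random(200) < 0.3)
        patterns = pd.Series(rng.choice(list("ABC"), 200))
        base = chi2_by_pattern(flagged, patterns)["chi2"]
        relabel = patterns.map({"A": "C", "B": "A", "C": "B"})
        assert chi2_by_pattern(flagged, relabel)["chi2"] == pytest.approx(base)


def ari_pair_counting(a, b):
    """ARI via exhaustive pair enumeration (independent of sklearn)."""
    keys = sorted(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(keys, 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        n11 += sa and sb
        n00 += (not sa) and (not sb)
        n10 += sa and not sb
        n01 += (not sa) and sb
    num = 2.0 * (n00 * n11 - n01 * n10)
    den = (n00 + n01) * (n01 + n11) + (n00 + n10) * (n10 + n11)
    return num / den if den else 1.0


class TestMobility:
    def test_identical_labelings(self):
        labels = {f"c{i}": p for i, p in enumerate(["High", "Middle", "Low"] * 4)}
        m = mobility(labels, dict(labels))
        assert m.ari == pytest.approx(1.0)
        assert m.movers == 0 and m.movers_fraction == 0.0

    def test_random_relabeling_ari_near_zero(self):
        rng = np.random.default_rng(0)
        ids = [f"c{i}" for i in range(1000)]
        pats = rng.choice(["High", "Middle", "Low"], 1000, p=[0.25, 0.5, 0.25])
        a = dict(zip(ids, pats))
        b = dict(zip(ids, rng.permutation(pats)))
        assert abs(mobility(a, b).ari) < 0.05

    def test_six_child_example_matches_pair_counting_oracle(self):
        a = {"1": "High", "2": "High", "3": "Middle", "4": "Middle", "5": "Low", "6": "Low"}
        b = {"1": "High", "2": "Middle", "3": "Middle", "4": "Low", "5": "Low", "6": "Low"}
        m = mobility(a, b)
        assert m.ari == pytest.approx(ari_pair_counting(a, b), abs=1e-12)
        assert m.movers == 2 and m.n_common == 6

    def test_invariant_to_pattern_name_permutation(self):
        a = {"1": "High", "2": "Middle", "3": "Low", "4": "High", "5": "Middle"}
        swap = {"High": "Low", "Middle": "High", "Low": "Middle"}
        b = {k: swap[v] for k, v in a.items()}
        assert mobility(a, b).ari == pytest.approx(mobility(a, a).ari)

    def test_differing_name_sets_report_only_ari(self):
        a = {"1": "High", "2": "Low", "3": "High", "4": "Low"}
        b = {"1": "C1", "2": "C2", "3": "C1", "4": "C2"}
        m = mobility(a, b)
        assert m.movers is None and m.ari == pytest.approx(1.0)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            mobility({"1": "High"}, {"2": "Low"})
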