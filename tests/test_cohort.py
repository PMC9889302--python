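"""Cohort I/O, age scales, baseline centering and the exclusion cascade."""

import numpy as np
import pytest

from growthshape.cohort import (
    CenteringConfig,
    ChildTrajectory,
    CohortFormatError,
    ExclusionConfig,
    MissingBaselineError,
    VisitRecord,
    baseline_center,
    exclusion_cascade,
    ga_corrected_age,
    read_cohort_long,
    write_cohort_long,
)

COHORT_CSV = """child_id,sex,ga_weeks,visit_tag,age_days,weight_kg,length_cm
a1,F,40,birth,0,3.2,49
a1,F,40,m3,91,6.1,60
a1,F,40,m12,365,9.5,74
b2,M,35,birth,0,2.4,45
b2,M,35,m3,91,5.2,57
b2,M,35,m12,370,,73
"""


@pytest.fixture
def cohort_file(tmp_path):
    p = tmp_path / "cohort.csv"
    p.write_text(COHORT_CSV)
    return p


class TestIO:
    def test_grouping_and_sorting(self, cohort_file):
        cohort = read_cohort_long(cohort_file)
        assert [c.child_id for c in cohort] == ["a1", "b2"]
        assert all(len(c.visits) == 3 for c in cohort)

    def test_blank_weight_means_missing_and_no_bmi(self, cohort_file):
        b2 = read_cohort_long(cohort_file)[1]
        m12 = b2.visit("m12")
        assert m12.weight is None and m12.bmi is None
        assert m12.length_height == 73

    def test_bmi_derived_when_both_present(self, cohort_file):
        a1 = read_cohort_long(cohort_file)[0]
        birth = a1.visit("birth")
        assert birth.bmi == pytest.approx(3.2 / 0.49**2)

    def test_preterm_threshold(self, cohort_file):
        a1, b2 = read_cohort_long(cohort_file)
        assert not a1.preterm and b2.preterm

    def test_roundtrip_through_write(self, cohort_file, tmp_path):
        cohort = read_cohort_long(cohort_file)
        out = tmp_path / "again.csv"
        write_cohort_long(cohort, out)
        again = read_cohort_long(out)
        for c1, c2 in zip(cohort, again):
            assert c1.child_id == c2.child_id and c1.ga_days == c2.ga_days
            for v1, v2 in zip(c1.visits, c2.visits):
                assert v1.visit_tag == v2.visit_tag
                assert v1.weight == v2.weight and v1.length_height == v2.length_height

    def test_duplicate_visit_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "child_id,sex,ga_weeks,visit_tag,age_days,weight_kg,length_cm\n"
            "a,F,40,birth,0,3,49\na,F,40,birth,0,3,49\n"
        )
        with pytest.raises(CohortFormatError, match="duplicate"):
            read_cohort_long(p)

    def test_unknown_visit_tag_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "child_id,sex,ga_weeks,visit_tag,age_days,weight_kg,length_cm\n"
            "a,F,40,m7,200,3,49\n"
        )
        with pytest.raises(CohortFormatError, match="visit_tag"):
            read_cohort_long(p)


class TestGACorrection:
    @pytest.mark.parametrize(
        "ga_days, age_days, expected",
        [
            (245, 90, 55),    # 35 wk preterm: 90 - (280 - 245)
            (280, 90, 90),    # full term unchanged
            (266, 90, 90),    # 38 wk term: not corrected by default
        ],
    )
    def test_correction(self, ga_days, age_days, expected):
        assert ga_corrected_age(age_days, ga_days) == expected

    def test_apply_to_term(self):
        assert ga_corrected_age(90, 266, apply_to_term=True) == 76

    def test_identity_for_term_over_grid(self):
        for ga in range(259, 316, 7):
            assert ga_corrected_age(123.0, ga) == 123.0


class TestCentering:
    def test_birth_minus_two_leaves_residual_0_004(self):
        centered = baseline_center([-2.0, -1.0, 0.0])
        assert centered[0] == pytest.approx(0.004)

    def test_zero_birth_z_is_identity(self):
        z = [0.0, 0.7, 1.1]
        np.testing.assert_allclose(baseline_center(z), z)

    def test_worked_series(self):
        np.testing.assert_allclose(
            baseline_center([1.0, 2.0, 3.0]), [-0.002, 0.998, 1.998]
        )

    def test_shape_preserved_exactly(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=7)
        c = baseline_center(z)
        np.testing.assert_allclose(np.diff(c), np.diff(z), rtol=0, atol=1e-12)

    def test_missing_birth_z_signalled(self):
        with pytest.raises(MissingBaselineError):
            baseline_center([float("nan"), 1.0, 2.0])

    def test_disabled_config_passthrough(self):
        z = [1.0, 2.0]
        np.testing.assert_array_equal(
            baseline_center(z, CenteringConfig(enabled=False)), z
        )


def make_child(child_id, ga_days=280.0, n_followups=6, haz_obs=7, ga_conflict=False):
    """A healthy term child with 7 visits; HAZ observed at the first
    ``haz_obs`` visits, WAZ/BMIZ everywhere."""
    ages = [0, 91, 365, 730, 1461, 2483, 4018]
    tags = ["birth", "m3", "m12", "m24", "m48", "y6", "y11"]
    visits = []
    for i, (tag, age) in enumerate(zip(tags, ages)):
        if tag != "birth" and i > n_followups:
            continue
        v = VisitRecord(tag, age, weight=3.0 + i, length_height=49.0 + 5 * i)
        v.z = {
            "HAZ": 0.1 if i < haz_obs else float("nan"),
            "WAZ": 0.2,
            "BMIZ": 0.0,
        }
        visits.append(v)
    return ChildTrajectory(child_id, "F", ga_days, visits, ga_conflict=ga_conflict)


class TestExclusionCascade:
    def test_clean_cohort_fully_retained(self):
        cohort = [make_child(f"c{i}") for i in range(5)]
        kept, report = exclusion_cascade(cohort)
        assert report.retained == 5
        assert all(v == 0 for v in report.counts.values())

    def test_reasons_applied_in_order_once_each(self):
        cohort = [
            make_child("ok"),
            make_child("noga", ga_days=None),
            make_child("conflict", ga_conflict=True),
            make_child("shortga", ga_days=140.0),
        ]
        # a child failing several rules counts at its first triggering reason
        cohort[1].visits[0].weight = None
        kept, report = exclusion_cascade(cohort)
        assert report.counts["missing_discordant_ga"] == 3
        assert report.counts["implausible_birth_anthro"] == 0
        assert report.retained == 1

    def test_implausible_birth_anthropometry(self):
        bad_w = make_child("w")
        bad_w.visits[0].weight = 0.1
        bad_l = make_child("l")
        bad_l.visits[0].length_height = 20.0
        kept, report = exclusion_cascade([make_child("ok"), bad_w, bad_l])
        assert report.counts["implausible_birth_anthro"] == 2

    def test_single_followup_excluded(self):
        c = make_child("single", n_followups=1)
        assert len(c.visits) == 2
        _, report = exclusion_cascade([c])
        assert report.counts["single_followup"] == 1

    def test_either_index_below_min_obs_excludes(self):
        # 2 HAZ observations but plenty of WAZ: still excluded
        c = make_child("sparse", haz_obs=2)
        _, report = exclusion_cascade([c])
        assert report.counts["under3_observations"] == 1

    def test_totals_reconcile(self):
        cohort = [make_child("a"), make_child("b", ga_days=None), make_child("c", haz_obs=1)]
        kept, report = exclusion_cascade(cohort)
        assert report.total == len(cohort)
        assert report.retained == len(kept)

    def test_cascade_is_stable_on_its_own_output(self):
        cohort = [
            make_child("a"), make_child("b", ga_days=None),
            make_child("c", n_followups=1), make_child("d", haz_obs=2),
        ]
        kept, _ = exclusion_cascade(cohort)
        kept2, report2 = exclusion_cascade(kept)
        assert len(kept2) == len(kept)
        assert all(v == 0 for v in report2.counts.values())

    def test_min_obs_configurable(self):
        c = make_child("c", haz_obs=3)
        _, r_default = exclusion_cascade([c])
        assert r_default.retained == 1
        _, r_strict = exclusion_cascade([c], ExclusionConfig(min_obs=4))
        assert r_strict.counts["under3_observations"] == 1
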