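"""CVH scoring: categorization, normalization, what-if recalculation."""

import itertools
import json

import pytest

from cvhrx import (
    Category,
    CVHScore,
    Factor,
    RiskFactorValue,
    WillingnessProfile,
    categorize_factor,
    compute_cvh_score,
    what_if,
)
from cvhrx.scoring import ConfigError, CutpointTable, EmptyProfileError, POINTS
from conftest import VALUES_BY_CATEGORY, profile_with


@pytest.mark.parametrize(
    "factor, value, expected",
    [
        (Factor.smoking, "never", Category.ideal),
        (Factor.smoking, "former", Category.intermediate),
        (Factor.smoking, "current", Category.poor),
        (Factor.physical_activity, 420, Category.ideal),
        (Factor.physical_activity, 419, Category.intermediate),
        (Factor.physical_activity, 0, Category.poor),
        (Factor.bmi_percentile, 96, Category.poor),
        (Factor.bmi_percentile, 85, Category.intermediate),
        (Factor.bmi_percentile, 84.9, Category.ideal),
        (Factor.cholesterol, 170, Category.intermediate),
        (Factor.cholesterol, 199.9, Category.intermediate),
        (Factor.cholesterol, 200, Category.poor),
        (Factor.glucose, 99, Category.ideal),
        (Factor.diet, 4, Category.ideal),
        (Factor.diet, 2, Category.intermediate),
        (Factor.diet, 1, Category.poor),
        # blood pressure: the worse of the two components wins
        (Factor.blood_pressure, (110, 70), Category.ideal),
        (Factor.blood_pressure, (110, 85), Category.intermediate),
        (Factor.blood_pressure, (145, 70), Category.poor),
    ],
)
def test_categorize_factor_boundaries(cutpoints, factor, value, expected):
    a = categorize_factor(RiskFactorValue(factor, value=value), cutpoints)
    assert a.category == expected
    assert a.points == POINTS[expected]
    assert a.color == {"ideal": "green", "intermediate": "yellow", "poor": "red"}[expected.value]


def test_unavailable_factor_is_excluded_signal(cutpoints):
    with pytest.raises(EmptyProfileError):
        categorize_factor(RiskFactorValue(Factor.diet, available=False), cutpoints)


def test_unknown_factor_id_is_config_error():
    with pytest.raises(ValueError):
        RiskFactorValue("triglycerides", value=100)


def test_unknown_smoking_value_is_config_error(cutpoints):
    with pytest.raises(ConfigError):
        categorize_factor(RiskFactorValue(Factor.smoking, value="sometimes"), cutpoints)


def test_cutpoint_table_requires_all_seven_factors():
    with pytest.raises(ConfigError):
        CutpointTable({"diet": {"direction": "higher_is_better", "boundaries": [2, 4]}})


class TestComputeScore:
    def test_all_ideal_is_14_of_14(self, all_ideal_profile, cutpoints):
        s = compute_cvh_score(all_ideal_profile, cutpoints)
        assert (s.total_points, s.max_points, s.score) == (14, 14, 1.0)

    def test_all_poor_is_zero(self, all_poor_profile, cutpoints):
        s = compute_cvh_score(all_poor_profile, cutpoints)
        assert (s.total_points, s.score) == (0, 0.0)

    def test_mixed_profile_arithmetic(self, cutpoints):
        cats = dict.fromkeys(Factor, "ideal")
        cats[Factor.smoking] = "intermediate"
        cats[Factor.diet] = "poor"
        s = compute_cvh_score(profile_with(cats), cutpoints)
        assert s.total_points == 11
        assert s.score == pytest.approx(11 / 14)

    def test_six_factor_renormalization(self, all_ideal_profile, cutpoints):
        # dropping a factor shrinks the denominator: 6 ideal factors still score 1.0
        profile = [fv for fv in all_ideal_profile if fv.factor != Factor.glucose]
        s = compute_cvh_score(profile, cutpoints)
        assert (s.total_points, s.max_points, s.score) == (12, 12, 1.0)

    def test_unavailable_factors_excluded_from_denominator(self, cutpoints):
        profile = profile_with({Factor.diet: "poor", Factor.smoking: "ideal"})
        profile.append(RiskFactorValue(Factor.glucose, available=False))
        s = compute_cvh_score(profile, cutpoints)
        assert s.max_points == 4
        assert s.total_points == 2

    def test_empty_profile_error(self, cutpoints):
        with pytest.raises(EmptyProfileError):
            compute_cvh_score([RiskFactorValue(Factor.diet, available=False)], cutpoints)


def test_exhaustive_category_enumeration(cutpoints):
    """Over all 3^7 category assignments: totals add up, score in [0,1], and
    raising any one factor by one level raises the total by exactly 1."""
    levels = ["poor", "intermediate", "ideal"]
    points_of = {"poor": 0, "intermediate": 1, "ideal": 2}
    factors = list(Factor)
    for combo in itertools.product(range(3), repeat=7):
        expected_T = sum(points_of[levels[i]] for i in combo)
        s = compute_cvh_score(
            profile_with({f: levels[i] for f, i in zip(factors, combo)}), cutpoints
        )
        assert s.total_points == expected_T
        assert s.total_points == sum(a.points for a in s.assessments)
        assert 0.0 <= s.score <= 1.0
        # single-level monotonicity, checked arithmetically against the oracle
        for j, lvl in enumerate(combo):
            if lvl < 2:
                bumped = sum(
                    points_of[levels[i if k != j else i + 1]]
                    for k, i in enumerate(combo)
                )
                assert bumped == expected_T + 1


class TestWhatIf:
    def test_slider_improvement_from_all_poor(self, all_poor_profile, cutpoints):
        s = what_if(all_poor_profile, Factor.physical_activity, 450, cutpoints)
        assert s.total_points == 2
        assert s.score == pytest.approx(2 / 14)

    def test_identity_when_value_unchanged(self, all_ideal_profile, cutpoints):
        base = compute_cvh_score(all_ideal_profile, cutpoints)
        same = what_if(
            all_ideal_profile, Factor.diet, VALUES_BY_CATEGORY["ideal"][Factor.diet], cutpoints
        )
        assert same == base

    def test_profile_not_mutated(self, all_poor_profile, cutpoints):
        before = json.dumps([(fv.factor.value, str(fv.value)) for fv in all_poor_profile])
        what_if(all_poor_profile, Factor.smoking, "never", cutpoints)
        after = json.dumps([(fv.factor.value, str(fv.value)) for fv in all_poor_profile])
        assert before == after

    def test_only_named_factor_changes(self, all_poor_profile, cutpoints):
        base = compute_cvh_score(all_poor_profile, cutpoints)
        new = what_if(all_poor_profile, Factor.glucose, 90, cutpoints)
        diffs = [
            (a.factor, a.category, b.category)
            for a, b in zip(base.assessments, new.assessments)
            if a.category != b.category
        ]
        assert [d[0] for d in diffs] == [Factor.glucose]

    def test_unknown_factor_rejected(self, all_poor_profile, cutpoints):
        with pytest.raises(KeyError):
            what_if(all_poor_profile[:3], Factor.diet, 5, cutpoints)


def test_willingness_profile_validation():
    WillingnessProfile(pa_willingness=5, diet_willingness=1)
    with pytest.raises(ValueError):
        WillingnessProfile(pa_willingness=0, diet_willingness=3)
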