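"""Prescription engine: activity plans, progression, stoplight-diet logic."""

import itertools

import pytest
import yaml

from cvhrx import (
    ActivityStatus,
    DietBehavior,
    DietSurvey,
    IntensityClass,
    PADoseMatrix,
    ProgressionConfig,
    classify_activity_status,
    classify_intensity,
    default_activity_menu,
    default_dose_matrix,
    default_food_lists,
    flag_problem_behaviors,
    generate_diet_recs,
    generate_pa_plan,
)
from cvhrx.prescriptions import DIET_SCREENER_ITEMS, ConfigError


@pytest.mark.parametrize(
    "mvpa, expected",
    [
        (0, ActivityStatus.inactive),
        (1, ActivityStatus.somewhat_active),
        (149, ActivityStatus.somewhat_active),
        (150, ActivityStatus.moderately_active),
        (299, ActivityStatus.moderately_active),
        (300, ActivityStatus.active),
        (1000, ActivityStatus.active),
    ],
)
def test_activity_status_thresholds(mvpa, expected):
    assert classify_activity_status(mvpa) == expected


def test_activity_status_rejects_negative():
    with pytest.raises(ValueError):
        classify_activity_status(-1)


@pytest.mark.parametrize(
    "met, expected",
    [
        (2.5, IntensityClass.light),
        (2.99, IntensityClass.light),
        (3.0, IntensityClass.moderate),
        (5.99, IntensityClass.moderate),
        (6.0, IntensityClass.vigorous),
        (6.5, IntensityClass.vigorous),
    ],
)
def test_intensity_bands(met, expected):
    assert classify_intensity(met) == expected


def test_intensity_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_intensity(0)


def test_menu_intensities_consistent_with_met():
    menu = default_activity_menu(exclude_tags=())
    assert menu, "menu must not be empty"
    for act in menu:
        assert act.intensity_class == classify_intensity(act.met)


def test_menu_region_filtering_by_tag():
    full = default_activity_menu(exclude_tags=())
    filtered = default_activity_menu(exclude_tags=("coastal",))
    removed = {a.name for a in full} - {a.name for a in filtered}
    assert removed == {"surfing"}


class TestPAPlan:
    @pytest.fixture
    def two_activities(self):
        return default_activity_menu()[:2]

    def test_default_cell_progression(self, two_activities):
        # 30 min x 3/wk cell, 10%/week, no cap in reach over 4 weeks
        plan = generate_pa_plan(
            "overweight", "inactive",
            progression=ProgressionConfig(horizon_weeks=4, weekly_cap_min_per_week=10_000),
            chosen_activities=two_activities,
        )
        assert plan.weekly_minutes == [90, 99.0, 108.9, 119.8]

    def test_identity_progression(self, two_activities):
        plan = generate_pa_plan(
            "obese", "active",
            progression=ProgressionConfig(weekly_multiplier=1.0, horizon_weeks=6),
            chosen_activities=two_activities,
        )
        assert len(set(plan.weekly_minutes)) == 1

    def test_closed_form_growth_without_cap(self, two_activities):
        cfg = ProgressionConfig(horizon_weeks=10, weekly_cap_min_per_week=1e9)
        plan = generate_pa_plan("severe_obese", "inactive", progression=cfg,
                                chosen_activities=two_activities)
        d1 = plan.weekly_minutes[0]
        r = cfg.weekly_multiplier
        for w, d in enumerate(plan.weekly_minutes, start=1):
            # each week rounds to 0.1 min and earlier roundings compound by r
            rounding_bound = 0.05 * (r ** (w - 1) - 1) / (r - 1) + 0.05
            assert d == pytest.approx(d1 * r ** (w - 1), abs=rounding_bound)

    def test_goals_nondecreasing_and_capped(self, two_activities):
        cfg = ProgressionConfig(horizon_weeks=30, weekly_cap_min_per_week=420)
        plan = generate_pa_plan("overweight", "active", progression=cfg,
                                chosen_activities=two_activities)
        mins = plan.weekly_minutes
        assert all(b >= a for a, b in zip(mins, mins[1:]))
        assert all(m <= 420 for m in mins)
        assert mins[-1] == 420  # long horizon reaches the cap

    def test_severe_obese_inactive_starts_lower(self, two_activities):
        p_so = generate_pa_plan("severe_obese", "inactive", chosen_activities=two_activities)
        p_ow = generate_pa_plan("overweight", "inactive", chosen_activities=two_activities)
        assert p_so.weekly_minutes[0] < p_ow.weekly_minutes[0]

    def test_empty_activity_selection_rejected(self):
        with pytest.raises(ValueError, match="patient picks"):
            generate_pa_plan("obese", "inactive", chosen_activities=[])

    def test_selected_activities_recorded_verbatim(self, two_activities):
        plan = generate_pa_plan("obese", "inactive", chosen_activities=two_activities)
        assert list(plan.selected_activities) == list(two_activities)


class TestDoseMatrix:
    def test_default_satisfies_ordering(self):
        m = default_dose_matrix()
        so = m.cell("severe_obese", "inactive")
        ow = m.cell("overweight", "inactive")
        assert so.minutes_per_session < ow.minutes_per_session
        assert so.sessions_per_week <= ow.sessions_per_week

    def test_all_twelve_cells_positive(self):
        m = default_dose_matrix()
        for tier in ("overweight", "obese", "severe_obese"):
            for status in ActivityStatus:
                cell = m.cell(tier, status)
                assert cell.minutes_per_session > 0 and cell.sessions_per_week > 0

    def test_loader_rejects_ordering_violation(self, tmp_path):
        import yaml as _y

        with open(tmp_path / "bad.yaml", "w") as fh:
            raw = {
                tier: {
                    s.value: {"minutes_per_session": 30, "sessions_per_week": 3,
                              "intensity_target": "moderate"}
                    for s in ActivityStatus
                }
                for tier in ("overweight", "obese", "severe_obese")
            }
            # equal starting minutes violates the strict ordering
            _y.safe_dump(raw, fh)
        with pytest.raises(ConfigError, match="ordering"):
            PADoseMatrix.from_yaml(tmp_path / "bad.yaml")

    def test_loader_rejects_missing_cell(self):
        with pytest.raises(ConfigError):
            PADoseMatrix({"overweight": {}})


def make_survey(problems: set[DietBehavior]) -> DietSurvey:
    answers = {}
    for b in DietBehavior:
        healthy = DIET_SCREENER_ITEMS[b]["healthy_answer"]
        answers[b] = (not healthy) if b in problems else healthy
    return DietSurvey(answers)


class TestDietLogic:
    def test_all_healthy_flags_nothing(self):
        assert flag_problem_behaviors(make_survey(set())) == set()

    def test_vegetable_no_flags_vegetable(self):
        # "Do you eat 2 or more vegetables a day?" answered no
        assert flag_problem_behaviors(make_survey({DietBehavior.vegetable})) == {
            DietBehavior.vegetable
        }

    def test_all_unhealthy_flags_all_five(self):
        assert flag_problem_behaviors(make_survey(set(DietBehavior))) == set(DietBehavior)

    def test_missing_item_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            DietSurvey({DietBehavior.fruit: True})

    def test_rec_count_equals_flag_count_exhaustive(self):
        behaviors = list(DietBehavior)
        for mask in itertools.product([False, True], repeat=5):
            problems = {b for b, m in zip(behaviors, mask) if m}
            recs = generate_diet_recs(flag_problem_behaviors(make_survey(problems)))
            assert len(recs) == len(problems)
            assert {r.behavior for r in recs} == problems

    def test_recs_carry_three_tiers(self):
        recs = generate_diet_recs(set(DietBehavior))
        for rec in recs:
            assert set(rec.food_lists) == {"green", "yellow", "red"}
            assert all(rec.food_lists[t] for t in ("green", "yellow", "red"))

    def test_max_behaviors_limits_in_survey_order(self):
        recs = generate_diet_recs(set(DietBehavior), max_behaviors=2)
        assert [r.behavior for r in recs] == [DietBehavior.fruit, DietBehavior.vegetable]

    def test_missing_library_entry_is_config_error(self):
        library = {k: v for k, v in default_food_lists().items() if k != "ssb"}
        with pytest.raises(ConfigError, match="ssb"):
            generate_diet_recs({DietBehavior.ssb}, food_list_library=library)

    def test_healthy_component_count_feeds_diet_factor(self):
        assert make_survey(set()).healthy_component_count() == 5
        assert make_survey(set(DietBehavior)).healthy_component_count() == 0
        assert make_survey({DietBehavior.ssb, DietBehavior.fruit}).healthy_component_count() == 3
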