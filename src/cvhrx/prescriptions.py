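"""Tailored behavior-change prescriptions: progressive activity plans and
stoplight-diet recommendations.

The physical-activity plan starts from a dose matrix keyed by the patient's
obesity level (overweight / obese / severely obese) and current activity
status (inactive / somewhat active / moderately active / active): heavier,
less active patients begin with shorter sessions and fewer of them. The
weekly minute goal then ramps geometrically — 10% per week by default —
until it reaches a cap (420 min/week, the 60 min/day youth guideline).
Patients pick the activities they enjoy from a MET-rated menu; the choice
is mandatory by design, since autonomy drives adherence.

Diet recommendations follow the stoplight (traffic-light) framework over
five key eating behaviors — fruit, vegetables, whole grains, sugar-sweetened
beverages and snacking. A behavior gets a recommendation only when the
screener flags it as a problem; each recommendation carries green
"anytime", yellow "sometimes" and red "rarely" food lists.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ActivityStatus",
    "IntensityClass",
    "DietBehavior",
    "Activity",
    "PADoseMatrix",
    "ProgressionConfig",
    "PAPlan",
    "DietSurvey",
    "DietRecommendation",
    "classify_activity_status",
    "classify_intensity",
    "generate_pa_plan",
    "flag_problem_behaviors",
    "generate_diet_recs",
    "load_activity_menu",
    "default_activity_menu",
    "default_dose_matrix",
    "default_food_lists",
    "DIET_SCREENER_ITEMS",
]


class ConfigError(ValueError):
    pass


class ActivityStatus(str, enum.Enum):
    inactive = "inactive"
    somewhat_active = "somewhat_active"
    moderately_active = "moderately_active"
    active = "active"


class IntensityClass(str, enum.Enum):
    light = "light"
    moderate = "moderate"
    vigorous = "vigorous"


class DietBehavior(str, enum.Enum):
    fruit = "fruit"
    vegetable = "vegetable"
    whole_grains = "whole_grains"
    ssb = "ssb"
    snacking = "snacking"


# Screener items: question text and the answer that counts as healthy.
DIET_SCREENER_ITEMS: dict[DietBehavior, dict] = {
    DietBehavior.fruit: {
        "question": "Do you eat 2 or more fruits a day?",
        "healthy_answer": True,
    },
    DietBehavior.vegetable: {
        "question": "Do you eat 2 or more vegetables a day?",
        "healthy_answer": True,
    },
    DietBehavior.whole_grains: {
        "question": "Do you usually choose whole grains, like whole-wheat bread or oatmeal?",
        "healthy_answer": True,
    },
    DietBehavior.ssb: {
        "question": "Do you drink soda or other sugary drinks most days?",
        "healthy_answer": False,
    },
    DietBehavior.snacking: {
        "question": "Do you snack on chips, sweets, or candy most days?",
        "healthy_answer": False,
    },
}


def classify_intensity(met: float) -> IntensityClass:
    """Intensity class from a MET value: light <3.0, moderate 3.0-<6.0, vigorous >=6.0."""
    if met <= 0:
        raise ValueError(f"MET must be positive, got {met}")
    if met < 3.0:
        return IntensityClass.light
    return IntensityClass.moderate if met < 6.0 else IntensityClass.vigorous


def classify_activity_status(mvpa_min_per_week: float) -> ActivityStatus:
    """Four-level activity status from weekly MVPA minutes.

    Default thresholds: 0 inactive; 1-149 somewhat active; 150-299
    moderately active; >=300 active (anchored to the 150/300 min/week
    guideline echoes).
    """
    if mvpa_min_per_week < 0:
        raise ValueError(f"MVPA minutes cannot be negative: {mvpa_min_per_week}")
    if mvpa_min_per_week == 0:
        return ActivityStatus.inactive
    if mvpa_min_per_week < 150:
        return ActivityStatus.somewhat_active
    if mvpa_min_per_week < 300:
        return ActivityStatus.moderately_active
    return ActivityStatus.active


@dataclass(frozen=True)
class Activity:
    name: str
    met: float
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.met <= 0:
            raise ValueError(f"{self.name}: MET must be positive")
        object.__setattr__(self, "tags", tuple(self.tags))

    @property
    def intensity_class(self) -> IntensityClass:
        return classify_intensity(self.met)


@dataclass(frozen=True)
class DoseCell:
    minutes_per_session: float
    sessions_per_week: int
    intensity_target: IntensityClass

    def __post_init__(self) -> None:
        if self.minutes_per_session <= 0 or self.sessions_per_week <= 0:
            raise ConfigError("dose cell values must be positive")
        object.__setattr__(self, "intensity_target", IntensityClass(self.intensity_target))

    @property
    def weekly_minutes(self) -> float:
        return self.minutes_per_session * self.sessions_per_week


WEIGHT_TIERS = ("overweight", "obese", "severe_obese")


class PADoseMatrix:
    """Starting dose by (weight status, activity status): 3 x 4 = 12 cells.

    Load-time validation enforces the clinical ordering constraint that the
    severely obese, inactive cell starts with fewer minutes per session —
    and no more sessions — than the overweight, inactive cell.
    """

    def __init__(self, cells: Mapping[str, Mapping[str, Mapping]]):
        self._cells: dict[tuple[str, ActivityStatus], DoseCell] = {}
        for tier in WEIGHT_TIERS:
            if tier not in cells:
                raise ConfigError(f"dose matrix missing weight tier {tier!r}")
            for status in ActivityStatus:
                if status.value not in cells[tier]:
                    raise ConfigError(f"dose matrix missing cell ({tier}, {status.value})")
                self._cells[(tier, status)] = DoseCell(**cells[tier][status.value])
        so = self._cells[("severe_obese", ActivityStatus.inactive)]
        ow = self._cells[("overweight", ActivityStatus.inactive)]
        if not (so.minutes_per_session < ow.minutes_per_session
                and so.sessions_per_week <= ow.sessions_per_week):
            raise ConfigError(
                "dose matrix violates the starting-dose ordering: severely obese "
                "inactive patients start with shorter sessions and no more "
                "weekly sessions than overweight inactive patients"
            )

    def cell(self, weight_status: str, activity_status: ActivityStatus | str) -> DoseCell:
        key = (str(weight_status), ActivityStatus(activity_status))
        if key not in self._cells:
            raise ConfigError(f"no dose cell for {key}")
        return self._cells[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PADoseMatrix":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


@dataclass(frozen=True)
class ProgressionConfig:
    """Geometric weekly ramp: multiplier r > 1 up to a weekly-minute cap."""

    weekly_multiplier: float = 1.10
    horizon_weeks: int = 12
    weekly_cap_min_per_week: float = 420.0

    def __post_init__(self) -> None:
        if self.weekly_multiplier < 1.0:
            raise ConfigError("weekly_multiplier must be >= 1")
        if self.weekly_cap_min_per_week <= 0 or self.horizon_weeks < 1:
            raise ConfigError("cap and horizon must be positive")


@dataclass(frozen=True)
class WeekGoal:
    week: int
    minutes_per_week: float
    sessions_per_week: int


@dataclass(frozen=True)
class PAPlan:
    weight_status: str
    activity_status: ActivityStatus
    intensity_target: IntensityClass
    weeks: tuple[WeekGoal, ...]
    selected_activities: tuple[Activity, ...]

    @property
    def weekly_minutes(self) -> list[float]:
        return [w.minutes_per_week for w in self.weeks]


def generate_pa_plan(
    weight_status: str,
    activity_status: ActivityStatus | str,
    dose_matrix: PADoseMatrix | None = None,
    progression: ProgressionConfig | None = None,
    chosen_activities: Sequence[Activity] = (),
) -> PAPlan:
    """Build the progressive weekly plan from the dose matrix.

    Week 1 equals minutes x sessions from the matched cell; each later week
    multiplies the previous by the weekly multiplier, rounded to 0.1 min and
    capped. Patient-chosen activities are recorded verbatim and must be
    non-empty: picking activities is the patient's part of the prescription.
    """
    if not chosen_activities:
        raise ValueError("chosen_activities must be non-empty: the patient picks activities")
    dose_matrix = dose_matrix or default_dose_matrix()
    progression = progression or ProgressionConfig()
    status = ActivityStatus(activity_status)
    cell = dose_matrix.cell(weight_status, status)
    cap = progression.weekly_cap_min_per_week
    minutes = min(round(cell.weekly_minutes, 1), cap)
    weeks = []
    for w in range(1, progression.horizon_weeks + 1):
        if w > 1:
            minutes = min(round(minutes * progression.weekly_multiplier, 1), cap)
        weeks.append(WeekGoal(week=w, minutes_per_week=minutes,
                              sessions_per_week=cell.sessions_per_week))
    return PAPlan(
        weight_status=str(weight_status),
        activity_status=status,
        intensity_target=cell.intensity_target,
        weeks=tuple(weeks),
        selected_activities=tuple(chosen_activities),
    )


@dataclass(frozen=True)
class DietSurvey:
    """Answers to the five-item eating-behavior screener (True = "yes")."""

    answers: Mapping[DietBehavior, bool]

    def __post_init__(self) -> None:
        answers = {DietBehavior(k): bool(v) for k, v in dict(self.answers).items()}
        missing = [b.value for b in DietBehavior if b not in answers]
        if missing:
            raise ValueError(f"diet survey missing items: {missing}")
        extra = set(answers) - set(DietBehavior)
        if extra:
            raise ValueError(f"unknown diet survey items: {sorted(extra)}")
        object.__setattr__(self, "answers", answers)

    def healthy_component_count(self) -> int:
        """Number of behaviors meeting the healthy criterion (0-5); feeds the
        diet factor of the CVH score."""
        return sum(
            1
            for b, item in DIET_SCREENER_ITEMS.items()
            if self.answers[b] == item["healthy_answer"]
        )


def flag_problem_behaviors(diet_survey: DietSurvey) -> set[DietBehavior]:
    """Behaviors whose screener answer fails the healthy criterion."""
    return {
        b
        for b, item in DIET_SCREENER_ITEMS.items()
        if diet_survey.answers[b] != item["healthy_answer"]
    }


@dataclass(frozen=True)
class DietRecommendation:
    behavior: DietBehavior
    goal_statement: str
    food_lists: Mapping[str, tuple[str, ...]]  # green / yellow / red

    def __post_init__(self) -> None:
        lists = {k: tuple(v) for k, v in dict(self.food_lists).items()}
        if set(lists) != {"green", "yellow", "red"}:
            raise ConfigError(f"{self.behavior}: food lists must have green/yellow/red tiers")
        object.__setattr__(self, "food_lists", lists)


def generate_diet_recs(
    flags: Iterable[DietBehavior],
    food_list_library: Mapping | None = None,
    max_behaviors: int | None = None,
) -> list[DietRecommendation]:
    """One stoplight recommendation per flagged behavior.

    ``max_behaviors`` optionally limits focus to the first k flagged
    behaviors in screener order, for families who prefer to start small.
    """
    library = food_list_library or default_food_lists()
    flags = {DietBehavior(f) for f in flags}
    ordered = [b for b in DietBehavior if b in flags]  # survey order
    if max_behaviors is not None:
        ordered = ordered[:max_behaviors]
    recs = []
    for behavior in ordered:
        if behavior.value not in library:
            raise ConfigError(f"food-list library has no entry for {behavior.value!r}")
        entry = library[behavior.value]
        recs.append(
            DietRecommendation(
                behavior=behavior,
                goal_statement=entry["goal"],
                food_lists={tier: tuple(entry[tier]) for tier in ("green", "yellow", "red")},
            )
        )
    return recs


def load_activity_menu(path: str | Path, exclude_tags: Iterable[str] = ()) -> list[Activity]:
    """Load the YAML activity menu, dropping activities carrying excluded tags
    (e.g., region filtering of coastal activities)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _build_menu(raw, exclude_tags)


def _build_menu(raw: Sequence[Mapping], exclude_tags: Iterable[str]) -> list[Activity]:
    excl = set(exclude_tags)
    menu = []
    for item in raw:
        act = Activity(name=item["name"], met=float(item["met"]), tags=tuple(item.get("tags", ())))
        if excl & set(act.tags):
            continue
        menu.append(act)
    return menu


def default_activity_menu(exclude_tags: Iterable[str] = ("coastal",)) -> list[Activity]:
    """Bundled menu; coastal-only activities are excluded by default."""
    with resources.files("cvhrx.data").joinpath("activities.yaml").open() as fh:
        return _build_menu(yaml.safe_load(fh), exclude_tags)


def default_dose_matrix() -> PADoseMatrix:
    with resources.files("cvhrx.data").joinpath("dose_matrix.yaml").open() as fh:
        return PADoseMatrix(yaml.safe_load(fh))


def default_food_lists() -> dict:
    with resources.files("cvhrx.data").joinpath("food_lists.yaml").open() as fh:
        return yaml.safe_load(fh)
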