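"""Life's Simple 7 cardiovascular-health (CVH) scoring.

Each of the seven risk factors — BMI percentile, blood pressure, total
cholesterol, fasting glucose, smoking status, physical activity and diet
quality — is rated *ideal* (2 points, green), *intermediate* (1 point,
yellow) or *poor* (0 points, red) against pediatric cut points. Points are
summed and divided by the maximum attainable (2 per available factor; 14
when all seven are present), giving a score in [0, 1].

Cut points are configuration, not constants: the default table ships as
YAML and any factor's boundaries or category map can be overridden. The
``what_if`` operation supports the interactive "slider" use: it rescores a
profile with one factor's value replaced, without mutating the original,
so a clinician can show a patient how a behavior change moves the score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "Factor",
    "Category",
    "RiskFactorValue",
    "FactorAssessment",
    "CVHScore",
    "WillingnessProfile",
    "CutpointTable",
    "default_cutpoints",
    "categorize_factor",
    "compute_cvh_score",
    "what_if",
]


class ConfigError(ValueError):
    pass


class EmptyProfileError(ValueError):
    pass


class Factor(str, enum.Enum):
    bmi_percentile = "bmi_percentile"
    blood_pressure = "blood_pressure"
    cholesterol = "cholesterol"
    glucose = "glucose"
    smoking = "smoking"
    physical_activity = "physical_activity"
    diet = "diet"


class Category(str, enum.Enum):
    ideal = "ideal"
    intermediate = "intermediate"
    poor = "poor"


POINTS = {Category.ideal: 2, Category.intermediate: 1, Category.poor: 0}
COLORS = {Category.ideal: "green", Category.intermediate: "yellow", Category.poor: "red"}


@dataclass(frozen=True)
class RiskFactorValue:
    """One factor's raw value and whether it was measured at this visit."""

    factor: Factor
    value: object = None
    available: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor", Factor(self.factor))
        if self.available and self.value is None:
            raise ValueError(f"{self.factor.value}: available factor requires a value")
        if not self.available and self.value is not None:
            raise ValueError(f"{self.factor.value}: unavailable factor must carry no value")


@dataclass(frozen=True)
class FactorAssessment:
    factor: Factor
    category: Category

    @property
    def points(self) -> int:
        return POINTS[self.category]

    @property
    def color(self) -> str:
        return COLORS[self.category]


@dataclass(frozen=True)
class CVHScore:
    """Per-factor assessments plus the normalized overall score."""

    assessments: tuple[FactorAssessment, ...]

    @property
    def total_points(self) -> int:
        return sum(a.points for a in self.assessments)

    @property
    def max_points(self) -> int:
        return 2 * len(self.assessments)

    @property
    def score(self) -> float:
        return self.total_points / self.max_points


@dataclass(frozen=True)
class WillingnessProfile:
    """Willingness-to-change Likert items (1 = not at all ... 5 = very willing).

    Displayed alongside the profile for the prevention conversation; it does
    not enter the score and does not auto-prioritize recommendations.
    """

    pa_willingness: int
    diet_willingness: int

    def __post_init__(self) -> None:
        for name in ("pa_willingness", "diet_willingness"):
            v = getattr(self, name)
            if not 1 <= int(v) <= 5:
                raise ValueError(f"{name} must be a 1-5 Likert value, got {v}")


def _categorize_scalar(value: float, direction: str, boundaries: Sequence[float]) -> Category:
    lo, hi = boundaries
    if not lo < hi:
        raise ConfigError(f"boundaries must be strictly increasing, got {boundaries}")
    if direction == "lower_is_better":
        if value < lo:
            return Category.ideal
        return Category.intermediate if value < hi else Category.poor
    if direction == "higher_is_better":
        if value < lo:
            return Category.poor
        return Category.intermediate if value < hi else Category.ideal
    raise ConfigError(f"unknown direction {direction!r}")


class CutpointTable:
    """Factor -> cut-point rules, loadable from YAML/JSON-style mappings.

    Three rule kinds: ``scalar`` (direction + two boundaries), ``pair``
    (independent systolic/diastolic scalar rules; the worse component
    determines the category) and ``categorical`` (explicit category map,
    used for smoking with never/former/current).
    """

    def __init__(self, config: Mapping[str, Mapping]):
        self._rules: dict[Factor, dict] = {}
        for key, rule in config.items():
            factor = Factor(key)  # raises for unknown factor ids
            rule = dict(rule)
            kind = rule.get("kind", "scalar")
            if kind == "scalar":
                if "direction" not in rule or "boundaries" not in rule:
                    raise ConfigError(f"{key}: scalar rule requires direction and boundaries")
            elif kind == "pair":
                for comp in ("systolic", "diastolic"):
                    if comp not in rule:
                        raise ConfigError(f"{key}: pair rule requires {comp}")
            elif kind == "categorical":
                cmap = rule.get("category_map")
                if not cmap:
                    raise ConfigError(f"{key}: categorical rule requires category_map")
                rule["category_map"] = {k: Category(v) for k, v in cmap.items()}
            else:
                raise ConfigError(f"{key}: unknown rule kind {kind!r}")
            rule["kind"] = kind
            self._rules[factor] = rule
        missing = [f.value for f in Factor if f not in self._rules]
        if missing:
            raise ConfigError(f"cut-point table missing factors: {missing}")

    def rule(self, factor: Factor) -> dict:
        return self._rules[Factor(factor)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CutpointTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def default_cutpoints() -> CutpointTable:
    """The bundled AHA-style pediatric default cut points."""
    with resources.files("cvhrx.data").joinpath("cutpoints.yaml").open() as fh:
        return CutpointTable(yaml.safe_load(fh))


def categorize_factor(factor_value: RiskFactorValue, cutpoints: CutpointTable) -> FactorAssessment:
    """Rate one available factor as ideal/intermediate/poor."""
    if not factor_value.available:
        raise EmptyProfileError(f"{factor_value.factor.value} is not available for scoring")
    rule = cutpoints.rule(factor_value.factor)
    kind = rule["kind"]
    if kind == "scalar":
        category = _categorize_scalar(float(factor_value.value), rule["direction"], rule["boundaries"])
    elif kind == "pair":
        sys_v, dia_v = factor_value.value  # (systolic, diastolic) mmHg
        cats = [
            _categorize_scalar(float(sys_v), rule["systolic"]["direction"], rule["systolic"]["boundaries"]),
            _categorize_scalar(float(dia_v), rule["diastolic"]["direction"], rule["diastolic"]["boundaries"]),
        ]
        category = min(cats, key=lambda c: POINTS[c])  # worse component wins
    else:  # categorical
        cmap = rule["category_map"]
        try:
            category = cmap[factor_value.value]
        except KeyError:
            raise ConfigError(
                f"{factor_value.factor.value}: value {factor_value.value!r} not in "
                f"category map {sorted(cmap)}"
            ) from None
    return FactorAssessment(factor=factor_value.factor, category=category)


def compute_cvh_score(
    profile: Sequence[RiskFactorValue], cutpoints: CutpointTable | None = None
) -> CVHScore:
    """Score a profile: sum 2/1/0 points over available factors, normalize.

    Unavailable factors are excluded from both the numerator and the
    denominator, so the score stays comparable across visits with
    different data availability.
    """
    cutpoints = cutpoints or default_cutpoints()
    assessments = tuple(
        categorize_factor(fv, cutpoints) for fv in profile if fv.available
    )
    if not assessments:
        raise EmptyProfileError("cannot score a profile with zero available factors")
    return CVHScore(assessments=assessments)


def what_if(
    profile: Sequence[RiskFactorValue],
    factor: Factor | str,
    new_value: object,
    cutpoints: CutpointTable | None = None,
) -> CVHScore:
    """Rescore with one factor's value replaced ("slider" recalculation).

    The input profile is left untouched; only the named factor's assessment
    may differ from ``compute_cvh_score(profile)``.
    """
    factor = Factor(factor)
    if not any(fv.factor == factor for fv in profile):
        raise KeyError(f"factor {factor.value!r} not present in profile")
    hypothetical = [
        RiskFactorValue(factor=factor, value=new_value, available=True)
        if fv.factor == factor
        else fv
        for fv in profile
    ]
    return compute_cvh_score(hypothetical, cutpoints)
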