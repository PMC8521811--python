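"""Post-visit follow-up: check-in scheduling, goal progression, messaging.

Three automated check-ins are scheduled at monthly intervals after the
clinic visit, delivered by the patient's preferred channel (email or SMS —
transport here is a logging stub). Each check-in collects 5-point Likert
adherence ratings (never ... always) for the activity and food-intake
goals. Ratings drive the next goal so that goals stay progressive and
attainable: high adherence advances the weekly-minute goal by 10%, middling
adherence holds it, and low adherence eases it by 10%, always bounded by
the starting goal (floor) and the progression cap.

All patient-facing text passes an autonomy-supportive language lint:
controlling words ("should", "must", "have to", "need to") are rejected;
suggestive phrasing ("may", "could") is the house style.
"""

from __future__ import annotations

import calendar
import datetime as dt
import enum
import json
import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "Channel",
    "CheckInSchedule",
    "CheckInResponse",
    "GoalUpdateRule",
    "MessageTemplate",
    "LintError",
    "schedule_checkins",
    "update_goal",
    "render_message",
    "autonomy_lint",
    "load_templates",
    "default_templates",
    "deliver_stub",
]

# Controlling-language lexicon; word-boundary, case-insensitive.
CONTROLLING_LEXICON = ("should", "must", "have to", "need to")
_LINT_RE = re.compile(
    r"\b(" + "|".join(re.escape(w) for w in CONTROLLING_LEXICON) + r")\b",
    re.IGNORECASE,
)


class LintError(ValueError):
    """Raised when text contains controlling (non-autonomy-supportive) language."""


class Channel(str, enum.Enum):
    email = "email"
    sms = "sms"


@dataclass(frozen=True)
class CheckInSchedule:
    visit_date: dt.date
    checkin_dates: tuple[dt.date, ...]
    channel: Channel

    def __post_init__(self) -> None:
        dates = tuple(self.checkin_dates)
        if any(b <= a for a, b in zip((self.visit_date,) + dates, dates)):
            raise ValueError("check-in dates must be strictly increasing after the visit")
        object.__setattr__(self, "checkin_dates", dates)
        object.__setattr__(self, "channel", Channel(self.channel))


@dataclass(frozen=True)
class CheckInResponse:
    checkin_index: int
    pa_adherence: int
    diet_adherence: int

    def __post_init__(self) -> None:
        if self.checkin_index not in (1, 2, 3):
            raise ValueError("checkin_index must be 1, 2 or 3")
        for name in ("pa_adherence", "diet_adherence"):
            v = getattr(self, name)
            if not 1 <= v <= 5:
                raise ValueError(f"{name} must be a 1-5 Likert value, got {v}")


@dataclass(frozen=True)
class GoalUpdateRule:
    """Likert -> goal multiplier: >=4 advance x1.10, =3 hold, <=2 ease x0.90,
    bounded below by the starting goal and above by the progression cap."""

    advance_threshold: int = 4
    ease_threshold: int = 2
    advance_multiplier: float = 1.10
    ease_multiplier: float = 0.90
    floor: float = 0.0
    cap: float = 420.0

    def __post_init__(self) -> None:
        if not self.ease_multiplier < 1.0 < self.advance_multiplier:
            raise ValueError("require ease_multiplier < 1 < advance_multiplier")
        if self.floor > self.cap:
            raise ValueError("floor cannot exceed cap")


def _add_months(d: dt.date, months: int) -> dt.date:
    """Calendar-month shift with month-end clamping (Jan 31 + 1mo -> Feb 28/29)."""
    month_index = d.month - 1 + months
    year = d.year + month_index // 12
    month = month_index % 12 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def schedule_checkins(
    visit_date: dt.date | str,
    n_checkins: int = 3,
    cadence_months: int = 1,
    channel: Channel | str = Channel.email,
) -> CheckInSchedule:
    """Three monthly check-ins after the visit date (count and cadence
    configurable). Month-end dates clamp to the last day of shorter months."""
    if isinstance(visit_date, str):
        visit_date = dt.date.fromisoformat(visit_date)
    if n_checkins < 1:
        raise ValueError("n_checkins must be >= 1")
    dates = tuple(_add_months(visit_date, cadence_months * i) for i in range(1, n_checkins + 1))
    return CheckInSchedule(visit_date=visit_date, checkin_dates=dates, channel=Channel(channel))


def update_goal(
    current_goal_min_per_week: float,
    response: int,
    rule: GoalUpdateRule | None = None,
) -> float:
    """Next weekly-minute goal from a 1-5 adherence rating, rounded to 0.1."""
    rule = rule or GoalUpdateRule()
    if not 1 <= int(response) <= 5:
        raise ValueError(f"response must be a 1-5 Likert value, got {response}")
    if response >= rule.advance_threshold:
        new = min(current_goal_min_per_week * rule.advance_multiplier, rule.cap)
    elif response <= rule.ease_threshold:
        new = max(current_goal_min_per_week * rule.ease_multiplier, rule.floor)
    else:
        new = current_goal_min_per_week
    return round(new, 1)


def autonomy_lint(text: str) -> None:
    """Reject text containing the controlling-language lexicon."""
    m = _LINT_RE.search(text)
    if m:
        raise LintError(f"controlling language {m.group(0)!r} in message text")


@dataclass(frozen=True)
class MessageTemplate:
    id: str
    tone_class: str
    body: str

    def __post_init__(self) -> None:
        if self.tone_class not in ("advance", "hold", "ease"):
            raise ValueError(f"unknown tone_class {self.tone_class!r}")
        autonomy_lint(self.body)  # templates are linted at load time

    @property
    def placeholders(self) -> set[str]:
        return {f for _, f, _, _ in string.Formatter().parse(self.body) if f}


def render_message(template: MessageTemplate, context: Mapping[str, object]) -> str:
    """Substitute placeholders and lint the rendered result."""
    missing = template.placeholders - set(context)
    if missing:
        raise KeyError(f"unresolved placeholders: {sorted(missing)}")
    text = template.body.format(**context)
    autonomy_lint(text)
    return text


def load_templates(path: str | Path) -> dict[str, MessageTemplate]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {t["id"]: MessageTemplate(**t) for t in raw}


def default_templates() -> dict[str, MessageTemplate]:
    with resources.files("cvhrx.data").joinpath("templates.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {t["id"]: MessageTemplate(**t) for t in raw}


def template_for(kind: str, response: int, templates: Mapping[str, MessageTemplate],
                 rule: GoalUpdateRule | None = None) -> MessageTemplate:
    """Pick the advance/hold/ease template for a goal domain ('pa' or 'diet')."""
    rule = rule or GoalUpdateRule()
    if response >= rule.advance_threshold:
        tone = "advance"
    elif response <= rule.ease_threshold:
        tone = "ease"
    else:
        tone = "hold"
    return templates[f"{tone}_{kind}"]


def deliver_stub(
    log_path: str | Path,
    document_id: str,
    channel: Channel | str,
    body: str,
    when: dt.datetime | None = None,
) -> dict:
    """Append a delivery record to a JSON-lines log; no network transport."""
    record = {
        "document_id": document_id,
        "channel": Channel(channel).value,
        "timestamp": (when or dt.datetime.now()).isoformat(timespec="seconds"),
        "status": "delivered_stub",
        "chars": len(body),
    }
    with open(log_path, "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")
    return record
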