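"""Prescription-document assembly, rendering and patient/survey file I/O.

The behavioral "prescription" handed to the patient after the visit has
four sections: goals (the progressive activity plan plus any stoplight-diet
recommendations), the activities the patient selected, nearby community
resources, and educational material. The document is JSON-first — the text
and HTML renders are deterministic projections of the same structure — and
all patient-facing text passes the autonomy-supportive language lint.
"""

from __future__ import annotations

import html as _html
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from importlib import resources as _ilres

from .followup import autonomy_lint
from .prescriptions import Activity, DietRecommendation, PAPlan
from .resources import ResourceHit

__all__ = [
    "PrescriptionDocument",
    "assemble_prescription",
    "render_document",
    "summarize_likert_items",
    "read_patients",
    "default_education_library",
]

SECTION_KEYS = ("goals", "activities", "resources", "education")


@dataclass(frozen=True)
class PrescriptionDocument:
    """The patient-facing prescription: four sections, JSON-serializable."""

    patient_id: str
    preferred_channel: str
    sections: Mapping[str, object]

    def __post_init__(self) -> None:
        missing = [k for k in SECTION_KEYS if k not in self.sections]
        if missing:
            raise ValueError(f"document missing sections: {missing}")
        object.__setattr__(self, "sections", dict(self.sections))

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "preferred_channel": self.preferred_channel,
            "sections": self.sections,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PrescriptionDocument":
        return cls(
            patient_id=d["patient_id"],
            preferred_channel=d["preferred_channel"],
            sections=d["sections"],
        )


def default_education_library() -> dict:
    with _ilres.files("cvhrx.data").joinpath("education.yaml").open() as fh:
        return yaml.safe_load(fh)


def _plan_to_dict(plan: PAPlan) -> dict:
    return {
        "weight_status": plan.weight_status,
        "activity_status": plan.activity_status.value,
        "intensity_target": plan.intensity_target.value,
        "weeks": [
            {
                "week": w.week,
                "minutes_per_week": w.minutes_per_week,
                "sessions_per_week": w.sessions_per_week,
            }
            for w in plan.weeks
        ],
    }


def assemble_prescription(
    patient_id: str,
    pa_plan: PAPlan,
    diet_recs: Sequence[DietRecommendation] = (),
    resource_hits: Sequence[ResourceHit] = (),
    education_library: Mapping | None = None,
    preferred_channel: str = "email",
    max_resources: int = 5,
) -> PrescriptionDocument:
    """Build the four-section document.

    Education blocks are selected by the flagged diet behaviors plus the
    general activity and stoplight blocks; the resources section is limited
    to the top ``max_resources`` hits.
    """
    if pa_plan is None:
        raise ValueError("a physical-activity plan is required")
    library = education_library or default_education_library()
    education_keys = ["physical_activity"]
    if diet_recs:
        education_keys.append("stoplight_overview")
        education_keys += [rec.behavior.value for rec in diet_recs]
    education_keys.append("family_tips")
    education = [
        {"title": library[k]["title"], "body": library[k]["body"]}
        for k in education_keys
        if k in library
    ]
    sections = {
        "goals": {
            "physical_activity": _plan_to_dict(pa_plan),
            "diet": [
                {
                    "behavior": rec.behavior.value,
                    "goal_statement": rec.goal_statement,
                    "food_lists": {t: list(v) for t, v in rec.food_lists.items()},
                }
                for rec in diet_recs
            ],
        },
        "activities": [
            {"name": a.name, "met": a.met, "intensity": a.intensity_class.value}
            for a in pa_plan.selected_activities
        ],
        "resources": [
            {
                "name": h.resource.name,
                "category": h.resource.category,
                "distance_km": h.distance_km,
                "address": h.resource.address,
                "hours": h.resource.hours,
                "amenities": list(h.resource.amenities),
                "color": h.resource.color,
            }
            for h in list(resource_hits)[:max_resources]
        ],
        "education": education,
    }
    return PrescriptionDocument(
        patient_id=str(patient_id), preferred_channel=preferred_channel, sections=sections
    )


def _render_text(doc: PrescriptionDocument) -> str:
    s = doc.sections
    lines = [f"Healthy Habits Plan for patient {doc.patient_id}", "=" * 40, ""]
    pa = s["goals"]["physical_activity"]
    lines.append("YOUR ACTIVITY GOALS")
    lines.append(
        f"  Target intensity: {pa['intensity_target']}  "
        f"(status: {pa['activity_status']}, level: {pa['weight_status']})"
    )
    for w in pa["weeks"]:
        lines.append(
            f"  Week {w['week']:>2}: {w['minutes_per_week']:.1f} min "
            f"over {w['sessions_per_week']} sessions"
        )
    lines.append("")
    if s["goals"]["diet"]:
        lines.append("YOUR FOOD GOALS")
        for rec in s["goals"]["diet"]:
            lines.append(f"  [{rec['behavior']}] {rec['goal_statement']}")
            for tier, label in (("green", "anytime"), ("yellow", "sometimes"), ("red", "rarely")):
                lines.append(f"    {tier} ({label}): " + ", ".join(rec["food_lists"][tier]))
        lines.append("")
    lines.append("ACTIVITIES YOU PICKED")
    for a in s["activities"]:
        lines.append(f"  - {a['name']} ({a['intensity']}, {a['met']} METs)")
    lines.append("")
    if s["resources"]:
        lines.append("RESOURCES NEAR YOU")
        for r in s["resources"]:
            lines.append(f"  - {r['name']} [{r['category']}] {r['distance_km']:.2f} km")
        lines.append("")
    lines.append("GOOD TO KNOW")
    for block in s["education"]:
        lines.append(f"  {block['title']}")
        lines.append(f"    {block['body']}")
    return "\n".join(lines) + "\n"


def _render_html(doc: PrescriptionDocument) -> str:
    s = doc.sections
    esc = _html.escape
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        "<style>"
        ".green{background:#d3f2d3}.yellow{background:#fdf3c8}.red{background:#f9d2d2}"
        "table.stoplight{border-collapse:collapse}table.stoplight td,th{padding:4px 8px}"
        "</style></head><body>",
        f"<h1>Healthy Habits Plan — patient {esc(doc.patient_id)}</h1>",
        "<h2>Your activity goals</h2><ul>",
    ]
    pa = s["goals"]["physical_activity"]
    for w in pa["weeks"]:
        parts.append(
            f"<li>Week {w['week']}: {w['minutes_per_week']:.1f} min over "
            f"{w['sessions_per_week']} sessions</li>"
        )
    parts.append("</ul>")
    for rec in s["goals"]["diet"]:
        parts.append(f"<h2>Food goal: {esc(rec['behavior'])}</h2>")
        parts.append(f"<p>{esc(rec['goal_statement'])}</p>")
        parts.append("<table class='stoplight'><tr><th>anytime</th><th>sometimes</th><th>rarely</th></tr><tr>")
        for tier in ("green", "yellow", "red"):
            items = "".join(f"<div>{esc(f)}</div>" for f in rec["food_lists"][tier])
            parts.append(f"<td class='{tier}'>{items}</td>")
        parts.append("</tr></table>")
    parts.append("<h2>Activities you picked</h2><ul>")
    for a in s["activities"]:
        parts.append(f"<li>{esc(a['name'])} ({esc(a['intensity'])})</li>")
    parts.append("</ul>")
    if s["resources"]:
        parts.append("<h2>Resources near you</h2><ul>")
        for r in s["resources"]:
            parts.append(
                f"<li style='color:{esc(r['color'])}'>{esc(r['name'])} "
                f"[{esc(r['category'])}] {r['distance_km']:.2f} km</li>"
            )
        parts.append("</ul>")
    parts.append("<h2>Good to know</h2>")
    for block in s["education"]:
        parts.append(f"<h3>{esc(block['title'])}</h3><p>{esc(block['body'])}</p>")
    parts.append("</body></html>")
    return "\n".join(parts)


def render_document(doc: PrescriptionDocument, format: str = "text") -> str:
    """Render to ``text``, ``html`` or ``json``; deterministic for fixed input.

    The text render is additionally passed through the autonomy-language
    lint, so a controlling phrase anywhere in the assembled content fails
    loudly rather than reaching the patient.
    """
    if format == "json":
        return json.dumps(doc.to_dict(), sort_keys=True, indent=2)
    if format == "text":
        out = _render_text(doc)
        autonomy_lint(out)
        return out
    if format == "html":
        return _render_html(doc)
    raise ValueError(f"unknown format {format!r}; expected text, html or json")


def summarize_likert_items(item_means: Sequence[float]) -> float:
    """Unweighted mean of per-item Likert means (1-5 scale), to one decimal."""
    means = [float(m) for m in item_means]
    if not means:
        raise ValueError("at least one item mean is required")
    bad = [m for m in means if not 1.0 <= m <= 5.0]
    if bad:
        raise ValueError(f"item means outside the 1-5 scale: {bad}")
    return round(sum(means) / len(means), 1)


PATIENT_COLUMNS = [
    "id", "age_months", "sex", "height_cm", "weight_kg",
    "systolic_bp", "diastolic_bp", "cholesterol", "glucose", "smoking",
    "mvpa_min_per_week",
    "diet_fruit", "diet_vegetable", "diet_whole_grains", "diet_ssb", "diet_snacking",
    "pa_willingness", "diet_willingness",
    "lat", "lon", "preferred_channel",
]

REQUIRED_PATIENT_COLUMNS = ["id", "age_months", "sex", "height_cm", "weight_kg"]


def read_patients(path: str | Path) -> tuple[list[dict], list[dict]]:
    """Read patient records from CSV or JSON.

    Returns ``(records, rejects)``: validated row dicts plus per-row
    diagnostics for rejected rows. The reader validates structure only; it
    does not apply the eligibility filter.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_PATIENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"patient file missing required columns: {missing}")
    records, rejects = [], []
    for i, row in frame.iterrows():
        try:
            rec = row.to_dict()
            rec["age_months"] = int(rec["age_months"])
            rec["height_cm"] = float(rec["height_cm"])
            rec["weight_kg"] = float(rec["weight_kg"])
            if rec["sex"] not in ("male", "female"):
                raise ValueError(f"sex must be male/female, got {rec['sex']!r}")
            if rec["height_cm"] <= 0 or rec["weight_kg"] <= 0:
                raise ValueError("height and weight must be positive")
            records.append(rec)
        except (ValueError, TypeError, KeyError) as exc:
            rejects.append({"row": int(i), "reason": str(exc)})
    return records, rejects
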