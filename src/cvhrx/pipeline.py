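"""End-to-end glue: patient record -> risk profile -> score -> prescription."""

from __future__ import annotations

import datetime as dt
from typing import Sequence

from .anthropometry import LMSReference, classify_weight_status, default_lms_table
from .cohort import PatientRecord
from .documents import PrescriptionDocument, assemble_prescription
from .followup import CheckInSchedule, schedule_checkins
from .prescriptions import (
    Activity,
    DietSurvey,
    classify_activity_status,
    default_activity_menu,
    flag_problem_behaviors,
    generate_diet_recs,
    generate_pa_plan,
)
from .resources import GeoPoint, ResourceCatalog, find_nearby
from .scoring import CVHScore, Factor, RiskFactorValue, compute_cvh_score


def risk_profile(patient: PatientRecord, lms_table: LMSReference | None = None) -> list[RiskFactorValue]:
    """Assemble the seven-factor risk profile from one patient record.

    BMI percentile is always derivable from the measurement; the other six
    factors are available only when the record carries them.
    """
    lms = lms_table or default_lms_table()
    status = classify_weight_status(patient.measurement, lms)
    profile = [RiskFactorValue(Factor.bmi_percentile, value=status.percentile)]

    def opt(factor: Factor, value) -> RiskFactorValue:
        if value is None:
            return RiskFactorValue(factor, available=False)
        return RiskFactorValue(factor, value=value)

    bp = None
    if patient.systolic_bp is not None and patient.diastolic_bp is not None:
        bp = (patient.systolic_bp, patient.diastolic_bp)
    profile.append(opt(Factor.blood_pressure, bp))
    profile.append(opt(Factor.cholesterol, patient.cholesterol))
    profile.append(opt(Factor.glucose, patient.glucose))
    profile.append(opt(Factor.smoking, patient.smoking))
    profile.append(opt(Factor.physical_activity, patient.mvpa_min_per_week))
    diet_count = None
    if patient.diet_answers is not None:
        diet_count = DietSurvey(patient.diet_answers).healthy_component_count()
    profile.append(opt(Factor.diet, diet_count))
    return profile


def prescribe_for(
    patient: PatientRecord,
    chosen_activities: Sequence[Activity] | None = None,
    catalog: ResourceCatalog | None = None,
    lms_table: LMSReference | None = None,
    visit_date: dt.date | None = None,
) -> tuple[CVHScore, PrescriptionDocument, CheckInSchedule]:
    """Score, build the prescription document, and schedule check-ins.

    Activity status falls back to ``inactive`` when weekly MVPA is missing
    (the conservative starting dose); activities default to the two least
    intense menu options when the patient has not yet picked.
    """
    lms = lms_table or default_lms_table()
    score = compute_cvh_score(risk_profile(patient, lms))
    status = classify_weight_status(patient.measurement, lms)
    weight_tier = status.category.value
    if weight_tier in ("healthy", "underweight"):
        weight_tier = "overweight"  # plans are defined for the eligible tiers
    activity_status = classify_activity_status(patient.mvpa_min_per_week or 0.0)
    if chosen_activities is None:
        menu = sorted(default_activity_menu(), key=lambda a: a.met)
        chosen_activities = menu[:2]
    plan = generate_pa_plan(weight_tier, activity_status, chosen_activities=chosen_activities)
    recs = []
    if patient.diet_answers is not None:
        recs = generate_diet_recs(flag_problem_behaviors(DietSurvey(patient.diet_answers)))
    hits = []
    if catalog is not None:
        hits = find_nearby(catalog, GeoPoint(patient.home_lat, patient.home_lon))
    document = assemble_prescription(
        patient_id=patient.id,
        pa_plan=plan,
        diet_recs=recs,
        resource_hits=hits,
        preferred_channel=patient.preferred_channel,
    )
    visit = visit_date or dt.date.today()
    schedule = schedule_checkins(visit, channel=patient.preferred_channel)
    return score, document, schedule
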