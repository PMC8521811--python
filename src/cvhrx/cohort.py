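"""Seedable synthetic adolescent cohort with the structure the tool expects.

Generates patient records — demographics, anthropometry, risk-factor values
with realistic missingness, diet-screener answers, weekly activity minutes,
willingness ratings, a home location and a contact preference — for testing
every downstream module offline. The BMI-for-age z-score is sampled first
(skewed toward overweight/obesity, matching the tool's clinic population of
12-19-year-olds with BMI percentile >= 85) and the weight is back-solved
through the LMS reference from a sampled height, so downstream scoring
recovers exactly the z that was drawn. Distribution defaults are invented
for testing and are not epidemiological claims.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .anthropometry import (
    LMSReference,
    Measurement,
    Sex,
    classify_weight_status,
    compute_bmi,
    default_lms_table,
    lms_inverse,
)
from .prescriptions import DIET_SCREENER_ITEMS, DietBehavior
from .scoring import Factor

__all__ = ["CohortConfig", "PatientRecord", "generate_cohort", "check_eligibility", "cohort_to_frame"]


@dataclass(frozen=True)
class CohortConfig:
    n: int = 50
    seed: int = 0
    age_range_months: tuple[int, int] = (144, 239)
    male_fraction: float = 0.5
    bmi_z_mean: float = 1.5
    bmi_z_sd: float = 0.6
    factor_availability: float = 0.9       # per optional factor
    diet_problem_prevalence: float = 0.5   # per behavior
    mvpa_median: float = 90.0              # min/week, lognormal
    mvpa_log_sd: float = 0.9
    home_bbox: tuple[float, float, float, float] = (38.50, 38.80, -90.45, -90.10)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for p in (self.male_fraction, self.factor_availability, self.diet_problem_prevalence):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        lo, hi = self.age_range_months
        if lo >= hi:
            raise ValueError("age range must be increasing")


@dataclass(frozen=True)
class PatientRecord:
    id: str
    measurement: Measurement
    systolic_bp: float | None
    diastolic_bp: float | None
    cholesterol: float | None
    glucose: float | None
    smoking: str | None
    mvpa_min_per_week: float | None
    diet_answers: dict[DietBehavior, bool] | None
    pa_willingness: int
    diet_willingness: int
    home_lat: float
    home_lon: float
    preferred_channel: str

    def to_row(self) -> dict:
        row = {
            "id": self.id,
            "age_months": self.measurement.age_months,
            "sex": self.measurement.sex.value,
            "height_cm": round(self.measurement.height_cm, 2),
            "weight_kg": round(self.measurement.weight_kg, 2),
            "systolic_bp": self.systolic_bp,
            "diastolic_bp": self.diastolic_bp,
            "cholesterol": self.cholesterol,
            "glucose": self.glucose,
            "smoking": self.smoking,
            "mvpa_min_per_week": self.mvpa_min_per_week,
            "pa_willingness": self.pa_willingness,
            "diet_willingness": self.diet_willingness,
            "lat": round(self.home_lat, 6),
            "lon": round(self.home_lon, 6),
            "preferred_channel": self.preferred_channel,
        }
        for b in DietBehavior:
            row[f"diet_{b.value}"] = (
                None if self.diet_answers is None else bool(self.diet_answers[b])
            )
        return row


# Rough sex/age-typical height curves (cm): linear in age with plateau for girls.
def _height_mean(sex: Sex, age_months: float) -> float:
    years = age_months / 12.0
    if sex == Sex.male:
        return 149.0 + (min(years, 19.0) - 12.0) * (176.0 - 149.0) / 7.0
    return 151.0 + (min(years, 16.0) - 12.0) * (163.0 - 151.0) / 4.0


def _one_patient(i: int, cfg: CohortConfig, lms: LMSReference) -> PatientRecord:
    # counter-derived substream: record i is identical regardless of n
    rng = np.random.default_rng([cfg.seed % (2**31), i])
    sex = Sex.male if rng.random() < cfg.male_fraction else Sex.female
    age = int(rng.integers(cfg.age_range_months[0], cfg.age_range_months[1] + 1))
    z = float(np.clip(rng.normal(cfg.bmi_z_mean, cfg.bmi_z_sd), -3.5, 3.5))
    L, M, S = lms.lookup(sex, age)
    # keep the Box-Cox base away from its singularity so BMI stays physical
    if L < 0:
        z = min(z, -0.9 / (L * S))
    elif L > 0:
        z = max(z, -0.9 / (L * S))
    bmi = lms_inverse(z, L, M, S)
    height = float(np.clip(rng.normal(_height_mean(sex, age), 7.0), 130.0, 210.0))
    weight = bmi * (height / 100.0) ** 2
    meas = Measurement(age_months=age, sex=sex, height_cm=height, weight_kg=weight)

    avail = rng.random(4) < cfg.factor_availability  # bp, chol, glucose, smoking
    systolic = diastolic = cholesterol = glucose = None
    smoking = None
    if avail[0]:
        systolic = float(np.round(rng.normal(112.0, 10.0), 0))
        diastolic = float(np.round(rng.normal(68.0, 8.0), 0))
    if avail[1]:
        cholesterol = float(np.round(rng.normal(165.0, 28.0), 0))
    if avail[2]:
        glucose = float(np.round(rng.normal(92.0, 10.0), 0))
    if avail[3]:
        smoking = str(rng.choice(["never", "former", "current"], p=[0.88, 0.07, 0.05]))

    mvpa = None
    if rng.random() < cfg.factor_availability:
        mvpa = float(np.round(rng.lognormal(np.log(cfg.mvpa_median), cfg.mvpa_log_sd), 0))
        if rng.random() < 0.10:  # a slice of truly inactive patients
            mvpa = 0.0

    diet_answers = None
    if rng.random() < cfg.factor_availability:
        diet_answers = {}
        for b in DietBehavior:
            problem = rng.random() < cfg.diet_problem_prevalence
            healthy = DIET_SCREENER_ITEMS[b]["healthy_answer"]
            diet_answers[b] = (not healthy) if problem else healthy

    lat_lo, lat_hi, lon_lo, lon_hi = cfg.home_bbox
    return PatientRecord(
        id=f"P{i:04d}",
        measurement=meas,
        systolic_bp=systolic,
        diastolic_bp=diastolic,
        cholesterol=cholesterol,
        glucose=glucose,
        smoking=smoking,
        mvpa_min_per_week=mvpa,
        diet_answers=diet_answers,
        pa_willingness=int(rng.integers(1, 6)),
        diet_willingness=int(rng.integers(1, 6)),
        home_lat=float(rng.uniform(lat_lo, lat_hi)),
        home_lon=float(rng.uniform(lon_lo, lon_hi)),
        preferred_channel=str(rng.choice(["email", "sms"])),
    )


def generate_cohort(config: CohortConfig, lms_table: LMSReference | None = None) -> list[PatientRecord]:
    """Generate ``config.n`` patients; bit-reproducible for a fixed seed."""
    lms = lms_table or default_lms_table()
    lo, hi = config.age_range_months
    for sex in Sex:
        tlo, thi = lms.age_range(sex)
        if lo < tlo or hi > thi:
            raise ValueError(
                f"age range {config.age_range_months} exceeds LMS coverage [{tlo}, {thi}]"
            )
    return [_one_patient(i, config, lms) for i in range(config.n)]


def check_eligibility(
    patient: PatientRecord, lms_table: LMSReference | None = None
) -> tuple[bool, list[str]]:
    """Eligibility: adolescent (144-239 months) with BMI percentile >= 85.

    Returns the verdict plus machine-readable reason codes for any failure.
    """
    lms = lms_table or default_lms_table()
    reasons = []
    age = patient.measurement.age_months
    if not 144 <= age <= 239:
        reasons.append("age_out_of_range")
    status = classify_weight_status(patient.measurement, lms)
    if status.percentile < 85.0:
        reasons.append("bmi_percentile_below_85")
    return (not reasons), reasons


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the documented patient-file schema."""
    return pd.DataFrame([p.to_row() for p in cohort])
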