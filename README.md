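# cvhrx

Offline toolkit for point-of-care preventive cardiology with adolescents
(12–19 years) who have overweight or obesity. It implements the computational
core of a clinic-facing behavior-change workflow:

1. **Cardiovascular-health (CVH) scoring.** Each of the Life's Simple 7 risk
   factors — BMI percentile, blood pressure, total cholesterol, fasting
   glucose, smoking status, physical activity and diet quality — is rated
   *ideal* (2 points, green), *intermediate* (1, yellow) or *poor* (0, red)
   against pediatric cut points. The score is the points sum divided by the
   maximum attainable, `T / (2·n_available)` ∈ [0, 1], with 14 points possible
   when all seven factors are measured. A non-mutating `what_if` recalculation
   supports the interactive "slider" conversation.
2. **Anthropometry.** BMI-for-age z-scores via the LMS method
   (`z = ((x/M)^L − 1)/(L·S)`, or `ln(x/M)/S` for `L = 0`) with weight-status
   tiers: overweight ≥85th percentile, obese ≥95th, severe obesity at
   BMI ≥ 120% of the 95th-percentile BMI.
3. **Prescriptions.** A progressive physical-activity plan (starting dose from
   an obesity-level × activity-status matrix, +10%/week to a 420 min/week cap)
   with a MET-rated activity menu, and stoplight-diet recommendations (green
   "anytime" / yellow "sometimes" / red "rarely" food lists) generated only
   for the eating behaviors a five-item screener flags as problems.
4. **Community resources.** An offline geolocated catalog (GeoJSON or CSV)
   queried by great-circle distance from the patient's home.
5. **Follow-up.** Three monthly check-ins; 5-point Likert adherence responses
   advance (×1.10), hold, or ease (×0.90) the weekly goal within
   [floor, cap]; all patient-facing text passes an autonomy-supportive
   language lint (no "should", "must", "have to", "need to").
6. **Synthetic cohort.** A seedable generator of realistic adolescent patient
   records so every module is testable with no downloads.

## Worked example

```python
from cvhrx import (Factor, RiskFactorValue, compute_cvh_score, what_if,
                   generate_pa_plan, default_activity_menu, ProgressionConfig)

profile = [
    RiskFactorValue(Factor.bmi_percentile, value=96),
    RiskFactorValue(Factor.blood_pressure, value=(118, 74)),
    RiskFactorValue(Factor.cholesterol, value=150),
    RiskFactorValue(Factor.glucose, value=90),
    RiskFactorValue(Factor.smoking, value="never"),
    RiskFactorValue(Factor.physical_activity, value=60),
    RiskFactorValue(Factor.diet, value=3),
]
s = compute_cvh_score(profile)
print(s.total_points, "/", s.max_points, "=", round(s.score, 3))
# 10 / 14 = 0.714    (BMI poor, activity and diet intermediate)

w = what_if(profile, Factor.physical_activity, 450)   # slider: MVPA -> ideal
print(w.total_points, "/", w.max_points)
# 11 / 14

plan = generate_pa_plan(
    "overweight", "inactive",
    progression=ProgressionConfig(horizon_weeks=4, weekly_cap_min_per_week=420),
    chosen_activities=default_activity_menu()[:2],
)
print(plan.weekly_minutes)
# [90, 99.0, 108.9, 119.8]   # 30 min x 3/wk start, +10% each week
```

The score line means the patient earns 10 of 14 possible points; moving the
activity slider to the ideal range shows the score rising to 11/14. The plan
starts at 90 weekly minutes and grows 10% per week.

A CLI wraps the same library:

```sh
cvhrx simulate --n 25 --seed 7 --out cohort.csv
cvhrx score cohort.csv
cvhrx schedule 2021-01-31         # -> 2021-02-28, 2021-03-31, 2021-04-30
cvhrx checkin 100 --pa-response 5 # -> new goal 110.0 + encouragement message
```

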