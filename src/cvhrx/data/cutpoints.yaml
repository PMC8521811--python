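# Default pediatric risk-factor cut points (AHA-style defaults; overridable).
# Interval convention: half-open on the worse direction. For lower_is_better,
# ideal is value < boundaries[0]; intermediate boundaries[0] <= value <
# boundaries[1]; poor value >= boundaries[1]. For higher_is_better the order
# reverses: poor < boundaries[0] <= intermediate < boundaries[1] <= ideal.
bmi_percentile:
  direction: lower_is_better
  boundaries: [85, 95]          # percentile
blood_pressure:
  kind: pair                    # (systolic, diastolic) mmHg; worse component wins
  systolic:
    direction: lower_is_better
    boundaries: [120, 140]
  diastolic:
    direction: lower_is_better
    boundaries: [80, 90]
cholesterol:
  direction: lower_is_better
  boundaries: [170, 200]        # total cholesterol mg/dL
glucose:
  direction: lower_is_better
  boundaries: [100, 126]        # fasting glucose mg/dL
smoking:
  kind: categorical
  category_map:
    never: ideal
    former: intermediate
    current: poor
physical_activity:
  direction: higher_is_better
  boundaries: [1, 420]          # min/week MVPA; 420 = 60 min/day x 7
diet:
  direction: higher_is_better
  boundaries: [2, 4]            # healthy diet components out of 5
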