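# Methods

## Scope and model

`cvhrx` is a rule engine, not a fitted statistical model: it encodes the
scoring, prescription, scheduling and messaging rules of a point-of-care
behavior-change workflow for adolescents with overweight/obesity, plus the
anthropometric transforms they depend on. Every clinical threshold lives in
overridable configuration (YAML); the code owns only the rule semantics.

## Anthropometry

BMI-for-age z-scores use the LMS method: a growth reference supplies, per sex
and age in months, a Box-Cox power `L`, median `M` (kg/m²) and coefficient of
variation `S`, and a BMI `x` maps to `z = ((x/M)^L − 1)/(L·S)` with the log
limit `ln(x/M)/S` as `L → 0`. Numerically, the log branch is used for
`|L| < 1e-5`: below that the Box-Cox numerator `(x/M)^L − 1` loses double
precision, and the two branches agree to ~`L·ln(x/M)²/(2S)` ≈ 1e-4 at the
crossover. LMS parameters are linearly interpolated in age between table rows
(reference tables are monthly, so linear error is negligible); interpolation
at a knot reproduces the knot exactly.

Weight-status tiers follow US pediatric convention: underweight <5th
percentile, healthy 5–<85th, overweight 85–<95th, obese ≥95th, and severe
obesity when BMI ≥ 120% of the 95th-percentile BMI for age/sex. The severe
tier is checked first so it wins over plain "obese". The percentile is the
standard-normal CDF of z, on a 0–100 scale.

The bundled reference table (`data/lms_reference_synthetic.csv`) is
**synthetic**: smooth L/M/S curves over 144–240 months for both sexes with
realistic magnitudes (e.g., male median BMI rising ~17.8 → ~22.7 kg/m²). It
makes the package self-contained and exercises every code path, but it is not
the CDC 2000 reference; z-scores computed from it are not clinically
interpretable. A real table in the same CSV schema drops in unchanged.

## CVH scoring

Seven factors, three categories each, 2/1/0 points, normalized by
`2 × n_available`. Unavailable factors leave both numerator and denominator,
so a six-factor all-ideal profile still scores 1.0. Default cut points
(shipped as `data/cutpoints.yaml`, all overridable):

| factor | ideal | intermediate | poor |
|---|---|---|---|
| BMI percentile | <85 | 85–<95 | ≥95 |
| blood pressure (mmHg) | <120/80 | 120–139 or 80–89 | ≥140 or ≥90 |
| total cholesterol (mg/dL) | <170 | 170–199 | ≥200 |
| fasting glucose (mg/dL) | <100 | 100–125 | ≥126 |
| smoking | never | former | current |
| MVPA (min/week) | ≥420 | 1–419 | 0 |
| healthy diet components (0–5) | 4–5 | 2–3 | 0–1 |

Intervals are half-open toward the worse category (a boundary value falls in
the worse-adjacent band). Blood pressure takes the worse of the systolic and
diastolic components; a precomputed category can be emulated by supplying a
value inside the desired band. Smoking has three levels (never/former/
current). Willingness-to-change Likert items are carried with the profile for
the conversation but deliberately do not affect the score or auto-prioritize
recommendations.

`what_if` re-scores a copy of the profile with one factor's value replaced —
the input is immutable (frozen dataclasses), which the tests verify by
serializing before/after.

## Prescriptions

**Activity.** The starting dose comes from a 3×4 matrix (overweight/obese/
severe-obese × inactive/somewhat/moderately/active). The shipped numbers
(20 min × 3/wk up to 45 min × 5/wk) are placeholders satisfying the clinical
ordering constraint — severely obese inactive patients start with shorter
sessions and no more weekly sessions than overweight inactive patients — and
that constraint is re-validated whenever a user-supplied matrix loads.
Activity status uses 0 / 1–149 / 150–299 / ≥300 min/week MVPA thresholds.
Weekly minute goals follow `d_{w+1} = min(round(d_w · r, 0.1), cap)` with
`r = 1.10` and cap 420 min/week (60 min/day youth guideline) over a 12-week
default horizon. Rounding compounds, so over w weeks the trajectory can drift
from the closed form `d₁·r^{w−1}` by at most `0.05·(r^{w−1}−1)/(r−1)`; tests
use that bound. Activity choice is mandatory (autonomy by design); the menu
carries MET values and intensity is derived as light <3.0, moderate 3.0–<6.0,
vigorous ≥6.0 METs, checked for consistency at load. Tag-based exclusion
filters regionally irrelevant activities (the default drops `coastal`).

**Diet.** Five screener items (fruit, vegetables, whole grains, sugar-
sweetened beverages, snacking) each have a defined healthy answer; a behavior
is flagged iff its answer fails that criterion, and exactly one
recommendation — goal statement plus green/yellow/red food lists — is emitted
per flagged behavior. `max_behaviors` optionally truncates to the first k
flags in screener order for families preferring a narrower focus. Diet goals
do not ramp numerically; only follow-up message tone varies.

## Resources

The catalog is a GeoJSON FeatureCollection or CSV with nine closed categories,
each assigned a distinct display color. Records failing validation (bad
coordinates, unknown category, missing name) are rejected individually with
diagnostics; the rest load. Queries use the haversine great-circle distance on
a 6371.0 km sphere — a straight-line proxy, since routing is out of scope —
with defaults of 8 km radius and k = 10, ties broken by name then catalog
order. Distances are reported to 0.01 km.

## Follow-up

Three check-ins at monthly intervals (both count and cadence are parameters),
with month-end overflow clamped to the target month's last day (Jan 31 →
Feb 28/29). The Likert → goal rule (≥4: ×1.10 capped; 3: hold; ≤2: ×0.90
floored at the week-1 goal; round to 0.1 min) is an invented concretization of
"progressive and attainable" and is fully overridable; under constant maximal
adherence it reproduces the prescription engine's capped geometric ramp
exactly, which a cross-module test asserts. Message templates are plain
`str.format` bodies linted at load time and again after rendering against a
word-boundary, case-insensitive lexicon of controlling phrases (should, must,
have to, need to). Delivery is a JSON-lines logging stub; no transport.

## Documents

The prescription document is JSON-first with four mandatory sections (goals,
activities, resources, education); text and HTML renders are deterministic
projections, and the text render is itself passed through the autonomy lint so
a controlling phrase anywhere in assembled content fails loudly. Education
blocks are selected by flagged behaviors plus general activity/stoplight/
family blocks. The satisfaction summary is an unweighted mean of per-item
Likert means, reported to one decimal.

## Synthetic cohort

Per patient, a counter-derived RNG substream (`default_rng([seed, i])`) makes
records independent of cohort size and cohorts bit-reproducible. The
BMI-for-age z is drawn first — default normal(1.5, 0.6), clipped to ±3.5 and
kept clear of the Box-Cox singularity — then BMI is obtained by the inverse
LMS transform and weight back-solved from a sex/age-typical sampled height,
so downstream classification recovers the sampled z to machine precision.
Other defaults: 90% per-factor availability, 50% problem prevalence per diet
behavior, lognormal MVPA with median 90 min/week (plus a 10% truly inactive
slice), uniform home locations in a metro bounding box, mostly never-smokers.
These defaults are testing conventions, not epidemiological claims: the
generator emulates record structure, missingness and the overweight-skewed
clinic population, not correlations among risk factors, growth over time, or
true prevalence. Passing tests therefore demonstrate the rules, transforms
and plumbing — not clinical effectiveness.

Eligibility is age 144–239 months and BMI percentile ≥85, returned with
reason codes.

## Problem sizes and determinism

The test suite enumerates all 3⁷ = 2 187 scoring profiles and all 2⁵ diet flag
sets exhaustively, uses 1 000 random goal-update sequences and 100-entry
random catalogs against brute-force oracles, and a 2 000-patient cohort for
parameter recovery; the acceptance script uses a 500-patient cohort. All
randomness is seeded (hypothesis runs derandomized), and the whole suite runs
in a few seconds on one CPU.

## Known limitations

- No blood-pressure percentile-by-height computation; bands operate on raw
  mmHg (or an emulated category).
- No energy-expenditure/kcal math, no geocoding, routing or live business
  data, no real email/SMS transport, no EHR integration, no PDF.
- Literacy level of educational text is only lightly controlled (short
  sentences by convention); no readability metric is enforced.
- The shipped dose-matrix numbers and Likert→multiplier mapping are documented
  placeholders pending clinically sourced tables.
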