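"""Pediatric anthropometry: BMI, LMS-based BMI-for-age z-scores, weight-status tiers.

The LMS method expresses a growth reference as three age- and sex-specific
parameters — a Box-Cox power (L), the median (M) and a coefficient of
variation (S) — and converts a measurement ``x`` into a z-score::

    z = ((x / M)**L - 1) / (L * S)      if L != 0
    z = ln(x / M) / S                   if L == 0

The package ships a small synthetic reference table covering ages 144-240
months for both sexes so that everything runs offline; a full CDC 2000
growth-chart table in the same CSV schema (``sex,agemos,L,M,S``) may be
supplied instead for clinical use.

Weight-status tiers follow standard US pediatric convention: underweight
below the 5th percentile, healthy 5th to <85th, overweight 85th to <95th,
obese at or above the 95th, and severe obesity at BMI >= 120% of the
95th-percentile BMI for age and sex.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Sex",
    "WeightCategory",
    "Measurement",
    "LMSReference",
    "WeightStatus",
    "compute_bmi",
    "lms_zscore",
    "lms_inverse",
    "zscore_to_percentile",
    "classify_weight_status",
    "load_lms_table",
    "default_lms_table",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class CoverageError(KeyError):
    """Raised when an age/sex combination falls outside the reference table."""


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class WeightCategory(str, enum.Enum):
    underweight = "underweight"
    healthy = "healthy"
    overweight = "overweight"
    obese = "obese"
    severe_obese = "severe_obese"


@dataclass(frozen=True)
class Measurement:
    """A single clinic measurement of one adolescent."""

    age_months: int
    sex: Sex
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.age_months < 24:
            raise ValidationError(f"age_months must be >= 24, got {self.age_months}")
        if not (40 < self.height_cm < 250):
            raise ValidationError(f"height_cm out of plausible range: {self.height_cm}")
        if not (10 < self.weight_kg < 400):
            raise ValidationError(f"weight_kg out of plausible range: {self.weight_kg}")
        object.__setattr__(self, "sex", Sex(self.sex))


@dataclass(frozen=True)
class WeightStatus:
    """BMI plus its z-score, percentile and pediatric weight-status tier."""

    bmi: float
    z: float
    percentile: float
    p95_bmi: float
    category: WeightCategory


class LMSReference:
    """Sex- and age-indexed L/M/S growth-reference table.

    Parameters are linearly interpolated in ``age_months`` between table rows;
    interpolation at a knot reproduces the knot exactly.
    """

    REQUIRED_COLUMNS = ("sex", "agemos", "L", "M", "S")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"LMS table missing columns: {missing}")
        table = table.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        table["sex"] = table["sex"].map(lambda s: Sex(s).value)
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValidationError("LMS table requires M > 0 and S > 0 in every row")
        table = table.sort_values(["sex", "agemos"], kind="mergesort").reset_index(drop=True)
        if table.duplicated(["sex", "agemos"]).any():
            raise ValidationError("duplicate (sex, agemos) rows in LMS table")
        self._by_sex = {
            sex: grp.set_index("agemos")[["L", "M", "S"]]
            for sex, grp in table.groupby("sex", sort=False)
        }
        self.table = table

    def age_range(self, sex: Sex | str) -> tuple[float, float]:
        grp = self._by_sex[Sex(sex).value]
        return float(grp.index.min()), float(grp.index.max())

    def lookup(self, sex: Sex | str, age_months: float) -> tuple[float, float, float]:
        """Return (L, M, S) at ``age_months``, linearly interpolated."""
        sex = Sex(sex).value
        if sex not in self._by_sex:
            raise CoverageError(f"no rows for sex={sex!r}")
        grp = self._by_sex[sex]
        lo, hi = float(grp.index.min()), float(grp.index.max())
        if not (lo <= age_months <= hi):
            raise CoverageError(
                f"age {age_months} months outside table coverage [{lo}, {hi}] for {sex}"
            )
        out = tuple(
            float(np.interp(age_months, grp.index.to_numpy(float), grp[c].to_numpy(float)))
            for c in ("L", "M", "S")
        )
        return out  # type: ignore[return-value]


def compute_bmi(height_cm: float, weight_kg: float) -> float:
    """Body-mass index in kg/m² from height in cm and weight in kg."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValidationError("height_cm and weight_kg must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


# Below this |L| the Box-Cox branch loses precision in double arithmetic
# (the (x/M)**L - 1 numerator underflows); the log-limit form is used there.
# The two branches agree to ~L*ln(x/M)**2/(2S) ~ 1e-4 at the crossover.
_L_EPS = 1e-5


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """LMS z-score of measurement ``x`` given Box-Cox power L, median M, CV S."""
    if x <= 0 or M <= 0 or S <= 0:
        raise ValidationError("x, M and S must all be positive")
    if abs(L) < _L_EPS:
        return math.log(x / M) / S
    return ((x / M) ** L - 1.0) / (L * S)


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement value whose LMS z-score equals ``z`` (inverse transform)."""
    if M <= 0 or S <= 0:
        raise ValidationError("M and S must be positive")
    if abs(L) < _L_EPS:
        return float(M * math.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0:
        raise ValidationError(f"z={z} outside the invertible range for L={L}, S={S}")
    return float(M * base ** (1.0 / L))


def zscore_to_percentile(z: float) -> float:
    """Standard-normal percentile (0-100 scale) of a z-score."""
    if not math.isfinite(z):
        raise ValidationError("z must be finite")
    return float(norm.cdf(z) * 100.0)


def classify_weight_status(measurement: Measurement, lms_table: LMSReference) -> WeightStatus:
    """BMI-for-age z, percentile and weight-status tier for one measurement.

    Tiers: underweight <5th percentile; healthy 5-<85th; overweight 85-<95th;
    obese >=95th; severe obesity when BMI >= 120% of the 95th-percentile BMI.
    """
    L, M, S = lms_table.lookup(measurement.sex, measurement.age_months)
    bmi = compute_bmi(measurement.height_cm, measurement.weight_kg)
    z = lms_zscore(bmi, L, M, S)
    percentile = zscore_to_percentile(z)
    p95 = lms_inverse(norm.ppf(0.95), L, M, S)
    if bmi >= 1.2 * p95:
        category = WeightCategory.severe_obese
    elif percentile >= 95.0:
        category = WeightCategory.obese
    elif percentile >= 85.0:
        category = WeightCategory.overweight
    elif percentile >= 5.0:
        category = WeightCategory.healthy
    else:
        category = WeightCategory.underweight
    return WeightStatus(bmi=bmi, z=z, percentile=percentile, p95_bmi=p95, category=category)


def load_lms_table(path: str | Path) -> LMSReference:
    """Load an LMS reference from a CSV with columns sex,agemos,L,M,S."""
    return LMSReference(pd.read_csv(path))


def default_lms_table() -> LMSReference:
    """The bundled synthetic reference table (ages 144-240 months, both sexes).

    Synthetic: smooth parameter curves with realistic magnitudes, shipped so the
    package is testable offline. Not the CDC 2000 reference; substitute the real
    table for clinical interpretation.
    """
    with resources.files("cvhrx.data").joinpath("lms_reference_synthetic.csv").open() as fh:
        return LMSReference(pd.read_csv(fh))
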