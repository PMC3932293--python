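"""Deterministic generators for the unpublished model backgrounds.

The economic models need several inputs that the source report uses but
never prints: an all-cause female life table, age-specific baseline fracture
hazards for the treated/reference population, post-hip-fracture excess
mortality, and a female population projection for 2010-2013.  This module
generates all of them synthetically, deterministically for a given set of
parameters, and calibrates the fracture hazards so that the budget-impact
pathway reproduces chosen annual fracture counts.

Mortality follows a Gompertz law (hazard a*exp(b*age)): two parameters,
easily calibrated and monotone in age.  Fracture hazards follow a
log-linear age gradient around a reference age scaled to hit calibration
targets.  Every generator accepts a ``seed`` for interface uniformity; the
generators here are fully deterministic and the seed only matters for the
optional sampling utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .parameters import FRACTURE_TYPES, TreatmentProfile, ValidationError

__all__ = [
    "CalibrationError",
    "LifeTable",
    "BaselineHazards",
    "PopulationProjection",
    "CalibrationExposure",
    "make_life_table",
    "make_baseline_hazards",
    "make_population_projection",
    "treated_annual_probability",
    "life_expectancy",
    "DEFAULT_AGE_MIX",
]

MIN_AGE, MAX_AGE = 45, 110

#: Age mix used to average age-specific hazards over a treated population
#: (band midpoints for 45-64, 65-74, 75+ with synthetic weights).
DEFAULT_AGE_MIX: tuple[tuple[float, float], ...] = ((55.0, 0.30), (70.0, 0.40), (80.0, 0.30))


class CalibrationError(ValueError):
    """Requested targets cannot be met by any valid probability schedule."""


@dataclass(frozen=True)
class LifeTable:
    """Six-month all-cause death probabilities by single year of age."""

    ages: np.ndarray
    q6m: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.q6m):
            raise ValidationError("ages and q6m must have equal length")
        if np.any((self.q6m < 0) | (self.q6m > 1)):
            raise ValidationError("death probabilities must lie in [0, 1]")
        over60 = self.ages >= 60
        if np.any(np.diff(self.q6m[over60]) < -1e-12):
            raise ValidationError("death probability must be nondecreasing after 60")
        if self.q6m[-1] != 1.0:
            raise ValidationError("terminal-age death probability must be 1")

    def q(self, age: float | np.ndarray) -> float | np.ndarray:
        """Interpolated six-month death probability at (possibly fractional) age."""
        return np.interp(age, self.ages, self.q6m)


@dataclass(frozen=True)
class BaselineHazards:
    """Six-month first-fracture probabilities by age for the reference cohort.

    ``excess_mortality_hip`` multiplies all-cause mortality during the first
    year after a hip/femoral fracture.
    """

    ages: np.ndarray
    probs: Mapping[str, np.ndarray]  # fracture type -> array over ages
    excess_mortality_hip: float = 2.0

    def __post_init__(self) -> None:
        for ftype in FRACTURE_TYPES:
            if ftype not in self.probs:
                raise ValidationError(f"missing hazard schedule for {ftype!r}")
            arr = self.probs[ftype]
            if len(arr) != len(self.ages):
                raise ValidationError(f"hazard schedule for {ftype!r} has wrong length")
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(f"{ftype} probabilities must lie in [0, 1]")
        if np.any(np.diff(self.probs["hip"]) < -1e-12):
            raise ValidationError("hip hazard must be nondecreasing with age")
        if self.excess_mortality_hip < 1.0:
            raise ValidationError("excess_mortality_hip must be >= 1")

    def six_month(self, fracture_type: str, age: float | np.ndarray) -> float | np.ndarray:
        return np.interp(age, self.ages, self.probs[fracture_type])

    def annual(self, fracture_type: str, age: float | np.ndarray) -> float | np.ndarray:
        """Annual first-fracture probability from two independent 6-month cycles."""
        p = self.six_month(fracture_type, age)
        return 1.0 - (1.0 - p) ** 2

    def scaled(self, factors: Mapping[str, float]) -> "BaselineHazards":
        """New schedule with each type's probabilities multiplied by a factor."""
        probs = {}
        for ftype in FRACTURE_TYPES:
            arr = self.probs[ftype] * factors.get(ftype, 1.0)
            if np.any(arr > 1.0):
                raise CalibrationError(
                    f"scaling factor for {ftype!r} pushes a probability above 1"
                )
            probs[ftype] = arr
        return replace(self, probs=probs)

    def validate_against(self, life_table: LifeTable) -> None:
        """Check total event probability (fractures + death) <= 1 at every age.

        The terminal closure row of the life table (death probability forced
        to 1) is exempt: there the engine applies mortality first and no
        survivor remains to fracture.
        """
        q = np.asarray(life_table.q(self.ages), dtype=float)
        frac = sum(self.probs[f] for f in FRACTURE_TYPES)
        if np.any(frac > 1.0 + 1e-12):
            raise ValidationError("summed fracture probabilities exceed 1")
        open_rows = q < 1.0
        total = frac[open_rows] + q[open_rows]
        if np.any(total > 1.0 + 1e-12):
            age = self.ages[open_rows][np.argmax(total)]
            raise ValidationError(
                f"fracture + death probability exceeds 1 at age {age}"
            )

    @classmethod
    def from_parametric(
        cls,
        p_ref: Mapping[str, float],
        gradients: Mapping[str, float],
        ref_age: float = 65.0,
        excess_mortality_hip: float = 2.0,
        ages: Sequence[int] | None = None,
    ) -> "BaselineHazards":
        """Log-linear schedules p(age) = p_ref * exp(g * (age - ref_age))."""
        ages_arr = np.arange(MIN_AGE, MAX_AGE + 1, dtype=float) if ages is None else np.asarray(ages, dtype=float)
        probs = {}
        for ftype in FRACTURE_TYPES:
            p = float(p_ref[ftype]) * np.exp(float(gradients.get(ftype, 0.0)) * (ages_arr - ref_age))
            probs[ftype] = np.minimum(p, 1.0)
        return cls(ages=ages_arr, probs=probs, excess_mortality_hip=excess_mortality_hip)

    @classmethod
    def flat(
        cls,
        annual: Mapping[str, float],
        excess_mortality_hip: float = 2.0,
    ) -> "BaselineHazards":
        """Age-constant schedule with given ANNUAL first-fracture probabilities."""
        ages_arr = np.arange(MIN_AGE, MAX_AGE + 1, dtype=float)
        probs = {}
        for ftype in FRACTURE_TYPES:
            a = float(annual.get(ftype, 0.0))
            if not 0.0 <= a <= 1.0:
                raise ValidationError(f"annual probability for {ftype!r} out of [0,1]")
            p6 = 1.0 - math.sqrt(1.0 - a)
            probs[ftype] = np.full_like(ages_arr, p6)
        return cls(ages=ages_arr, probs=probs, excess_mortality_hip=excess_mortality_hip)


@dataclass(frozen=True)
class PopulationProjection:
    """Women aged 45+ per calendar year, by age band."""

    counts: Mapping[int, Mapping[str, float]]  # year -> band -> count

    def __post_init__(self) -> None:
        years = sorted(self.counts)
        for year in years:
            if any(v <= 0 for v in self.counts[year].values()):
                raise ValidationError(f"population counts must be > 0 in {year}")
        for y0, y1 in zip(years, years[1:]):
            t0, t1 = self.total(y0), self.total(y1)
            if abs(t1 / t0 - 1.0) > 0.05:
                raise ValidationError(
                    f"year-on-year population change {y0}->{y1} exceeds 5%"
                )

    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.counts))

    def total(self, year: int) -> float:
        return sum(self.counts[year].values())


def make_life_table(
    gompertz_a: float,
    gompertz_b: float,
    seed: int = 0,
    ages: Sequence[int] | None = None,
) -> LifeTable:
    """Gompertz life table of six-month death probabilities.

    The probability for the half-year starting at each age integrates the
    Gompertz hazard a*e^(b*t) exactly over the cycle,
    ``q = 1 - exp(-(a/b)(e^(b(age+1/2)) - e^(b*age)))`` (reducing to
    ``1 - exp(-a/2)`` for b = 0), so the discrete survival curve coincides
    with the continuous Gompertz survival on the age grid.  The terminal age
    (110 by default) is forced to probability 1 so the cohort closes out.
    Parameters whose implied probability saturates before age 100 raise
    :class:`CalibrationError`.
    """
    if gompertz_a <= 0 or gompertz_b < 0:
        raise ValidationError("Gompertz parameters must satisfy a > 0, b >= 0")
    ages_arr = np.arange(MIN_AGE, MAX_AGE + 1, dtype=float) if ages is None else np.asarray(ages, dtype=float)
    if gompertz_b == 0:
        cumulative = np.full_like(ages_arr, 0.5 * gompertz_a)
    else:
        cumulative = (
            gompertz_a / gompertz_b
            * (np.exp(gompertz_b * (ages_arr + 0.5)) - np.exp(gompertz_b * ages_arr))
        )
    q = 1.0 - np.exp(-np.clip(cumulative, 0, 700))
    before_100 = ages_arr < 100
    if np.any(q[before_100] >= 1.0 - 1e-12):
        raise CalibrationError(
            "Gompertz parameters saturate the death probability before age 100"
        )
    q[-1] = 1.0
    return LifeTable(ages=ages_arr, q6m=q)


def life_expectancy(life_table: LifeTable, age: float) -> float:
    """Remaining life expectancy by brute-force summation of 6-month survival."""
    e, surv, a = 0.0, 1.0, float(age)
    while a < life_table.ages[-1] and surv > 1e-12:
        q = float(life_table.q(a))
        # Deaths within the cycle contribute a quarter-year on average.
        e += surv * (1.0 - q) * 0.5 + surv * q * 0.25
        surv *= 1.0 - q
        a += 0.5
    return e


@dataclass(frozen=True)
class CalibrationExposure:
    """Treated-population context the hazard calibration must reproduce.

    ``product_patients`` maps product id to patient count in the calibration
    year; ``profiles`` supplies each product's compliance-weighted efficacy.
    """

    product_patients: Mapping[str, float]
    profiles: Mapping[str, TreatmentProfile]
    age_mix: tuple[tuple[float, float], ...] = DEFAULT_AGE_MIX

    def __post_init__(self) -> None:
        for product in self.product_patients:
            if product not in self.profiles:
                raise ValidationError(f"no treatment profile for product {product!r}")
        wsum = sum(w for _, w in self.age_mix)
        if abs(wsum - 1.0) > 1e-9:
            raise ValidationError("age mix weights must sum to 1")


def treated_annual_probability(
    hazards: BaselineHazards,
    fracture_type: str,
    profile: TreatmentProfile,
    age_mix: tuple[tuple[float, float], ...] = DEFAULT_AGE_MIX,
) -> float:
    """Age-mix-averaged annual fracture probability under compliance-weighted efficacy."""
    reduction = 1.0 - profile.compliance * profile.rrr(fracture_type)
    return sum(
        w * float(hazards.annual(fracture_type, a)) * reduction for a, w in age_mix
    )


def _expected_count(
    hazards: BaselineHazards, fracture_type: str, exposure: CalibrationExposure
) -> float:
    return sum(
        n
        * treated_annual_probability(
            hazards, fracture_type, exposure.profiles[p], exposure.age_mix
        )
        for p, n in exposure.product_patients.items()
    )


def make_baseline_hazards(
    calibration: Mapping[str, float],
    exposure: CalibrationExposure,
    gradients: Mapping[str, float] | None = None,
    excess_mortality_hip: float = 2.0,
    seed: int = 0,
    rtol: float = 1e-10,
) -> BaselineHazards:
    """Calibrate age-specific hazards to target annual fracture counts.

    For each fracture type the reference probability at age 65 is solved so
    that applying the hazards to ``exposure`` (patient counts per product,
    each with its compliance-weighted efficacy, averaged over the age mix)
    reproduces ``calibration[type]`` expected fractures.  Deterministic;
    zero targets give zero hazards; infeasible targets raise
    :class:`CalibrationError`.
    """
    gradients = dict(gradients or {"hip": 0.05, "vertebral": 0.03, "other": 0.01})
    for t, target in calibration.items():
        if target < 0:
            raise CalibrationError(f"target count for {t!r} must be >= 0")

    p_ref: dict[str, float] = {f: 0.0 for f in FRACTURE_TYPES}
    for ftype in FRACTURE_TYPES:
        target = float(calibration.get(ftype, 0.0))
        if target == 0.0:
            continue
        g = float(gradients.get(ftype, 0.0))
        oldest = max(a for a, _ in exposure.age_mix)
        # Keep the schedule a genuine probability across the whole age range.
        p_max = 0.999 * math.exp(-abs(g) * (MAX_AGE - 65.0))

        def count_at(p65: float, _f=ftype) -> float:
            hz = BaselineHazards.from_parametric(
                {**{f: 0.0 for f in FRACTURE_TYPES}, _f: p65},
                gradients,
                excess_mortality_hip=excess_mortality_hip,
            )
            return _expected_count(hz, _f, exposure)

        upper = count_at(p_max)
        if upper < target:
            raise CalibrationError(
                f"target of {target:.0f} {ftype} fractures requires probabilities > 1"
            )
        p_ref[ftype] = brentq(
            lambda p: count_at(p) - target, 0.0, p_max, xtol=1e-15, rtol=1e-14
        )

    hazards = BaselineHazards.from_parametric(
        p_ref, gradients, excess_mortality_hip=excess_mortality_hip
    )
    for ftype in FRACTURE_TYPES:
        target = float(calibration.get(ftype, 0.0))
        got = _expected_count(hazards, ftype, exposure)
        if target > 0 and abs(got / target - 1.0) > max(rtol, 1e-6):
            raise CalibrationError(
                f"calibration failed to converge for {ftype!r}: {got} vs {target}"
            )
    return hazards


def make_population_projection(
    base_counts: Mapping[str, float],
    annual_growth: float,
    base_year: int = 2010,
    years: Iterable[int] = (2010, 2011, 2012, 2013),
) -> PopulationProjection:
    """Geometric projection of per-band population counts.

    ``annual_growth`` is a fraction per year; growth below -1 is nonsense and
    raises, growth outside +/-5 %/year violates the projection invariant.
    """
    if annual_growth <= -1.0:
        raise ValidationError("annual_growth must be > -1")
    if any(v <= 0 for v in base_counts.values()):
        raise ValidationError("base_counts must be > 0")
    counts = {
        int(year): {
            band: float(n) * (1.0 + annual_growth) ** (year - base_year)
            for band, n in base_counts.items()
        }
        for year in years
    }
    return PopulationProjection(counts=counts)
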