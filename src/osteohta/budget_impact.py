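"""Three-component budget-impact model for the introduction of denosumab.

The model multiplies a demographic projection (women aged 45+) by per-year
treatment uptake to obtain the treated population, splits it over the
available products by market share (the technology-prediction component),
and applies each product's compliance-weighted anti-fracture efficacy to
age-averaged baseline hazards (the disease component).  Two worlds are
compared: "with denosumab" uses the observed share table; "without
denosumab" redistributes denosumab's share over the products it displaces
(oral ibandronate and strontium ranelate by default, weighted by their
published spend erosion).  Outputs are per-year fracture counts by site and
per-year costs in four payer categories (medications, inpatient, outpatient,
community), and their with-minus-without deltas in thousands of euros
(negative = saving).

Fracture counting is expectation-based (deterministic); a sampling mode for
uncertainty runs is provided by ``sample_fractures``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .parameters import (
    FRACTURE_TYPES,
    CostUtilityCatalogue,
    MarketShareTable,
    ModelParameters,
    TreatmentProfile,
    ValidationError,
    load_parameters,
    load_printed_tables,
)
from .synthetic_inputs import (
    DEFAULT_AGE_MIX,
    BaselineHazards,
    CalibrationExposure,
    PopulationProjection,
    make_baseline_hazards,
    make_population_projection,
    treated_annual_probability,
)

__all__ = [
    "COST_CATEGORIES",
    "TreatedPopulation",
    "ScenarioOutcome",
    "BudgetImpact",
    "CostingRule",
    "project_treated",
    "calibrate_uptake",
    "apply_market_shares",
    "expected_fractures",
    "sample_fractures",
    "scenario_outcome",
    "fractures_avoided",
    "compute_budget_impact",
    "inpatient_share",
    "round_half_away_from_zero",
    "run_default_bim",
]

COST_CATEGORIES = ("medications", "inpatient", "outpatient", "community")


def round_half_away_from_zero(x: float) -> int:
    """Rounding used for reporting in thousands of euros (0.5 rounds away from 0)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class TreatedPopulation:
    """Treated patients per year, optionally split per product."""

    totals: Mapping[int, float]
    by_product: Mapping[int, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for year, total in self.totals.items():
            if total < 0:
                raise ValidationError(f"treated count for {year} must be >= 0")
            if year in self.by_product:
                split = sum(self.by_product[year].values())
                if any(v < 0 for v in self.by_product[year].values()):
                    raise ValidationError(f"negative product count in {year}")
                if abs(split - total) > 1e-6 * max(total, 1.0):
                    raise ValidationError(
                        f"product counts for {year} sum to {split}, not {total}"
                    )

    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.totals))


@dataclass(frozen=True)
class ScenarioOutcome:
    """Per-year fracture counts by site and costs by payer category."""

    fractures: Mapping[int, Mapping[str, float]]
    costs: Mapping[int, Mapping[str, float]]

    def __post_init__(self) -> None:
        for year, counts in self.fractures.items():
            if any(v < 0 for v in counts.values()):
                raise ValidationError(f"negative fracture count in {year}")
        for year, cats in self.costs.items():
            missing = [c for c in COST_CATEGORIES if c not in cats]
            if missing:
                raise ValidationError(f"missing cost categories {missing} in {year}")
            if any(v < 0 for v in cats.values()):
                raise ValidationError(f"negative category cost in {year}")

    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.fractures))


@dataclass(frozen=True)
class BudgetImpact:
    """With-minus-without cost deltas per year and category, in EUR.

    ``in_thousands`` reports rounded thousands of euros (half away from
    zero), the convention of the published budget table; totals are rounded
    from the unrounded sum, so the category rows add up to the total within
    the rounding unit.
    """

    deltas: Mapping[int, Mapping[str, float]]  # year -> category -> EUR

    def total(self, year: int) -> float:
        return sum(self.deltas[year].values())

    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.deltas))

    def in_thousands(self) -> dict[int, dict[str, int]]:
        out: dict[int, dict[str, int]] = {}
        for year in self.years():
            row = {
                cat: round_half_away_from_zero(self.deltas[year][cat] / 1000.0)
                for cat in COST_CATEGORIES
            }
            row["total"] = round_half_away_from_zero(self.total(year) / 1000.0)
            out[year] = row
        return out

    @classmethod
    def from_category_deltas_keur(
        cls, deltas_keur: Mapping[str, Mapping[int, float]]
    ) -> "BudgetImpact":
        """Build from per-category deltas given in thousands of euros."""
        years = sorted({y for row in deltas_keur.values() for y in row})
        missing = [c for c in COST_CATEGORIES if c not in deltas_keur]
        if missing:
            raise ValidationError(f"missing cost categories {missing}")
        return cls(
            {
                year: {
                    cat: 1000.0 * float(deltas_keur[cat].get(year, 0.0))
                    for cat in COST_CATEGORIES
                }
                for year in years
            }
        )


def project_treated(
    projection: PopulationProjection, uptake: Mapping[int, float]
) -> TreatedPopulation:
    """Treated patients per year as population x treatment rate.

    ``uptake`` maps each model year to the fraction of women 45+ who are
    osteoporotic and on antiosteoporotic therapy (disease prevalence and
    treatment rate collapsed into one rate).
    """
    totals = {}
    for year, rate in uptake.items():
        if not 0.0 <= rate <= 1.0:
            raise ValidationError(f"uptake rate for {year} must be in [0, 1]")
        totals[int(year)] = projection.total(year) * rate
    return TreatedPopulation(totals=totals)


def calibrate_uptake(
    projection: PopulationProjection,
    shares: MarketShareTable,
    denosumab_patients: Mapping[int, float],
    product: str = "denosumab",
) -> dict[int, float]:
    """Per-year treated rates honoring published patient-count anchors.

    Years with an anchor get the rate that makes ``share x treated``
    reproduce the anchor exactly.  Years without one interpolate the implied
    treated totals geometrically between the neighbouring anchors (constant
    extrapolation at the ends; years before the product enters the market
    use the first anchored total).
    """
    anchored_totals: dict[int, float] = {}
    for year, n in denosumab_patients.items():
        s = shares.share(year, product)
        if s <= 0:
            raise ValidationError(
                f"cannot anchor {n} {product} patients in {year}: share is 0"
            )
        anchored_totals[int(year)] = float(n) / s
    if not anchored_totals:
        raise ValidationError("at least one patient-count anchor is required")

    anchor_years = sorted(anchored_totals)
    totals: dict[int, float] = {}
    for year in projection.years():
        if year in anchored_totals:
            totals[year] = anchored_totals[year]
        elif year < anchor_years[0]:
            totals[year] = anchored_totals[anchor_years[0]]
        elif year > anchor_years[-1]:
            totals[year] = anchored_totals[anchor_years[-1]]
        else:
            lo = max(y for y in anchor_years if y < year)
            hi = min(y for y in anchor_years if y > year)
            frac = (year - lo) / (hi - lo)
            totals[year] = math.exp(
                (1 - frac) * math.log(anchored_totals[lo])
                + frac * math.log(anchored_totals[hi])
            )
    return {year: totals[year] / projection.total(year) for year in totals}


def apply_market_shares(
    treated: TreatedPopulation,
    shares: MarketShareTable,
    scenario: str = "with",
    denosumab_product: str = "denosumab",
    displaced_weights: Mapping[str, float] | None = None,
) -> TreatedPopulation:
    """Split the treated totals over products for one scenario.

    ``scenario="with"`` uses the share table as given; ``"without"``
    removes denosumab and redistributes its share over the displaced
    products in proportion to ``displaced_weights``.
    """
    if scenario not in ("with", "without"):
        raise ValueError("scenario must be 'with' or 'without'")
    displaced_weights = displaced_weights or {
        "ibandronate": 0.24,
        "strontium_ranelate": 0.76,
    }
    wsum = sum(displaced_weights.values())
    if wsum <= 0:
        raise ValidationError("displaced weights must sum to > 0")

    by_product: dict[int, dict[str, float]] = {}
    for year in treated.years():
        if year not in shares.shares:
            raise KeyError(f"no market shares for scenario year {year}")
        row = dict(shares.shares[year])
        if scenario == "without":
            freed = row.pop(denosumab_product, 0.0)
            for product, w in displaced_weights.items():
                row[product] = row.get(product, 0.0) + freed * w / wsum
        total = treated.totals[year]
        by_product[year] = {p: total * s for p, s in row.items()}
    return TreatedPopulation(totals=dict(treated.totals), by_product=by_product)


def expected_fractures(
    treated: TreatedPopulation,
    profiles: Mapping[str, TreatmentProfile],
    hazards: BaselineHazards,
    age_mix: tuple[tuple[float, float], ...] = DEFAULT_AGE_MIX,
) -> dict[int, dict[str, float]]:
    """Expected yearly fracture counts by site across all treated products.

    Per product: patients x age-averaged annual fracture probability under
    the product's compliance-weighted efficacy.
    """
    out: dict[int, dict[str, float]] = {}
    for year in treated.years():
        if year not in treated.by_product:
            raise ValidationError(f"no per-product split for {year}; apply shares first")
        counts = {}
        for ftype in FRACTURE_TYPES:
            total = 0.0
            for product, n in treated.by_product[year].items():
                if product not in profiles:
                    raise KeyError(f"no treatment profile for product {product!r}")
                total += n * treated_annual_probability(
                    hazards, ftype, profiles[product], age_mix
                )
            counts[ftype] = total
        out[year] = counts
    return out


def sample_fractures(
    expected: Mapping[int, Mapping[str, float]],
    seed: int,
) -> dict[int, dict[str, int]]:
    """Poisson sampling mode around the expected counts, for uncertainty runs."""
    rng = np.random.default_rng(seed)
    return {
        year: {f: int(rng.poisson(lam)) for f, lam in counts.items()}
        for year, counts in expected.items()
    }


@dataclass(frozen=True)
class CostingRule:
    """How fracture counts and drug use turn into the four payer categories.

    Medications: patients x annual price, with noncompliant patients paying
    half a year.  Inpatient: acute tariff per fracture at the event.
    Outpatient: a fraction of the acute tariff in the event year.  Community:
    a per-hip nursing cost accruing the year after the fracture.
    """

    outpatient_fraction: float = 0.213
    community_cost_per_hip: float = 6700.0

    def __post_init__(self) -> None:
        if self.outpatient_fraction < 0 or self.community_cost_per_hip < 0:
            raise ValidationError("costing-rule amounts must be >= 0")


def scenario_outcome(
    treated: TreatedPopulation,
    profiles: Mapping[str, TreatmentProfile],
    hazards: BaselineHazards,
    catalogue: CostUtilityCatalogue,
    costing: CostingRule | None = None,
    age_mix: tuple[tuple[float, float], ...] = DEFAULT_AGE_MIX,
) -> ScenarioOutcome:
    """Full per-year outcome (fracture counts and category costs) for one world."""
    costing = costing or CostingRule()
    fractures = expected_fractures(treated, profiles, hazards, age_mix)
    unit = catalogue.unit_cost_by_fracture

    costs: dict[int, dict[str, float]] = {}
    years = sorted(fractures)
    for i, year in enumerate(years):
        meds = sum(
            n
            * profiles[p].annual_drug_cost
            * (profiles[p].compliance + 0.5 * (1.0 - profiles[p].compliance))
            for p, n in treated.by_product[year].items()
        )
        inpatient = sum(fractures[year][f] * unit[f] for f in FRACTURE_TYPES)
        outpatient = inpatient * costing.outpatient_fraction
        prev_hip = fractures[years[i - 1]]["hip"] if i > 0 else 0.0
        community = prev_hip * costing.community_cost_per_hip
        costs[year] = {
            "medications": meds,
            "inpatient": inpatient,
            "outpatient": outpatient,
            "community": community,
        }
    return ScenarioOutcome(fractures=fractures, costs=costs)


def fractures_avoided(
    with_scenario: ScenarioOutcome | Mapping[int, Mapping[str, float]],
    without_scenario: ScenarioOutcome | Mapping[int, Mapping[str, float]],
) -> dict[int, dict[str, float]]:
    """Fractures avoided per year and site: without-world minus with-world."""
    wf = with_scenario.fractures if isinstance(with_scenario, ScenarioOutcome) else with_scenario
    of = without_scenario.fractures if isinstance(without_scenario, ScenarioOutcome) else without_scenario
    if sorted(wf) != sorted(of):
        raise ValidationError("scenario years do not match")
    return {
        year: {f: of[year][f] - wf[year][f] for f in of[year]}
        for year in sorted(of)
    }


def compute_budget_impact(
    with_scenario: ScenarioOutcome, without_scenario: ScenarioOutcome
) -> BudgetImpact:
    """Per-year, per-category cost delta of the with-denosumab world."""
    if sorted(with_scenario.costs) != sorted(without_scenario.costs):
        raise ValidationError("scenario years do not match")
    deltas = {
        year: {
            cat: with_scenario.costs[year][cat] - without_scenario.costs[year][cat]
            for cat in COST_CATEGORIES
        }
        for year in sorted(with_scenario.costs)
    }
    return BudgetImpact(deltas=deltas)


def inpatient_share(impact: BudgetImpact, year: int) -> float:
    """Inpatient share of the avoided fracture costs in one year.

    Fraction of the non-medication (fracture-related) cost delta magnitude
    attributable to inpatient care.
    """
    row = impact.deltas[year]
    fracture_related = sum(abs(row[c]) for c in ("inpatient", "outpatient", "community"))
    if fracture_related == 0:
        raise ValidationError(f"no fracture-related cost delta in {year}")
    return abs(row["inpatient"]) / fracture_related


def run_default_bim(
    params: ModelParameters | None = None,
    calibration_targets: Mapping[str, float] | None = None,
    seed: int = 0,
) -> dict[str, Any]:
    """Full budget-impact pipeline on the packaged default configuration.

    Builds the demographic projection, calibrates per-year uptake to the
    published denosumab patient anchors, calibrates baseline fracture hazards
    so the pre-entry year reproduces the published fracture counts (the
    "other" target, never published, defaults to the hip target scaled by the
    hospitalization mix), then evaluates both worlds and their budget impact.
    """
    params = params or load_parameters()
    cfg = params.config["budget_impact"]
    pop_cfg = cfg["population"]
    projection = make_population_projection(
        {str(b): float(n) for b, n in pop_cfg["counts"].items()},
        float(pop_cfg["annual_growth"]),
        base_year=int(pop_cfg["base_year"]),
        years=[int(y) for y in cfg["years"]],
    )
    uptake = calibrate_uptake(
        projection,
        params.market_shares,
        {int(y): float(n) for y, n in cfg["denosumab_patient_anchors"].items()},
    )
    treated = project_treated(projection, uptake)
    displaced = {str(p): float(w) for p, w in cfg["displaced_weights"].items()}
    with_world = apply_market_shares(treated, params.market_shares, "with")
    without_world = apply_market_shares(
        treated, params.market_shares, "without", displaced_weights=displaced
    )

    if calibration_targets is None:
        printed = load_printed_tables()["scenario_fractures"]
        base_year = min(int(y) for y in cfg["years"])
        hip_target = float(printed["hip"]["without"][base_year])
        vert_target = float(printed["vertebral"]["without"][base_year])
        hosp = load_printed_tables()["hospitalizations"]
        other_ratio = hosp["other"]["admissions"] / hosp["hip_femur"]["admissions"]
        calibration_targets = {
            "hip": hip_target,
            "vertebral": vert_target,
            "other": hip_target * other_ratio,
        }
    base_year = min(treated.years())
    age_mix = tuple(
        (float(a), float(w)) for a, w in sorted(cfg["age_mix"].items(), key=lambda kv: float(kv[0]))
    )
    exposure = CalibrationExposure(
        product_patients=dict(with_world.by_product[base_year]),
        profiles=params.treatments,
        age_mix=age_mix,
    )
    hazards = make_baseline_hazards(
        calibration_targets,
        exposure,
        gradients={str(k): float(v) for k, v in cfg["hazard_gradients"].items()},
        seed=seed,
    )
    costing = CostingRule(
        outpatient_fraction=float(cfg["outpatient_cost_fraction"]),
        community_cost_per_hip=float(cfg["community_cost_per_hip"]),
    )
    with_outcome = scenario_outcome(
        with_world, params.treatments, hazards, params.catalogue, costing, age_mix
    )
    without_outcome = scenario_outcome(
        without_world, params.treatments, hazards, params.catalogue, costing, age_mix
    )
    return {
        "projection": projection,
        "uptake": uptake,
        "treated": treated,
        "with_world": with_world,
        "without_world": without_world,
        "hazards": hazards,
        "calibration_targets": dict(calibration_targets),
        "with_outcome": with_outcome,
        "without_outcome": without_outcome,
        "avoided": fractures_avoided(with_outcome, without_outcome),
        "impact": compute_budget_impact(with_outcome, without_outcome),
    }
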