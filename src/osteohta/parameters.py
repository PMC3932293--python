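"""Typed containers, validators and loaders for the model inputs.

The economic models need four kinds of published inputs: per-drug efficacy
(relative risk reductions by fracture site) with compliance and price, acute
fracture costs with health-state utilities, per-year market shares of the
available products, and the discounting convention (3 %/year on six-month
cycles).  This module defines validated containers for each, YAML loaders
with a packaged default fixture, and the small efficacy-conversion helpers
(risk ratio from cumulative incidences, relative risk reduction from a risk
ratio) used to derive efficacy inputs from trial results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Mapping

import yaml

__all__ = [
    "FRACTURE_TYPES",
    "ParameterError",
    "SchemaError",
    "ValidationError",
    "UndefinedRatioError",
    "HarmfulEffectWarning",
    "TreatmentProfile",
    "CostUtilityCatalogue",
    "MarketShareTable",
    "DiscountSpec",
    "ModelParameters",
    "load_parameters",
    "save_parameters",
    "load_printed_tables",
    "rr_from_cumulative_incidence",
    "rrr_from_rr",
]

#: Fracture sites modelled throughout the package.
FRACTURE_TYPES = ("hip", "vertebral", "other")


class ParameterError(ValueError):
    """Base class for invalid model inputs."""


class SchemaError(ParameterError):
    """A required field is missing or has the wrong type; names the field."""


class ValidationError(ParameterError):
    """A field is present but violates a domain invariant."""


class UndefinedRatioError(ParameterError):
    """A risk ratio was requested with a zero denominator."""


class HarmfulEffectWarning(UserWarning):
    """Raised (as a warning) when a risk ratio above 1 is floored to RRR 0."""


def _require(mapping: Mapping[str, Any], key: str, context: str) -> Any:
    if key not in mapping:
        raise SchemaError(f"missing field {key!r} in {context}")
    return mapping[key]


def _check_fraction(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class TreatmentProfile:
    """One drug's anti-fracture efficacy, adherence and cost assumptions.

    Efficacy is expressed as relative risk reductions (RRR, fractions of
    baseline risk removed) for hip/femoral, vertebral and non-hip
    non-vertebral ("other") fractures.  ``compliance`` is the fraction of
    patients who persist on therapy; ``offset_time`` is the number of years
    over which efficacy decays to zero after discontinuation.
    """

    name: str
    rrr_hip: float
    rrr_vertebral: float
    rrr_other: float
    compliance: float
    annual_drug_cost: float
    treatment_duration: float = 5.0
    offset_time: float = 1.0
    label: str = ""
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for fname in ("rrr_hip", "rrr_vertebral", "rrr_other", "compliance"):
            _check_fraction(getattr(self, fname), f"{self.name}.{fname}")
        if self.annual_drug_cost < 0:
            raise ValidationError(f"{self.name}.annual_drug_cost must be >= 0")
        if self.treatment_duration <= 0:
            raise ValidationError(f"{self.name}.treatment_duration must be > 0")
        if self.offset_time < 0:
            raise ValidationError(f"{self.name}.offset_time must be >= 0")
        if not self.label:
            object.__setattr__(self, "label", self.name)

    def rrr(self, fracture_type: str) -> float:
        """Relative risk reduction for one of the modelled fracture sites."""
        try:
            return {
                "hip": self.rrr_hip,
                "vertebral": self.rrr_vertebral,
                "other": self.rrr_other,
            }[fracture_type]
        except KeyError:
            raise KeyError(f"unknown fracture type {fracture_type!r}") from None

    def effective_rrr(self, fracture_type: str, weight: float = 1.0) -> float:
        """RRR scaled by an efficacy weight (e.g. compliance or offset decay)."""
        return self.rrr(fracture_type) * weight


@dataclass(frozen=True)
class CostUtilityCatalogue:
    """Acute fracture costs and health-state utility weights.

    ``unit_cost_by_fracture`` holds the acute-episode cost per modelled site,
    with "other" pooled from a configurable mix of the published sub-table.
    Utilities distinguish the first year after fracture from subsequent
    years; an ``utility_subsequent`` entry equal to the healthy utility means
    the state recovers fully after the first year.
    """

    unit_cost_by_fracture: Mapping[str, float]
    utility_first_year: Mapping[str, float]
    utility_subsequent: Mapping[str, float]
    utility_healthy: float
    other_cost_breakdown: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_fraction(self.utility_healthy, "utility_healthy")
        for ftype in FRACTURE_TYPES:
            if ftype not in self.unit_cost_by_fracture:
                raise SchemaError(f"missing field unit cost for {ftype!r}")
            if self.unit_cost_by_fracture[ftype] < 0:
                raise ValidationError(f"unit cost for {ftype!r} must be >= 0")
            for table, tname in (
                (self.utility_first_year, "utility_first_year"),
                (self.utility_subsequent, "utility_subsequent"),
            ):
                if ftype not in table:
                    raise SchemaError(f"missing field {tname}[{ftype!r}]")
                _check_fraction(table[ftype], f"{tname}[{ftype!r}]")


@dataclass(frozen=True)
class MarketShareTable:
    """Per-year market shares (fractions summing to 1) for each product."""

    shares: Mapping[int, Mapping[str, float]]

    def __post_init__(self) -> None:
        for year, row in self.shares.items():
            total = sum(row.values())
            if any(v < 0 for v in row.values()):
                raise ValidationError(f"negative share in year {year}")
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"market shares for {year} sum to {total:.6f}, not 1"
                )

    @classmethod
    def from_raw(
        cls, raw: Mapping[int, Mapping[str, float]], tolerance: float = 0.01
    ) -> "MarketShareTable":
        """Normalize raw share columns that may carry printed rounding.

        Columns whose raw sum deviates from 1 by more than ``tolerance``
        (e.g. a column summing to 0.9) are rejected.
        """
        normalized: dict[int, dict[str, float]] = {}
        for year, row in raw.items():
            row = {p: float(v) for p, v in row.items()}
            if any(v < 0 for v in row.values()):
                raise ValidationError(f"negative share in year {year}")
            total = sum(row.values())
            if abs(total - 1.0) > tolerance:
                raise ValidationError(
                    f"market shares for {year} sum to {total * 100:.1f}%, "
                    f"outside the {tolerance * 100:.0f}% tolerance around 100%"
                )
            if abs(total - 1.0) <= 1e-12:  # already normalized; keep exact
                normalized[int(year)] = row
            else:
                normalized[int(year)] = {p: v / total for p, v in row.items()}
        return cls(normalized)

    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.shares))

    def products(self, year: int) -> tuple[str, ...]:
        return tuple(self.shares[year])

    def share(self, year: int, product: str) -> float:
        try:
            return self.shares[year].get(product, 0.0)
        except KeyError:
            raise KeyError(f"no market shares for year {year}") from None


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate applied on a fixed six-month cycle grid."""

    annual_rate: float = 0.03
    cycle_length: float = 0.5

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValidationError("annual_rate must be >= 0")
        if self.cycle_length != 0.5:
            raise ValidationError("cycle_length is fixed at 0.5 years")

    def factor(self, years_elapsed: float) -> float:
        """Discount factor (1 + r)^(-t) for an amount accruing t years out."""
        return (1.0 + self.annual_rate) ** (-years_elapsed)


@dataclass(frozen=True)
class ModelParameters:
    """Bundle of all loaded inputs plus the raw config for extensions."""

    treatments: Mapping[str, TreatmentProfile]
    catalogue: CostUtilityCatalogue
    market_shares: MarketShareTable
    discount: DiscountSpec
    config: Mapping[str, Any] = field(default_factory=dict, repr=False)


def _pooled_other_cost(cu: Mapping[str, Any]) -> float:
    costs = {k: float(v) for k, v in _require(cu, "other_fracture_costs", "costs_utilities").items()}
    mix = cu.get("other_fracture_mix") or {k: 1.0 for k in costs}
    total_w = sum(float(w) for w in mix.values())
    if total_w <= 0:
        raise ValidationError("other_fracture_mix weights must sum to > 0")
    return sum(costs[k] * float(w) for k, w in mix.items()) / total_w


def _build_catalogue(cu: Mapping[str, Any]) -> CostUtilityCatalogue:
    unit = _require(cu, "unit_costs", "costs_utilities")
    healthy = float(_require(cu, "healthy_utility", "costs_utilities"))
    utilities = _require(cu, "utilities", "costs_utilities")
    first, subsequent = {}, {}
    for ftype in FRACTURE_TYPES:
        entry = _require(utilities, ftype, "costs_utilities.utilities")
        first[ftype] = float(_require(entry, "first_year", f"utilities[{ftype}]"))
        sub = entry.get("subsequent")
        subsequent[ftype] = healthy if sub is None else float(sub)
    return CostUtilityCatalogue(
        unit_cost_by_fracture={
            "hip": float(_require(unit, "hip", "unit_costs")),
            "vertebral": float(_require(unit, "vertebral", "unit_costs")),
            "other": _pooled_other_cost(cu),
        },
        utility_first_year=first,
        utility_subsequent=subsequent,
        utility_healthy=healthy,
        other_cost_breakdown={
            k: float(v) for k, v in cu["other_fracture_costs"].items()
        },
    )


def _build_profile(name: str, entry: Mapping[str, Any]) -> TreatmentProfile:
    return TreatmentProfile(
        name=name,
        rrr_hip=float(_require(entry, "rrr_hip", f"treatments.{name}")),
        rrr_vertebral=float(_require(entry, "rrr_vertebral", f"treatments.{name}")),
        rrr_other=float(_require(entry, "rrr_other", f"treatments.{name}")),
        compliance=float(_require(entry, "compliance", f"treatments.{name}")),
        annual_drug_cost=float(_require(entry, "annual_drug_cost", f"treatments.{name}")),
        treatment_duration=float(entry.get("treatment_duration", 5.0)),
        offset_time=float(entry.get("offset_time", 1.0)),
        label=str(entry.get("label", name)),
        aliases=tuple(entry.get("aliases", ())),
    )


def default_config() -> dict[str, Any]:
    """Parsed copy of the packaged default parameter fixture."""
    text = resources.files("osteohta.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_parameters(path: str | None = None) -> ModelParameters:
    """Load and validate a full parameter set.

    With no ``path``, the packaged default fixture (the published input
    tables) is used.  Raises :class:`SchemaError` naming the first missing
    field and :class:`ValidationError` on invariant violations (e.g. a
    market-share column not summing to 100 % within tolerance).
    """
    if path is None:
        cfg = default_config()
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("parameter file is not a mapping")

    treatments_cfg = _require(cfg, "treatments", "parameter file")
    treatments = {
        name: _build_profile(name, entry) for name, entry in treatments_cfg.items()
    }
    catalogue = _build_catalogue(_require(cfg, "costs_utilities", "parameter file"))
    shares = MarketShareTable.from_raw(
        {int(y): row for y, row in _require(cfg, "market_shares", "parameter file").items()}
    )
    disc_cfg = _require(cfg, "discount", "parameter file")
    discount = DiscountSpec(
        annual_rate=float(_require(disc_cfg, "annual_rate", "discount")),
        cycle_length=float(disc_cfg.get("cycle_length_years", 0.5)),
    )
    return ModelParameters(treatments, catalogue, shares, discount, cfg)


def save_parameters(params: ModelParameters, path: str) -> None:
    """Write a parameter set back to YAML so that reloading round-trips."""
    cfg = dict(params.config) if params.config else {}
    cfg["discount"] = {
        "annual_rate": params.discount.annual_rate,
        "cycle_length_years": params.discount.cycle_length,
    }
    cfg["treatments"] = {
        name: {
            "label": p.label,
            "aliases": list(p.aliases),
            "rrr_hip": p.rrr_hip,
            "rrr_vertebral": p.rrr_vertebral,
            "rrr_other": p.rrr_other,
            "compliance": p.compliance,
            "annual_drug_cost": p.annual_drug_cost,
            "treatment_duration": p.treatment_duration,
            "offset_time": p.offset_time,
        }
        for name, p in params.treatments.items()
    }
    # Market shares are stored normalized; they reload unchanged.
    cfg["market_shares"] = {
        year: dict(row) for year, row in params.market_shares.shares.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_printed_tables() -> dict[str, Any]:
    """Published summary tables shipped as reference fixtures.

    Keys: ``hospitalizations``, ``discharge_rates_per_100k``,
    ``scenario_fractures``, ``budget_impact_keur``, ``cost_effectiveness``,
    ``vertebral_trial``.
    """
    text = resources.files("osteohta.data").joinpath("printed_tables.yaml").read_text()
    return yaml.safe_load(text)


def rr_from_cumulative_incidence(ci_treated: float, ci_control: float) -> float:
    """Risk ratio from cumulative incidences in treated and control arms."""
    _check_fraction(ci_treated, "ci_treated")
    _check_fraction(ci_control, "ci_control")
    if ci_control == 0:
        raise UndefinedRatioError("control cumulative incidence is zero")
    return ci_treated / ci_control


def rrr_from_rr(rr: float) -> float:
    """Relative risk reduction 1 - RR, floored at 0 for harmful effects.

    A risk ratio above 1 (treatment increases risk) is floored to an RRR of
    0 and flagged with :class:`HarmfulEffectWarning`.
    """
    if rr < 0:
        raise ValidationError(f"risk ratio must be >= 0, got {rr}")
    if rr > 1.0:
        warnings.warn(
            f"risk ratio {rr} > 1 implies a harmful effect; RRR floored to 0",
            HarmfulEffectWarning,
            stacklevel=2,
        )
        return 0.0
    return 1.0 - rr
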