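"""Hospitalization burden-of-illness calculator.

Aggregates hospital admission records for osteoporotic fractures (women aged
45+, reimbursed at DRG tariffs as a proxy of real costs) into per-type
counts and cost totals, the mean cost per admission, and discharge rates per
100,000 women.  Monetary accumulation uses exact decimal (cent) arithmetic
so that published totals are reproduced to the cent; binary floating point
is never used for the sums.

A synthetic record generator is included: it emits one record per admission
with per-type counts matching given marginals exactly and per-record tariffs
drawn from a Gamma shape and then rescaled, cent by cent, to hit the cost
marginal exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .parameters import ValidationError, load_printed_tables

__all__ = [
    "FRACTURE_LABELS",
    "AdmissionRecord",
    "AdmissionTable",
    "aggregate_admissions",
    "mean_cost_per_admission",
    "discharge_rate",
    "generate_admission_records",
    "load_admission_marginals",
]

#: Admission fracture categories (hip and femur pooled, as published).
FRACTURE_LABELS = ("hip_femur", "vertebral", "other")

_CENT = Decimal("0.01")

#: Age bands of the source record selection (optional on records).
AGE_BANDS = ("45-64", "65-74", "75+")


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospital discharge: fracture type, DRG tariff, optional age band."""

    fracture_type: str
    tariff_eur: Decimal
    age_band: str | None = None

    def __post_init__(self) -> None:
        if self.fracture_type not in FRACTURE_LABELS:
            raise ValidationError(
                f"unknown fracture type {self.fracture_type!r}; "
                f"expected one of {FRACTURE_LABELS}"
            )
        object.__setattr__(self, "tariff_eur", Decimal(self.tariff_eur))
        if self.tariff_eur < 0:
            raise ValidationError("tariff must be >= 0")
        if self.age_band is not None and self.age_band not in AGE_BANDS:
            raise ValidationError(f"unknown age band {self.age_band!r}")


@dataclass(frozen=True)
class AdmissionTable:
    """Per-fracture-type admission counts and cent-exact cost sums."""

    rows: Mapping[str, tuple[int, Decimal]]

    def __post_init__(self) -> None:
        for label, (count, cost) in self.rows.items():
            if label not in FRACTURE_LABELS:
                raise ValidationError(f"unknown fracture type {label!r}")
            if count < 0 or int(count) != count:
                raise ValidationError("admission counts must be nonnegative integers")
            if cost < 0:
                raise ValidationError("costs must be >= 0")

    @property
    def total_admissions(self) -> int:
        return sum(count for count, _ in self.rows.values())

    @property
    def total_cost(self) -> Decimal:
        return sum((cost for _, cost in self.rows.values()), Decimal("0.00"))


def aggregate_admissions(
    records: Iterable[AdmissionRecord | tuple],
) -> AdmissionTable:
    """Sum admission records into per-type counts and cent-exact costs.

    Records may be :class:`AdmissionRecord` or ``(fracture_type, tariff)``
    tuples; tariffs are coerced to :class:`~decimal.Decimal`.
    """
    counts = {label: 0 for label in FRACTURE_LABELS}
    costs = {label: Decimal("0.00") for label in FRACTURE_LABELS}
    for rec in records:
        if not isinstance(rec, AdmissionRecord):
            rec = AdmissionRecord(rec[0], Decimal(str(rec[1])))
        counts[rec.fracture_type] += 1
        costs[rec.fracture_type] += rec.tariff_eur
    return AdmissionTable(
        rows={label: (counts[label], costs[label]) for label in FRACTURE_LABELS}
    )


def mean_cost_per_admission(table: AdmissionTable) -> Decimal:
    """Grand total cost over grand total admissions, reported to the cent."""
    n = table.total_admissions
    if n == 0:
        raise ValidationError("mean cost is undefined with zero admissions")
    return (table.total_cost / Decimal(n)).quantize(_CENT, rounding=ROUND_HALF_UP)


def discharge_rate(admissions: int, population: float) -> float:
    """Discharges per 100,000 population, to two decimals."""
    if population <= 0:
        raise ValidationError("population must be > 0")
    if admissions < 0:
        raise ValidationError("admissions must be >= 0")
    return round(admissions / population * 100_000, 2)


def load_admission_marginals() -> dict[str, tuple[int, Decimal]]:
    """Published per-type admission counts and cost totals (EUR 2009)."""
    raw = load_printed_tables()["hospitalizations"]
    return {
        label: (int(entry["admissions"]), Decimal(entry["total_cost"]))
        for label, entry in raw.items()
    }


def generate_admission_records(
    marginals: Mapping[str, tuple[int, Decimal]] | None = None,
    seed: int = 0,
    cv: float = 0.5,
    age_band_weights: Sequence[float] = (0.2, 0.3, 0.5),
) -> list[AdmissionRecord]:
    """Synthetic per-admission records reproducing given marginals exactly.

    For each fracture type, ``count`` tariffs are drawn from a Gamma shape
    around the implied mean tariff (coefficient of variation ``cv``), scaled
    to the cost marginal, floored to cents, and the residual cents are
    assigned to the records with the largest fractional remainders so the
    per-type cost sums match to the cent.  Age bands are sampled with the
    given weights (the published table does not stratify them, so nothing is
    asserted on them).
    """
    marginals = marginals or load_admission_marginals()
    rng = np.random.default_rng(seed)
    records: list[AdmissionRecord] = []
    for label in FRACTURE_LABELS:
        if label not in marginals:
            continue
        count, total_cost = marginals[label]
        count = int(count)
        total_cost = Decimal(total_cost)
        if count == 0:
            if total_cost != 0:
                raise ValidationError(f"{label}: nonzero cost with zero admissions")
            continue
        target_cents = int(
            total_cost.quantize(_CENT, rounding=ROUND_HALF_UP) * 100
        )
        shape = 1.0 / (cv * cv)
        draws = rng.gamma(shape, 1.0 / shape, size=count)
        scaled = draws * (target_cents / draws.sum())
        floor_cents = np.floor(scaled).astype(np.int64)
        residual = int(target_cents - floor_cents.sum())
        if residual < 0 or residual > count:
            # Extremely skewed draws; fall back to a uniform cent split.
            floor_cents = np.full(count, target_cents // count, dtype=np.int64)
            residual = int(target_cents - floor_cents.sum())
        order = np.argsort(-(scaled - floor_cents))
        floor_cents[order[:residual]] += 1
        bands = rng.choice(AGE_BANDS, size=count, p=np.asarray(age_band_weights) / sum(age_band_weights))
        for cents, band in zip(floor_cents, bands):
            records.append(
                AdmissionRecord(
                    fracture_type=label,
                    tariff_eur=Decimal(int(cents)) * _CENT,
                    age_band=str(band),
                )
            )
    return records
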