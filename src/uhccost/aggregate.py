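"""Aggregation of treatment, surgical, salary and overhead costs into
monthly totals and annual per-household / per-person premiums.

Salaries enter as a single monthly scalar (a survey of private-sector
hospital salary structures, base 5.3 million INR/month).  Overhead is an
explicit residual component calibrated per drug scenario so that the base
case reproduces the published annual premiums; see docs/methods.md for why
the published components alone do not annualize to the published premium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .costing import (PriceList, TreatmentProtocol, load_protocols,
                      load_price_list, load_surgical_packages,
                      scale_surgical_package, specialty_monthly_treatment_cost)
from .params import SpecialtyProfile, ValidationError, _data_path

__all__ = [
    "CostSummary",
    "MONTHLY_SALARY_INR",
    "MONTHLY_OVERHEAD_INR",
    "total_monthly_treatment",
    "scenario_cost_ratio",
    "annual_premiums",
    "treatment_cost_table",
    "default_surgical_monthly",
]

#: Monthly staff-salary bill for the reference hospital, INR.
MONTHLY_SALARY_INR = 5_300_000.0

#: Residual monthly overhead per drug scenario, INR (calibrated; see docs).
MONTHLY_OVERHEAD_INR = {"generic": 644_459.0, "branded": 1_344_836.0}

MONTHS_PER_YEAR = 12


@dataclass(frozen=True)
class CostSummary:
    """Monthly recurrent cost decomposition and annual premiums, one scenario."""

    scenario: str
    monthly_treatment_opd: float
    monthly_treatment_ipd: float
    monthly_surgical: float
    monthly_salary: float
    monthly_overhead: float
    annual_total: float
    annual_per_household: float
    annual_per_person: float

    @property
    def monthly_total(self) -> float:
        return (self.monthly_treatment_opd + self.monthly_treatment_ipd
                + self.monthly_surgical + self.monthly_salary + self.monthly_overhead)


def total_monthly_treatment(
    specialty_costs: Mapping[str, tuple[float, float]] | Sequence[tuple[float, float]],
    surgical: float,
) -> float:
    """Sum per-specialty (OPD, IPD) pairs plus the surgical package line."""
    pairs = (specialty_costs.values() if isinstance(specialty_costs, Mapping)
             else specialty_costs)
    pairs = list(pairs)
    if surgical < 0 or any(o < 0 or i < 0 for o, i in pairs):
        raise ValidationError("cost components must be non-negative")
    return sum(o for o, _ in pairs) + sum(i for _, i in pairs) + surgical


def scenario_cost_ratio(branded_total: float, generic_total: float) -> float:
    """How many times costlier the branded scenario is than the generic one."""
    if generic_total <= 0:
        raise ValidationError("generic_total must be strictly positive")
    return branded_total / generic_total


def annual_premiums(
    monthly_treatment_opd: float,
    monthly_treatment_ipd: float,
    monthly_surgical: float,
    population: float,
    household_size: float,
    scenario: str = "generic",
    monthly_salary: float = MONTHLY_SALARY_INR,
    monthly_overhead: float | None = None,
) -> CostSummary:
    """Annualize monthly components and spread them over households.

    annual_total = 12 x sum(components);
    per_household = annual_total / (population / household_size);
    per_person = per_household / household_size.
    """
    if population <= 0:
        raise ValidationError("population must be strictly positive")
    if household_size <= 0:
        raise ValidationError("household_size must be strictly positive")
    if monthly_overhead is None:
        monthly_overhead = MONTHLY_OVERHEAD_INR.get(scenario, 0.0)
    components = (monthly_treatment_opd, monthly_treatment_ipd, monthly_surgical,
                  monthly_salary, monthly_overhead)
    if any(c < 0 for c in components):
        raise ValidationError("cost components must be non-negative")
    annual_total = MONTHS_PER_YEAR * sum(components)
    households = population / household_size
    per_household = annual_total / households
    return CostSummary(
        scenario=scenario,
        monthly_treatment_opd=monthly_treatment_opd,
        monthly_treatment_ipd=monthly_treatment_ipd,
        monthly_surgical=monthly_surgical,
        monthly_salary=monthly_salary,
        monthly_overhead=monthly_overhead,
        annual_total=annual_total,
        annual_per_household=per_household,
        annual_per_person=per_household / household_size,
    )


def default_surgical_monthly(scaling: float = 0.5) -> float:
    """Monthly surgical cost: shipped package rates scaled to hospital cost."""
    packages = load_surgical_packages(_data_path("surgical_packages.csv"))
    return sum(scale_surgical_package(rate, scaling) for rate in packages.values())


def treatment_cost_table(
    profiles: Sequence[SpecialtyProfile],
    protocols: Sequence[TreatmentProtocol] | None = None,
    prices: PriceList | None = None,
    scenario: str = "generic",
    ipd_cost_ratio: float = 10.0,
    visits: Mapping[str, float] | None = None,
    admissions: Mapping[str, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-specialty monthly (OPD, IPD) treatment costs via micro-costing.

    Demand defaults to the profiles' recorded visits and implied admissions;
    pass ``visits``/``admissions`` to cost a different demand scenario.
    Surgical specialties (``costed=False``) are excluded (their costs are in
    the pooled surgical package line).
    """
    if protocols is None:
        protocols = load_protocols(_data_path("protocols.csv"))
    if prices is None:
        prices = load_price_list(_data_path("price_list.csv"))
    by_spec: dict[str, list[TreatmentProtocol]] = {}
    for p in protocols:
        by_spec.setdefault(p.specialty, []).append(p)
    out: dict[str, tuple[float, float]] = {}
    for prof in profiles:
        if not prof.costed:
            continue
        v = visits[prof.name] if visits is not None else prof.monthly_opd_visits
        a = (admissions[prof.name] if admissions is not None
             else prof.monthly_ipd_admissions)
        out[prof.name] = specialty_monthly_treatment_cost(
            v, a, by_spec.get(prof.name, []), prices, scenario, ipd_cost_ratio)
    return out
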