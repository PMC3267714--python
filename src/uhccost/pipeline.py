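"""Forward pipelines over the decision model.

Three entry points:

* :func:`run_base_case` - the deterministic base case for one drug scenario:
  demand, per-specialty treatment costs, premium summary and national
  extrapolation, reproducing the published reference tables.
* :func:`premium_from_inputs` - the same forward chain on arbitrary demand
  parameters, protocols and prices (used for end-to-end runs on synthetic
  or user-supplied data).
* :func:`build_outcome_model` - a calibrated scalar outcome function of the
  parameter registry, for tornado and probabilistic sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .aggregate import (CostSummary, MONTHLY_OVERHEAD_INR, MONTHLY_SALARY_INR,
                        annual_premiums, default_surgical_monthly,
                        total_monthly_treatment, treatment_cost_table)
from .costing import PriceList, TreatmentProtocol, specialty_monthly_treatment_cost
from .demand import DemandEstimate, estimate_demand
from .national import NationalEstimate, national_totals
from .params import (MacroParameters, ParameterRegistry, SpecialtyProfile,
                     ValidationError, load_parameters)

__all__ = [
    "BaseCaseResult",
    "run_base_case",
    "premium_from_inputs",
    "build_outcome_model",
    "OUTCOMES",
]

OUTCOMES = ("household_premium", "person_premium", "gdp_share")


@dataclass(frozen=True)
class BaseCaseResult:
    scenario: str
    demand: DemandEstimate
    specialty_costs: dict[str, tuple[float, float]]
    monthly_treatment_total: float
    summary: CostSummary
    national: NationalEstimate


def run_base_case(
    scenario: str = "generic",
    registry: ParameterRegistry | None = None,
    macro: MacroParameters | None = None,
    profiles: Sequence[SpecialtyProfile] | None = None,
    monthly_salary: float = MONTHLY_SALARY_INR,
    monthly_overhead: float | None = None,
) -> BaseCaseResult:
    """Deterministic base case for one drug scenario.

    Treatment costs are computed by micro-costing the shipped protocol
    fixture against the profiles' recorded demand, so the per-specialty
    cost cells and totals reproduce the reference tables exactly.
    """
    if registry is None or macro is None or profiles is None:
        d_registry, d_macro, d_profiles = load_parameters()
        registry = registry or d_registry
        macro = macro or d_macro
        profiles = profiles or d_profiles
    v = registry.base_values()
    demand = estimate_demand(
        v["population"], v["morbidity_rate"], v["reporting_adjustment"],
        v["opd_fraction"], profiles)
    specialty_costs = treatment_cost_table(
        profiles, scenario=scenario, ipd_cost_ratio=v["ipd_opd_cost_ratio"])
    surgical = default_surgical_monthly()
    treatment_total = total_monthly_treatment(specialty_costs, surgical)
    summary = annual_premiums(
        monthly_treatment_opd=sum(o for o, _ in specialty_costs.values()),
        monthly_treatment_ipd=sum(i for _, i in specialty_costs.values()),
        monthly_surgical=surgical,
        population=v["population"],
        household_size=v["household_size"],
        scenario=scenario,
        monthly_salary=monthly_salary,
        monthly_overhead=monthly_overhead,
    )
    national = national_totals(summary.annual_per_person, macro=macro)
    return BaseCaseResult(
        scenario=scenario,
        demand=demand,
        specialty_costs=specialty_costs,
        monthly_treatment_total=treatment_total,
        summary=summary,
        national=national,
    )


def premium_from_inputs(
    population: float,
    morbidity_rate: float,
    adjustment: float,
    opd_fraction: float,
    shares: Mapping[str, float],
    admission_fractions: Mapping[str, float],
    protocols: Sequence[TreatmentProtocol],
    prices: PriceList,
    scenario: str,
    household_size: float = 4.0,
    monthly_salary: float = MONTHLY_SALARY_INR,
    monthly_overhead: float = 0.0,
    monthly_surgical: float = 0.0,
    ipd_cost_ratio: float = 10.0,
) -> CostSummary:
    """Forward demand -> costing -> premium chain on arbitrary inputs.

    ``shares`` are renormalized to sum to 1; per-specialty admissions are
    visits x admission fraction; costs come from micro-costing the supplied
    protocols against the price list.
    """
    total_share = sum(shares.values())
    if total_share <= 0:
        raise ValidationError("shares must have positive sum")
    load = population * morbidity_rate * adjustment
    opd_total = load * opd_fraction
    by_spec: dict[str, list[TreatmentProtocol]] = {}
    for p in protocols:
        by_spec.setdefault(p.specialty, []).append(p)
    opd_cost = ipd_cost = 0.0
    for s, share in shares.items():
        visits = opd_total * share / total_share
        admissions = visits * admission_fractions.get(s, 0.0)
        o, i = specialty_monthly_treatment_cost(
            visits, admissions, by_spec.get(s, []), prices, scenario,
            ipd_cost_ratio)
        opd_cost += o
        ipd_cost += i
    return annual_premiums(
        monthly_treatment_opd=opd_cost,
        monthly_treatment_ipd=ipd_cost,
        monthly_surgical=monthly_surgical,
        population=population,
        household_size=household_size,
        scenario=scenario,
        monthly_salary=monthly_salary,
        monthly_overhead=monthly_overhead,
    )


def build_outcome_model(
    registry: ParameterRegistry,
    profiles: Sequence[SpecialtyProfile],
    macro: MacroParameters,
    scenario: str = "generic",
    outcome: str = "household_premium",
    monthly_salary: float = MONTHLY_SALARY_INR,
    monthly_overhead: float | None = None,
) -> Callable[[Mapping[str, float]], float]:
    """Calibrated scalar outcome function of the parameter registry.

    Unit costs (per outpatient visit, per inpatient bed-day) and admission
    fractions are calibrated once against the registry's base values and the
    profiles' recorded costs, so the model evaluated at base reproduces the
    base-case outcome exactly.  The returned callable maps a full dict of
    parameter values to the outcome; specialty shares are renormalized
    internally, the inpatient-proportion and correction-factor parameters
    scale the inpatient share multiplicatively, and the IPD:OPD cost ratio
    scales inpatient unit costs relative to its base value.  Salaries and
    overhead are fixed monthly costs; treatment and surgical costs scale
    with realized demand.
    """
    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if monthly_overhead is None:
        monthly_overhead = MONTHLY_OVERHEAD_INR.get(scenario, 0.0)

    v0 = registry.base_values()
    load0 = v0["population"] * v0["morbidity_rate"] * v0["reporting_adjustment"]
    ipd_share0 = 1.0 - v0["opd_fraction"]
    opd_total0 = load0 * (1.0 - ipd_share0)
    shares0 = registry.normalized_shares()
    p0 = v0["ipd_treatment_proportion"]
    c0 = v0["ipd_correction_factor"]
    r0 = v0["ipd_opd_cost_ratio"]

    prof_by_name = {p.name: p for p in profiles}
    unit_opd: dict[str, float] = {}
    unit_bed_day: dict[str, float] = {}
    admission_fraction0: dict[str, float] = {}
    lump_ipd: dict[str, float] = {}  # bed-day-override specialties (no ALOS)
    surgical0 = default_surgical_monthly()

    for name, share in shares0.items():
        prof = prof_by_name.get(name)
        if prof is None or not prof.costed:
            continue
        visits0 = opd_total0 * share
        unit_opd[name] = prof.opd_cost(scenario) / visits0
        if prof.alos_days is not None and prof.monthly_bed_days > 0:
            admission_fraction0[name] = prof.monthly_ipd_admissions / visits0
            unit_bed_day[name] = prof.ipd_cost(scenario) / prof.monthly_bed_days
        elif prof.monthly_bed_days > 0:
            lump_ipd[name] = prof.ipd_cost(scenario)

    fx = macro.exchange_rate_inr_per_usd
    preventive = macro.preventive_cost_per_capita_inr
    gdp_pc = macro.gdp_per_capita_usd

    def model(values: Mapping[str, float]) -> float:
        P = values["population"]
        load = P * values["morbidity_rate"] * values["reporting_adjustment"]
        ipd_share = ipd_share0 * (values["ipd_treatment_proportion"] / p0) \
            * (values["ipd_correction_factor"] / c0)
        ipd_share = min(max(ipd_share, 0.0), 0.99)
        opd_total = load * (1.0 - ipd_share)
        raw = {s: values[f"opd_share_{s}"] for s in shares0}
        total_share = sum(raw.values())
        ratio_scale = values["ipd_opd_cost_ratio"] / r0
        ipd_scale = ipd_share / ipd_share0 if ipd_share0 > 0 else 1.0

        opd_cost = ipd_cost = 0.0
        for s, unit in unit_opd.items():
            visits = opd_total * raw[s] / total_share
            opd_cost += visits * unit
            if s in admission_fraction0:
                admissions = visits * admission_fraction0[s] * ipd_scale
                bed_days = admissions * values[f"alos_{s}"]
                ipd_cost += bed_days * unit_bed_day[s] * ratio_scale
        for s, lump in lump_ipd.items():
            ipd_cost += lump * (load / load0) * ipd_scale * ratio_scale
        surgical = surgical0 * load / load0
        monthly = opd_cost + ipd_cost + surgical + monthly_salary + monthly_overhead
        household = 12.0 * monthly / (P / values["household_size"])
        if outcome == "household_premium":
            return household
        person = household / values["household_size"]
        if outcome == "person_premium":
            return person
        # continuous %GDP (no printed-precision rounding inside the model)
        return (person + preventive) / fx / gdp_pc * 100.0

    return model
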