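"""National extrapolation: INR/USD totals, %GDP share and hospital-scale
(bed-strength) scenarios.

Reported billion-INR totals use floor (matching the printed convention for
the country-level figures); USD per-capita values are rounded to whole
dollars before entering the %GDP share, which is the printed precision the
published GDP shares were computed at.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .params import MacroParameters, ValidationError

__all__ = [
    "NationalEstimate",
    "ScaleScenario",
    "national_totals",
    "gdp_share_percent",
    "scenario_increase_percent",
    "efficient_population",
    "scale_cost_curve",
    "DEFAULT_BEDS_PER_100K",
]

#: Beds needed per 100,000 population in the base case: the monthly bed-day
#: sub-total (1984) spread over a 30-day month, kept unrounded.
DEFAULT_BEDS_PER_100K = 1984.0 / 30.0


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10 ** ndigits
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class NationalEstimate:
    """Country-level annual cost of the benefit package, one drug scenario."""

    annual_curative_inr_billion: float
    annual_total_inr_billion: float
    annual_curative_usd_billion: float
    annual_total_usd_billion: float
    gdp_share_percent: float


def gdp_share_percent(per_capita_curative_inr: float,
                      macro: MacroParameters,
                      preventive_per_capita_inr: float | None = None) -> float:
    """Health-sector allocation as % of GDP (preventive + curative).

    The curative per-capita cost is converted to whole USD first; preventive
    cost is added unrounded; the share is reported to 1 decimal place.
    """
    macro.validate()
    if preventive_per_capita_inr is None:
        preventive_per_capita_inr = macro.preventive_cost_per_capita_inr
    usd_curative = _round_half_up(
        per_capita_curative_inr / macro.exchange_rate_inr_per_usd)
    usd_preventive = (preventive_per_capita_inr
                      / macro.exchange_rate_inr_per_usd)
    return _round_half_up(
        (usd_curative + usd_preventive) / macro.gdp_per_capita_usd * 100, 1)


def national_totals(per_capita_curative_inr: float,
                    preventive_per_capita_inr: float | None = None,
                    macro: MacroParameters | None = None) -> NationalEstimate:
    """Scale a per-capita annual curative cost to national totals."""
    macro = macro or MacroParameters()
    macro.validate()
    if preventive_per_capita_inr is None:
        preventive_per_capita_inr = macro.preventive_cost_per_capita_inr
    if per_capita_curative_inr < 0 or preventive_per_capita_inr < 0:
        raise ValidationError("per-capita costs must be non-negative")
    pop = macro.national_population
    fx = macro.exchange_rate_inr_per_usd
    curative_inr = per_capita_curative_inr * pop
    total_inr = (per_capita_curative_inr + preventive_per_capita_inr) * pop
    return NationalEstimate(
        annual_curative_inr_billion=math.floor(curative_inr / 1e9),
        annual_total_inr_billion=math.floor(total_inr / 1e9),
        annual_curative_usd_billion=_round_half_up(curative_inr / fx / 1e9),
        annual_total_usd_billion=_round_half_up(total_inr / fx / 1e9),
        gdp_share_percent=gdp_share_percent(per_capita_curative_inr, macro,
                                            preventive_per_capita_inr),
    )


def scenario_increase_percent(branded_per_capita_inr: float,
                              generic_per_capita_inr: float,
                              preventive_per_capita_inr: float = 300.0) -> float:
    """Percent increase in total (curative + preventive) per-capita cost
    when switching from generic to branded drugs, whole percent."""
    generic_total = generic_per_capita_inr + preventive_per_capita_inr
    if generic_total <= 0:
        raise ValidationError("generic total per-capita cost must be positive")
    branded_total = branded_per_capita_inr + preventive_per_capita_inr
    return _round_half_up((branded_total / generic_total - 1.0) * 100)


@dataclass(frozen=True)
class ScaleScenario:
    """One hospital size: bed strength, efficient catchment, household cost."""

    beds: int
    efficient_population: float
    efficient_population_million: float
    annual_per_household: float


def efficient_population(beds: int,
                         beds_per_100k: float = DEFAULT_BEDS_PER_100K) -> float:
    """Catchment population a hospital of this bed strength serves
    efficiently: beds / (beds needed per 100,000) x 100,000."""
    if beds <= 0:
        raise ValidationError("beds must be strictly positive")
    if beds_per_100k <= 0:
        raise ValidationError("beds_per_100k must be strictly positive")
    return beds / beds_per_100k * 100_000.0


def scale_cost_curve(
    bed_sizes: Sequence[int],
    fixed_monthly_cost: float,
    variable_annual_per_household: float,
    household_size: float = 4.0,
    beds_per_100k: float = DEFAULT_BEDS_PER_100K,
) -> list[ScaleScenario]:
    """Per-household cost by hospital bed strength.

    Variable costs scale with population, so their per-household share is
    constant; the fixed monthly cost is amortized over the households of the
    efficient catchment, making the curve strictly decreasing in bed
    strength whenever the fixed cost is positive.
    """
    if list(bed_sizes) != sorted(bed_sizes):
        raise ValidationError("bed_sizes must be sorted ascending")
    if fixed_monthly_cost < 0 or variable_annual_per_household < 0:
        raise ValidationError("costs must be non-negative")
    out = []
    for beds in bed_sizes:
        pop = efficient_population(beds, beds_per_100k)
        households = pop / household_size
        per_household = (variable_annual_per_household
                         + fixed_monthly_cost * 12.0 / households)
        out.append(ScaleScenario(
            beds=beds,
            efficient_population=pop,
            efficient_population_million=_round_half_up(pop / 1e6, 2),
            annual_per_household=per_household,
        ))
    return out
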