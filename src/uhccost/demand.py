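"""Demand and capacity estimation for the reference population.

Converts population and morbidity parameters into monthly patient load,
splits it into outpatient visits and inpatient caseload, allocates visits
across specialties, regenerates bed-days from calibrated admission
fractions, and sizes beds and (configurably) staff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .params import SpecialtyProfile, ValidationError

__all__ = [
    "DemandEstimate",
    "StaffingNorms",
    "StaffingPlan",
    "monthly_patient_load",
    "split_opd_ipd",
    "allocate_specialty_visits",
    "derive_admission_fractions",
    "beds_required",
    "estimate_demand",
    "staffing_plan",
]

DAYS_PER_MONTH = 30


@dataclass(frozen=True)
class DemandEstimate:
    """Monthly service demand for the reference population."""

    monthly_load: float
    opd_visits_total: int
    opd_visits_by_specialty: dict[str, int]
    ipd_admissions_by_specialty: dict[str, float]
    bed_days_by_specialty: dict[str, float]
    beds_required: int

    @property
    def total_bed_days(self) -> float:
        return sum(self.bed_days_by_specialty.values())


def monthly_patient_load(population: float, morbidity_rate: float,
                         adjustment: float) -> float:
    """Patients presenting per month: population x morbidity x uptake adjustment.

    The uptake adjustment inflates survey-derived morbidity for the extra
    demand expected once care is free at the point of use.
    """
    for name, v in (("population", population), ("morbidity_rate", morbidity_rate),
                    ("adjustment", adjustment)):
        if v < 0:
            raise ValidationError(f"{name} must be non-negative, got {v}")
    return population * morbidity_rate * adjustment


def split_opd_ipd(monthly_load: float, opd_fraction: float) -> tuple[float, float]:
    """Split total load into outpatient visits and inpatient caseload."""
    if not (0.0 <= opd_fraction <= 1.0):
        raise ValidationError(f"opd_fraction must lie in [0, 1], got {opd_fraction}")
    opd = monthly_load * opd_fraction
    return opd, monthly_load - opd


def allocate_specialty_visits(opd_visits_total: float,
                              shares: Mapping[str, float]) -> dict[str, int]:
    """Allocate integer visits to specialties by largest-remainder rounding.

    ``shares`` must be normalized (sum 1); the rounded allocation preserves
    the (rounded) total exactly.
    """
    if any(v < 0 for v in shares.values()):
        raise ValidationError("negative specialty share")
    total = int(round(opd_visits_total))
    if total == 0 or not shares:
        return {s: 0 for s in shares}
    quotas = {s: opd_visits_total * v for s, v in shares.items()}
    alloc = {s: math.floor(q) for s, q in quotas.items()}
    shortfall = total - sum(alloc.values())
    # distribute leftover units to the largest fractional remainders
    order = sorted(shares, key=lambda s: (quotas[s] - alloc[s], quotas[s]),
                   reverse=True)
    for s in order[:shortfall]:
        alloc[s] += 1
    return alloc


def derive_admission_fractions(profiles: Sequence[SpecialtyProfile]) -> dict[str, float]:
    """Admissions per OPD visit, calibrated from recorded bed-days and ALOS.

    ``fraction[s] = (bed_days[s] / alos[s]) / opd_visits[s]``.  A specialty
    with zero bed-days gets 0; a specialty with bed-days but no ALOS is
    carried as a pooled monthly admission (see
    :attr:`SpecialtyProfile.monthly_ipd_admissions`).
    """
    fractions = {}
    for p in profiles:
        if p.monthly_bed_days > 0 and p.alos_days is not None and p.alos_days <= 0:
            raise ValidationError(f"{p.name}: zero ALOS with nonzero bed-days")
        if p.monthly_opd_visits <= 0:
            fractions[p.name] = 0.0
        else:
            fractions[p.name] = p.monthly_ipd_admissions / p.monthly_opd_visits
    return fractions


def beds_required(bed_days_total: float, days_per_month: float = DAYS_PER_MONTH,
                  occupancy: float = 1.0) -> int:
    """Beds needed to supply the monthly bed-days, half-up rounded."""
    if bed_days_total < 0 or days_per_month <= 0:
        raise ValidationError("bed_days_total must be >= 0 and days_per_month > 0")
    if not (0.0 < occupancy <= 1.0):
        raise ValidationError(f"occupancy must lie in (0, 1], got {occupancy}")
    exact = bed_days_total / (days_per_month * occupancy)
    return math.floor(exact + 0.5)


def estimate_demand(population: float, morbidity_rate: float, adjustment: float,
                    opd_fraction: float,
                    profiles: Sequence[SpecialtyProfile],
                    days_per_month: float = DAYS_PER_MONTH,
                    occupancy: float = 1.0) -> DemandEstimate:
    """Full demand chain: load -> OPD/IPD split -> specialty visits ->
    admissions -> bed-days -> beds.

    Specialty shares are the profiles' exact OPD shares; admission fractions
    are calibrated from the profiles' recorded bed-days.  Specialties whose
    bed-days are a direct override (no ALOS) keep their recorded bed-days
    scaled with load.
    """
    load = monthly_patient_load(population, morbidity_rate, adjustment)
    opd_total, _ = split_opd_ipd(load, opd_fraction)
    shares = {p.name: p.opd_share for p in profiles}
    visits = allocate_specialty_visits(opd_total, shares)
    fractions = derive_admission_fractions(profiles)

    base_visits = {p.name: p.monthly_opd_visits for p in profiles}
    admissions: dict[str, float] = {}
    bed_days: dict[str, float] = {}
    for p in profiles:
        adm = visits[p.name] * fractions[p.name]
        admissions[p.name] = adm
        if p.alos_days is not None:
            bed_days[p.name] = adm * p.alos_days
        elif p.monthly_bed_days > 0 and base_visits[p.name] > 0:
            # direct override, scaled with realized visits
            bed_days[p.name] = p.monthly_bed_days * visits[p.name] / base_visits[p.name]
        else:
            bed_days[p.name] = 0.0
    total_bd = sum(bed_days.values())
    return DemandEstimate(
        monthly_load=load,
        opd_visits_total=int(round(opd_total)),
        opd_visits_by_specialty=visits,
        ipd_admissions_by_specialty=admissions,
        bed_days_by_specialty=bed_days,
        beds_required=beds_required(total_bd, days_per_month, occupancy) if total_bd else 0,
    )


# ---------------------------------------------------------------------------
# staffing (workload norms are configurable; published headcounts are not a
# reproduction target because the underlying norms were never published)


@dataclass(frozen=True)
class StaffingNorms:
    """Workload norms: how much work one staff member absorbs per day/bed.

    Defaults are calibration choices that reproduce the two derivable
    headcounts of the base case (25 consults/specialist/day -> 4 medicine
    specialists; 1 ANM per 5000 population -> 20 ANMs); all are overridable.
    """

    consults_per_specialist_per_day: float = 25.0
    beds_per_nurse: float = 1.05
    beds_per_medical_officer: float = 1.75
    patients_per_technician_per_day: float = 45.0
    anm_population_norm: float = 5000.0
    admin_team_size: int = 11

    def validate(self) -> None:
        for f in ("consults_per_specialist_per_day", "beds_per_nurse",
                  "beds_per_medical_officer", "patients_per_technician_per_day",
                  "anm_population_norm"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"staffing norm {f} must be strictly positive")


@dataclass(frozen=True)
class StaffingPlan:
    specialists_by_specialty: dict[str, int]
    medical_officers: int
    nurses: int
    technicians: int
    anms: int
    admin: int

    @property
    def total_specialists(self) -> int:
        return sum(self.specialists_by_specialty.values())


def staffing_plan(demand: DemandEstimate, norms: StaffingNorms,
                  population: float, opd_days_per_month: float = 24.0) -> StaffingPlan:
    """Ceiling(workload / norm) per cadre; deterministic and monotone in load."""
    norms.validate()
    if opd_days_per_month <= 0:
        raise ValidationError("opd_days_per_month must be positive")
    specialists = {}
    for s, v in demand.opd_visits_by_specialty.items():
        daily = v / opd_days_per_month
        specialists[s] = math.ceil(daily / norms.consults_per_specialist_per_day) if daily else 0
    beds = demand.beds_required
    daily_patients = demand.monthly_load / DAYS_PER_MONTH
    return StaffingPlan(
        specialists_by_specialty=specialists,
        medical_officers=math.ceil(beds / norms.beds_per_medical_officer) if beds else 0,
        nurses=math.ceil(beds / norms.beds_per_nurse) if beds else 0,
        technicians=math.ceil(daily_patients / norms.patients_per_technician_per_day)
        if daily_patients else 0,
        anms=math.ceil(population / norms.anm_population_norm) if population else 0,
        admin=norms.admin_team_size,
    )
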