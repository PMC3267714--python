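"""Typed registry of model parameters, macro inputs and specialty profiles.

Every scalar the decision model consumes lives here: the reference-population
parameters with their uncertainty ranges, the macro-economic inputs used for
national extrapolation, and the per-specialty demand/cost profiles derived
from one year of hospital service records.

Parameters carry a base value plus a low/high uncertainty range.  Ranges come
from state-wise variation where available; any parameter without a published
range gets a symmetric +/-20% band via :func:`default_range`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "ParamKind",
    "Parameter",
    "MacroParameters",
    "SpecialtyProfile",
    "ParameterRegistry",
    "ValidationError",
    "MissingParameterError",
    "default_range",
    "load_parameters",
    "load_default_registry",
    "load_default_profiles",
    "load_default_macro",
    "serialize_registry",
    "SPECIALTIES",
]

#: Canonical specialty identifiers, in the order the demand/cost tables use.
SPECIALTIES = (
    "ent",
    "dental",
    "dermatology",
    "ophthalmology",
    "psychiatry",
    "general_medicine",
    "orthopedics",
    "gynecology",
    "pediatrics",
    "surgery",
)

#: Parameter names that must be present in any complete registry.
REQUIRED_PARAMETERS = (
    "population",
    "morbidity_rate",
    "reporting_adjustment",
    "monthly_patient_load",
    "ipd_opd_cost_ratio",
    "ipd_treatment_proportion",
    "ipd_correction_factor",
    "opd_days_per_month",
    "household_size",
    "opd_fraction",
)


class ValidationError(ValueError):
    """An invariant on a parameter, profile or macro input is violated."""


class MissingParameterError(KeyError):
    """A required parameter is absent from a configuration source."""


class ParamKind(str, Enum):
    COUNT = "count"
    RATE = "rate"
    PROPORTION = "proportion"
    RATIO = "ratio"
    DAYS = "days"
    CURRENCY_INR = "currency-INR"
    CURRENCY_USD = "currency-USD"


def default_range(base: float, spread: float = 0.20) -> tuple[float, float]:
    """Symmetric uncertainty band ``(base*(1-spread), base*(1+spread))``.

    Used for every parameter lacking an explicit published range; the default
    20% spread mirrors the state-wise variation in morbidity around the
    national average.
    """
    if not (0.0 <= spread < 1.0):
        raise ValidationError(f"spread must lie in [0, 1), got {spread}")
    if base != base or base in (float("inf"), float("-inf")):
        raise ValidationError("base must be finite")
    return base * (1.0 - spread), base * (1.0 + spread)


@dataclass(frozen=True)
class Parameter:
    """One named scalar model input with its uncertainty range.

    ``range_inconsistent`` flags a published range that is arithmetically
    incompatible with the base case (it is excluded from sampling);
    ``derived`` marks quantities computed from other parameters rather than
    primary inputs (also excluded from sampling); ``fixed`` marks structural
    constants with degenerate ranges.
    """

    name: str
    base: float
    low: float
    high: float
    units: str = ""
    kind: ParamKind = ParamKind.COUNT
    range_inconsistent: bool = False
    derived: bool = False
    fixed: bool = False

    @property
    def sampled(self) -> bool:
        """Whether sensitivity analyses vary this parameter."""
        return not (self.range_inconsistent or self.derived or self.fixed
                    or self.low == self.high)

    def validate(self) -> None:
        errors = []
        if not self.range_inconsistent and not (self.low <= self.base <= self.high):
            errors.append(f"{self.name}: range [{self.low}, {self.high}] "
                          f"does not bracket base {self.base}")
        if self.kind is ParamKind.PROPORTION:
            if not (0.0 <= self.low and self.high <= 1.0 and 0.0 <= self.base <= 1.0):
                errors.append(f"{self.name}: proportion outside [0, 1]")
        if self.kind in (ParamKind.COUNT, ParamKind.CURRENCY_INR, ParamKind.CURRENCY_USD):
            if min(self.base, self.low) < 0:
                errors.append(f"{self.name}: negative {self.kind.value}")
        if errors:
            raise ValidationError("; ".join(errors))


@dataclass(frozen=True)
class MacroParameters:
    """Country-level inputs for extrapolating the reference-population cost."""

    national_population: float = 1.2e9
    gdp_per_capita_usd: float = 1176.0
    exchange_rate_inr_per_usd: float = 1713.0 / 38.0
    preventive_cost_per_capita_inr: float = 300.0

    def validate(self) -> None:
        for name in ("national_population", "gdp_per_capita_usd",
                     "exchange_rate_inr_per_usd", "preventive_cost_per_capita_inr"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"macro parameter {name} must be strictly positive")


@dataclass(frozen=True)
class SpecialtyProfile:
    """One clinical specialty's demand and recurrent-cost attributes.

    ``monthly_opd_visits`` and ``monthly_bed_days`` are the service-record
    aggregates for the reference population; ``alos_days`` is the specialty's
    average length of inpatient stay.  ``alos_days`` may be ``None`` for a
    specialty whose few bed-days are carried as a direct override (dental),
    in which case the bed-days are treated as one pooled monthly admission.
    Cost fields are monthly recurrent treatment expenditures (INR) under each
    drug scenario; ``costed=False`` marks surgical specialties whose costs
    are pooled into the surgical package line instead.
    """

    name: str
    monthly_opd_visits: float
    monthly_bed_days: float
    alos_days: float | None
    opd_cost_branded: float = 0.0
    ipd_cost_branded: float = 0.0
    opd_cost_generic: float = 0.0
    ipd_cost_generic: float = 0.0
    costed: bool = True
    opd_share: float = 0.0  # exact share of total OPD visits, set at load time

    @property
    def monthly_ipd_admissions(self) -> float:
        """Admissions implied by bed-days and ALOS (pooled override: 1)."""
        if self.monthly_bed_days == 0:
            return 0.0
        if self.alos_days is None:
            return 1.0
        return self.monthly_bed_days / self.alos_days

    def opd_cost(self, scenario: str) -> float:
        return self.opd_cost_branded if scenario == "branded" else self.opd_cost_generic

    def ipd_cost(self, scenario: str) -> float:
        return self.ipd_cost_branded if scenario == "branded" else self.ipd_cost_generic

    def validate(self) -> None:
        if self.monthly_opd_visits < 0 or self.monthly_bed_days < 0:
            raise ValidationError(f"{self.name}: negative demand quantity")
        if self.alos_days is not None and self.alos_days <= 0:
            raise ValidationError(f"{self.name}: ALOS must be positive")
        for setting in ("opd", "ipd"):
            b = getattr(self, f"{setting}_cost_branded")
            g = getattr(self, f"{setting}_cost_generic")
            if b < 0 or g < 0:
                raise ValidationError(f"{self.name}: negative {setting} cost")
            if g > b:
                raise ValidationError(
                    f"{self.name}: generic {setting} cost {g} exceeds branded {b}")


class ParameterRegistry(Mapping[str, Parameter]):
    """Ordered, validated mapping of parameter name -> :class:`Parameter`."""

    def __init__(self, parameters: Iterable[Parameter]):
        self._params: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self._params:
                raise ValidationError(f"duplicate parameter {p.name!r}")
            self._params[p.name] = p

    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def base_values(self) -> dict[str, float]:
        return {name: p.base for name, p in self._params.items()}

    def sampled(self) -> list[Parameter]:
        return [p for p in self._params.values() if p.sampled]

    def with_overrides(self, **overrides: float) -> "ParameterRegistry":
        """New registry with selected base values replaced (ranges rescaled
        for overridden parameters via :func:`default_range` if the old range
        no longer brackets the new base)."""
        params = []
        for name, p in self._params.items():
            if name in overrides:
                base = float(overrides[name])
                low, high = p.low, p.high
                if not (low <= base <= high):
                    low, high = default_range(base)
                p = replace(p, base=base, low=low, high=high)
            params.append(p)
        reg = ParameterRegistry(params)
        reg.validate()
        return reg

    def validate(self) -> None:
        missing = [n for n in REQUIRED_PARAMETERS if n not in self._params]
        if missing:
            raise MissingParameterError(
                f"missing required parameter(s): {', '.join(missing)}")
        for p in self._params.values():
            p.validate()
        for name in ("population", "morbidity_rate", "household_size"):
            if self._params[name].base <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    def normalized_shares(self) -> dict[str, float]:
        """Specialty OPD shares renormalized to sum exactly to 1."""
        raw = {s: self._params[f"opd_share_{s}"].base
               for s in SPECIALTIES if f"opd_share_{s}" in self._params}
        total = sum(raw.values())
        if total <= 0:
            raise ValidationError("specialty shares must have positive sum")
        return {s: v / total for s, v in raw.items()}


# ---------------------------------------------------------------------------
# loading / serialization


def _parse_flags(raw: str) -> dict[str, bool]:
    flags = {f.strip() for f in (raw or "").split(";") if f.strip()}
    return {
        "range_inconsistent": "range_inconsistent" in flags,
        "derived": "derived" in flags,
        "fixed": "fixed" in flags,
    }


def _read_parameter_rows(rows: Iterable[Mapping[str, str]]) -> ParameterRegistry:
    params = []
    for row in rows:
        base = float(row["base"])
        low = float(row["low"]) if row.get("low") not in (None, "") else None
        high = float(row["high"]) if row.get("high") not in (None, "") else None
        if low is None or high is None:
            low, high = default_range(base)
        params.append(Parameter(
            name=row["name"].strip(),
            base=base, low=low, high=high,
            units=(row.get("units") or "").strip(),
            kind=ParamKind((row.get("kind") or "count").strip()),
            **_parse_flags(row.get("flags", "")),
        ))
    registry = ParameterRegistry(params)
    registry.validate()
    return registry


def _read_profile_rows(rows: Iterable[Mapping[str, str]]) -> list[SpecialtyProfile]:
    profiles = []
    for row in rows:
        def num(key: str, default: float = 0.0) -> float:
            v = row.get(key)
            return float(v) if v not in (None, "") else default
        alos = row.get("alos_days")
        profiles.append(SpecialtyProfile(
            name=row["name"].strip(),
            monthly_opd_visits=num("monthly_opd_visits"),
            monthly_bed_days=num("monthly_bed_days"),
            alos_days=float(alos) if alos not in (None, "") else None,
            opd_cost_branded=num("opd_cost_branded"),
            ipd_cost_branded=num("ipd_cost_branded"),
            opd_cost_generic=num("opd_cost_generic"),
            ipd_cost_generic=num("ipd_cost_generic"),
            costed=bool(int(num("costed", 1))),
        ))
    total_visits = sum(p.monthly_opd_visits for p in profiles)
    if total_visits > 0:
        profiles = [replace(p, opd_share=p.monthly_opd_visits / total_visits)
                    for p in profiles]
    for p in profiles:
        p.validate()
    return profiles


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("uhccost").joinpath("data", filename)))


def load_parameters(
    parameters_csv: str | Path | None = None,
    specialties_csv: str | Path | None = None,
    macro_yaml: str | Path | None = None,
) -> tuple[ParameterRegistry, MacroParameters, list[SpecialtyProfile]]:
    """Load the full model configuration (defaults: the shipped fixtures).

    Raises :class:`MissingParameterError` if a required parameter is absent
    and :class:`ValidationError` on any invariant violation.
    """
    pcsv = Path(parameters_csv) if parameters_csv else _data_path("table2_parameters.csv")
    scsv = Path(specialties_csv) if specialties_csv else _data_path("table3_specialties.csv")
    myml = Path(macro_yaml) if macro_yaml else _data_path("macro.yaml")

    with open(pcsv, newline="") as fh:
        registry = _read_parameter_rows(csv.DictReader(fh))
    with open(scsv, newline="") as fh:
        profiles = _read_profile_rows(csv.DictReader(fh))
    raw = yaml.safe_load(Path(myml).read_text()) or {}
    macro = MacroParameters(
        national_population=float(raw.get("national_population", 1.2e9)),
        gdp_per_capita_usd=float(raw.get("gdp_per_capita_usd", 1176.0)),
        exchange_rate_inr_per_usd=float(raw.get("exchange_rate_inr_per_usd", 1713.0 / 38.0)),
        preventive_cost_per_capita_inr=float(raw.get("preventive_cost_per_capita_inr", 300.0)),
    )
    macro.validate()
    return registry, macro, profiles


def load_default_registry() -> ParameterRegistry:
    return load_parameters()[0]


def load_default_macro() -> MacroParameters:
    return load_parameters()[1]


def load_default_profiles() -> list[SpecialtyProfile]:
    return load_parameters()[2]


def serialize_registry(registry: ParameterRegistry) -> str:
    """Render a registry back to CSV text; inverse of the CSV loader."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["name", "base", "low", "high", "units", "kind", "flags"])
    for p in registry.values():
        flags = ";".join(f for f in ("derived", "range_inconsistent", "fixed")
                         if getattr(p, f))
        writer.writerow([p.name, repr(p.base), repr(p.low), repr(p.high),
                         p.units, p.kind.value, flags])
    return buf.getvalue()


def parse_registry(text: str) -> ParameterRegistry:
    """Parse CSV text produced by :func:`serialize_registry`."""
    return _read_parameter_rows(csv.DictReader(io.StringIO(text)))
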