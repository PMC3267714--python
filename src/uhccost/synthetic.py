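"""Synthetic hospital service records and price lists.

The study-design data this emulates is one year of administrative service
records from public hospitals: encounters tagged with a specialty, an
outpatient/inpatient flag and, for admissions, a length of stay.  The
generator draws specialty from a categorical distribution (the proportional
morbidity rates), setting from a Bernoulli on the outpatient fraction, and
length of stay from a shifted Poisson, ``1 + Poisson(alos - 1)`` - positive,
integer-valued, and mean-matched to the specialty's average length of stay,
which is the only stay statistic the model consumes.

The companion estimator recovers shares, ALOS and the outpatient fraction
from records, closing the loop for end-to-end parameter-recovery tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .costing import PriceList
from .params import ValidationError

__all__ = [
    "ServiceRecord",
    "generate_service_records",
    "estimate_profiles",
    "generate_price_list",
    "write_service_records",
    "read_service_records",
]


@dataclass(frozen=True)
class ServiceRecord:
    """One hospital encounter."""

    encounter_id: int
    specialty: str
    setting: str  # OPD | IPD
    length_of_stay: int | None  # days, IPD only
    month: int  # 1..12

    def __post_init__(self):
        if self.setting == "OPD" and self.length_of_stay is not None:
            raise ValidationError("OPD records carry no length of stay")
        if self.setting == "IPD" and (self.length_of_stay is None
                                      or self.length_of_stay < 1):
            raise ValidationError("IPD length of stay must be >= 1 day")


def generate_service_records(
    true_shares: Mapping[str, float],
    true_alos: Mapping[str, float],
    opd_fraction: float,
    n_encounters: int,
    seed: int,
) -> list[ServiceRecord]:
    """Draw ``n_encounters`` synthetic encounters from known truth.

    ``true_shares`` must sum to 1 (tolerance 1e-9) and every specialty needs
    a positive ALOS; reproducible for a fixed seed.
    """
    if n_encounters <= 0:
        raise ValidationError("n_encounters must be strictly positive")
    names = list(true_shares)
    probs = np.array([true_shares[s] for s in names], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(f"shares must sum to 1, got {probs.sum()}")
    if not (0.0 <= opd_fraction <= 1.0):
        raise ValidationError("opd_fraction must lie in [0, 1]")
    alos = np.array([true_alos[s] for s in names], dtype=float)
    if np.any(alos <= 0):
        raise ValidationError("every ALOS must be strictly positive")

    rng = np.random.default_rng(seed)
    spec_idx = rng.choice(len(names), size=n_encounters, p=probs)
    is_opd = rng.random(n_encounters) < opd_fraction
    # shifted Poisson: positive integer stay with mean alos
    los = 1 + rng.poisson(np.maximum(alos[spec_idx] - 1.0, 0.0))
    months = rng.integers(1, 13, size=n_encounters)

    records = []
    for i in range(n_encounters):
        opd = bool(is_opd[i])
        records.append(ServiceRecord(
            encounter_id=i,
            specialty=names[spec_idx[i]],
            setting="OPD" if opd else "IPD",
            length_of_stay=None if opd else int(los[i]),
            month=int(months[i]),
        ))
    return records


def estimate_profiles(
    records: Sequence[ServiceRecord],
) -> tuple[dict[str, float], dict[str, float | None], float]:
    """Estimate (shares, alos, opd_fraction) from service records.

    Shares are specialty frequencies among OPD encounters; ALOS is the mean
    stay among IPD encounters (``None`` for a specialty with no admissions);
    the OPD fraction is the share of OPD encounters overall.
    """
    if not records:
        raise ValidationError("record list must be non-empty")
    opd = [r for r in records if r.setting == "OPD"]
    ipd = [r for r in records if r.setting == "IPD"]
    specialties = sorted({r.specialty for r in records})

    shares: dict[str, float] = {}
    if opd:
        for s in specialties:
            shares[s] = sum(1 for r in opd if r.specialty == s) / len(opd)
    else:
        for s in specialties:
            shares[s] = sum(1 for r in records if r.specialty == s) / len(records)

    alos: dict[str, float | None] = {}
    for s in specialties:
        stays = [r.length_of_stay for r in ipd if r.specialty == s]
        alos[s] = float(np.mean(stays)) if stays else None

    return shares, alos, len(opd) / len(records)


def generate_price_list(
    n_items: int,
    markup_range: tuple[float, float] = (1.2, 3.0),
    seed: int = 0,
    generic_price_range: tuple[float, float] = (5.0, 500.0),
    drug_fraction: float = 0.6,
) -> PriceList:
    """Synthetic rate-contract price list.

    Generic prices are log-uniform over ``generic_price_range``; branded
    drug prices apply a uniform markup from ``markup_range`` (low >= 1);
    consumables and diagnostics are priced identically in both scenarios.
    """
    if markup_range[0] < 1.0 or markup_range[1] < markup_range[0]:
        raise ValidationError("markup range must satisfy 1 <= low <= high")
    rng = np.random.default_rng(seed)
    prices, categories = {}, {}
    for i in range(n_items):
        generic = float(np.exp(rng.uniform(np.log(generic_price_range[0]),
                                           np.log(generic_price_range[1]))))
        generic = round(generic, 2)
        if rng.random() < drug_fraction:
            markup = rng.uniform(*markup_range)
            item, cat = f"drug_{i:04d}", "drug"
            branded = round(generic * markup, 2)
        else:
            cat = "consumable" if rng.random() < 0.5 else "diagnostic"
            item = f"{cat}_{i:04d}"
            branded = generic
        prices[item] = (branded, generic)
        categories[item] = cat
    return PriceList(prices, categories)


# ---------------------------------------------------------------------------
# CSV round trip

_FIELDS = ("encounter_id", "specialty", "setting", "length_of_stay", "month")


def write_service_records(records: Iterable[ServiceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_FIELDS)
        for r in records:
            writer.writerow([r.encounter_id, r.specialty, r.setting,
                             "" if r.length_of_stay is None else r.length_of_stay,
                             r.month])


def read_service_records(path: str | Path) -> list[ServiceRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            los = row["length_of_stay"]
            records.append(ServiceRecord(
                encounter_id=int(row["encounter_id"]),
                specialty=row["specialty"],
                setting=row["setting"],
                length_of_stay=int(los) if los not in ("", None) else None,
                month=int(row["month"]),
            ))
    return records
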