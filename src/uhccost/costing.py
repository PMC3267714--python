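"""Micro-costing of standard treatment protocols.

An episode of care is costed bottom-up: quantities of drugs, consumables and
diagnostics from a standard treatment protocol, times unit prices from a
rate-contract price list carrying a branded and a generic column.  Where a
condition has no inpatient protocol, hospitalized care falls back to a
multiple of the outpatient episode cost (base 10, range 8-15).  Surgical
package rates are scaled down by 50% to the cost hospitals actually incur.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .params import ValidationError

__all__ = [
    "ProtocolLineItem",
    "TreatmentProtocol",
    "PriceList",
    "UnpricedItemError",
    "protocol_cost",
    "ipd_cost_fallback",
    "scale_surgical_package",
    "specialty_monthly_treatment_cost",
    "load_protocols",
    "load_price_list",
    "load_surgical_packages",
]

SCENARIOS = ("branded", "generic")
ITEM_CATEGORIES = ("drug", "consumable", "diagnostic")


class UnpricedItemError(KeyError):
    """A protocol references an item absent from the price list."""


@dataclass(frozen=True)
class ProtocolLineItem:
    item_id: str
    category: str  # drug | consumable | diagnostic
    quantity: float

    def __post_init__(self):
        if self.category not in ITEM_CATEGORIES:
            raise ValidationError(f"unknown item category {self.category!r}")
        if self.quantity < 0:
            raise ValidationError(f"{self.item_id}: negative quantity")


@dataclass(frozen=True)
class TreatmentProtocol:
    """Line-itemized standard treatment for one condition/setting.

    ``episode_weight`` is the condition's share of its specialty's caseload
    in the given setting; weights within a (specialty, setting) sum to <= 1.
    """

    condition: str
    specialty: str
    setting: str  # OPD | IPD
    items: tuple[ProtocolLineItem, ...]
    episode_weight: float = 1.0

    def __post_init__(self):
        if self.setting not in ("OPD", "IPD"):
            raise ValidationError(f"setting must be OPD or IPD, got {self.setting!r}")
        if not (0.0 <= self.episode_weight <= 1.0):
            raise ValidationError(f"{self.condition}: episode_weight outside [0, 1]")


class PriceList(Mapping[str, tuple[float, float]]):
    """item_id -> (price_branded, price_generic), in INR.

    Generic never exceeds branded for drugs; non-drug items carry identical
    prices in both scenarios.
    """

    def __init__(self, prices: Mapping[str, tuple[float, float]],
                 categories: Mapping[str, str] | None = None):
        self._prices = dict(prices)
        self._categories = dict(categories or {})
        self.validate()

    def __getitem__(self, item_id: str) -> tuple[float, float]:
        return self._prices[item_id]

    def __iter__(self):
        return iter(self._prices)

    def __len__(self):
        return len(self._prices)

    def price(self, item_id: str, scenario: str) -> float:
        if scenario not in SCENARIOS:
            raise ValidationError(f"unknown drug scenario {scenario!r}")
        try:
            branded, generic = self._prices[item_id]
        except KeyError:
            raise UnpricedItemError(f"no price for item {item_id!r}") from None
        return branded if scenario == "branded" else generic

    def validate(self) -> None:
        for item, (branded, generic) in self._prices.items():
            if branded < 0 or generic < 0:
                raise ValidationError(f"{item}: negative price")
            if generic > branded:
                raise ValidationError(
                    f"{item}: generic price {generic} exceeds branded {branded}")
            cat = self._categories.get(item)
            if cat in ("consumable", "diagnostic") and branded != generic:
                raise ValidationError(
                    f"{item}: non-drug prices must match across scenarios")


def protocol_cost(protocol: TreatmentProtocol, prices: PriceList,
                  scenario: str) -> float:
    """Cost of one episode: sum of quantity x unit price under the scenario."""
    return sum(item.quantity * prices.price(item.item_id, scenario)
               for item in protocol.items)


def ipd_cost_fallback(opd_episode_cost: float, cost_ratio: float) -> float:
    """Inpatient episode cost as a multiple of the outpatient episode cost.

    Used only for conditions lacking an inpatient protocol; the multiplier
    comes from regional outpatient-vs-inpatient unit-cost estimates.
    """
    if opd_episode_cost < 0 or cost_ratio < 0:
        raise ValidationError("opd_episode_cost and cost_ratio must be non-negative")
    return opd_episode_cost * cost_ratio


def scale_surgical_package(package_rate: float, scaling: float = 0.5) -> float:
    """Scale a surgical package rate down to the hospital's actual cost."""
    if package_rate < 0:
        raise ValidationError("package_rate must be non-negative")
    if not (0.0 < scaling <= 1.0):
        raise ValidationError(f"scaling must lie in (0, 1], got {scaling}")
    return package_rate * scaling


def _weighted_episode_cost(protocols: Sequence[TreatmentProtocol],
                           prices: PriceList, scenario: str) -> tuple[float, float]:
    """(sum of weight x episode cost, total weight) over protocols."""
    total_w = sum(p.episode_weight for p in protocols)
    if total_w > 1.0 + 1e-9:
        raise ValidationError(
            f"episode weights sum to {total_w} > 1 for "
            f"{protocols[0].specialty}/{protocols[0].setting}")
    cost = sum(p.episode_weight * protocol_cost(p, prices, scenario)
               for p in protocols)
    return cost, total_w


def specialty_monthly_treatment_cost(
    visits: float,
    admissions: float,
    protocols: Sequence[TreatmentProtocol],
    prices: PriceList,
    scenario: str,
    ipd_cost_ratio: float = 10.0,
) -> tuple[float, float]:
    """Monthly (OPD, IPD) treatment expenditure for one specialty.

    OPD cost is visits times the caseload-weighted outpatient episode cost.
    IPD cost is admissions times the weighted inpatient episode cost; any
    caseload share not covered by an inpatient protocol is costed by the
    ratio fallback applied to the mean outpatient episode cost.
    """
    if visits < 0 or admissions < 0:
        raise ValidationError("visits and admissions must be non-negative")
    opd_protocols = [p for p in protocols if p.setting == "OPD"]
    ipd_protocols = [p for p in protocols if p.setting == "IPD"]

    opd_episode, opd_w = (_weighted_episode_cost(opd_protocols, prices, scenario)
                          if opd_protocols else (0.0, 0.0))
    opd_cost = visits * opd_episode

    if ipd_protocols:
        ipd_episode, ipd_w = _weighted_episode_cost(ipd_protocols, prices, scenario)
    else:
        ipd_episode, ipd_w = 0.0, 0.0
    uncovered = max(0.0, 1.0 - ipd_w)
    if admissions > 0 and uncovered > 1e-12:
        mean_opd = opd_episode / opd_w if opd_w > 0 else 0.0
        ipd_episode += uncovered * ipd_cost_fallback(mean_opd, ipd_cost_ratio)
    ipd_cost = admissions * ipd_episode
    return opd_cost, ipd_cost


# ---------------------------------------------------------------------------
# CSV interfaces


def load_protocols(path: str | Path) -> list[TreatmentProtocol]:
    """Read protocols from CSV (condition, specialty, setting, item_id,
    category, quantity, episode_weight); line items sharing a condition and
    setting form one protocol."""
    grouped: dict[tuple[str, str, str, float], list[ProtocolLineItem]] = defaultdict(list)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["condition"].strip(), row["specialty"].strip(),
                   row["setting"].strip(), float(row["episode_weight"]))
            grouped[key].append(ProtocolLineItem(
                item_id=row["item_id"].strip(),
                category=row["category"].strip(),
                quantity=float(row["quantity"]),
            ))
    return [TreatmentProtocol(condition=c, specialty=s, setting=st,
                              items=tuple(items), episode_weight=w)
            for (c, s, st, w), items in grouped.items()]


def load_price_list(path: str | Path) -> PriceList:
    """Read a price list CSV (item_id, category, price_branded, price_generic)."""
    prices, categories = {}, {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            item = row["item_id"].strip()
            prices[item] = (float(row["price_branded"]), float(row["price_generic"]))
            categories[item] = (row.get("category") or "drug").strip()
    return PriceList(prices, categories)


def load_surgical_packages(path: str | Path) -> dict[str, float]:
    """Read surgical package rates CSV (package_id, rate_inr)."""
    with open(path, newline="") as fh:
        return {row["package_id"].strip(): float(row["rate_inr"])
                for row in csv.DictReader(fh)}
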