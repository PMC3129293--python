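"""Annualization: depreciation, two-year inflation averaging, currency
conversion, staff time valuation and in-kind imputation.

Capital items are converted to an annual charge by straight-line depreciation
over class-default service lives (general equipment 10 y, medical equipment
8 y, vehicles 8 y, buildings 30 y); buildings may be valued as floor area
times a regional cost per square metre.  Recurrent expenditures observed for
two fiscal years are averaged after uplifting the earlier year by a standard
inflation rate (5%).  Staff time is valued from the payroll: base salary plus
allowances divided by the expected direct-service minutes per year (220
working days x 6 direct hours x 60 minutes = 79,200 minutes by default).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

from pydantic import BaseModel, Field

from .errors import ImputationError, ParameterError
from .facility import (
    Asset,
    CostCategory,
    CostItem,
    FacilityRecord,
    StaffPosition,
    Traceability,
)
from .util import DEFAULT_INFLATION, KSH_PER_EUR

__all__ = [
    "Asset",
    "StaffPosition",
    "PriceList",
    "InKindSupply",
    "DEFAULT_LIFETIMES",
    "straight_line_depreciation",
    "building_initial_cost",
    "inflation_average",
    "convert_currency",
    "staff_minute_cost",
    "impute_inkind",
    "fallback_salary",
    "annualize_assets",
    "annualize_record",
]

#: Default service lives in years by asset class.
DEFAULT_LIFETIMES: dict[str, float] = {
    "general_equipment": 10.0,
    "medical_equipment": 8.0,
    "vehicle": 8.0,
    "building": 30.0,
}


class PriceList(BaseModel):
    """Ministry price list plus per-level standard equipment bundles."""

    prices: dict[str, float] = Field(default_factory=dict)
    #: level value -> {item code -> quantity} standard equipment bundle
    equipment_bundles: dict[str, dict[str, float]] = Field(default_factory=dict)

    def price(self, code: str) -> float:
        try:
            p = self.prices[code]
        except KeyError:
            raise ImputationError(f"no price for item code {code!r}") from None
        if p <= 0:
            raise ImputationError(f"nonpositive price for item code {code!r}")
        return p


class InKindSupply(BaseModel):
    """A supply received in kind (mainly pharmaceuticals), to be valued from the price list."""

    item_code: str
    quantity: float = Field(ge=0)
    year: str = ""
    centre_id: str = ""


def building_initial_cost(floor_area: float, unit_build_cost: float) -> float:
    """Initial building value: floor area [sqm] x build cost per sqm [Ksh/sqm]."""
    if floor_area <= 0 or unit_build_cost <= 0:
        raise ParameterError("floor_area and unit_build_cost must be positive")
    return floor_area * unit_build_cost


def effective_lifetime(asset: Asset) -> float:
    base = asset.lifetime_years
    if base is None:
        try:
            base = DEFAULT_LIFETIMES[asset.asset_class]
        except KeyError:
            raise ParameterError(
                f"unknown asset class {asset.asset_class!r} and no lifetime override"
            ) from None
    life = base * asset.condition_adjustment
    if life <= 0:
        raise ParameterError(f"nonpositive effective lifetime {life}")
    return life


def asset_initial_value(asset: Asset) -> float:
    if asset.initial_value is not None:
        return asset.initial_value
    return building_initial_cost(asset.floor_area, asset.unit_build_cost)


def straight_line_depreciation(asset: Asset) -> float:
    """Annual depreciation charge [Ksh/year]: initial value over effective lifetime."""
    return asset_initial_value(asset) / effective_lifetime(asset)


def inflation_average(
    cost_year1: float, cost_year2: float, inflation: float = DEFAULT_INFLATION
) -> float:
    """Average two fiscal years with the earlier year uplifted by ``inflation``."""
    if inflation < -1:
        raise ParameterError(f"inflation {inflation} below -100%")
    if cost_year1 < 0 or cost_year2 < 0:
        raise ParameterError("costs must be nonnegative")
    return (cost_year1 * (1.0 + inflation) + cost_year2) / 2.0


def convert_currency(amount_ksh: float, rate: float = KSH_PER_EUR) -> float:
    """Convert Ksh to EUR at a fixed rate; unrounded (rounding is a report concern)."""
    if rate <= 0:
        raise ParameterError(f"exchange rate must be positive, got {rate}")
    return amount_ksh / rate


def staff_minute_cost(position: StaffPosition) -> float:
    """Cost of one minute of direct staff time [Ksh/min].

    Full remuneration (base + allowances) divided by expected direct-service
    minutes per year; with the defaults the denominator is 79,200 minutes.
    """
    if position.annual_base is None:
        raise ParameterError(
            f"position {position.cadre!r} has no pay data; impute a salary first"
        )
    minutes = position.working_days * position.direct_hours_per_day * 60.0
    if minutes <= 0:
        raise ParameterError("zero working minutes per year")
    return (position.annual_base + position.annual_allowances) / minutes


def impute_inkind(
    items: Iterable[InKindSupply], prices: PriceList, year: str = ""
) -> list[CostItem]:
    """Value in-kind supplies from the price list as drugs/supplies cost items."""
    out: list[CostItem] = []
    for rec in items:
        amount = rec.quantity * prices.price(rec.item_code)
        out.append(
            CostItem(
                amount=amount,
                category=CostCategory.drugs_supplies,
                year=rec.year or year,
                traceability=Traceability.indirect,
                target=rec.centre_id,
            )
        )
    return out


def fallback_salary(
    position: StaffPosition, public_scale: Mapping[str, float | tuple[float, float]]
) -> StaffPosition:
    """Fill missing pay from the equivalent public-sector scale; flags the result imputed.

    Positions that already carry pay are returned unchanged.  The scale maps a
    cadre to an annual base salary, or to a (base, allowances) pair.
    """
    if position.annual_base is not None:
        return position
    try:
        entry = public_scale[position.cadre]
    except KeyError:
        raise ImputationError(
            f"cadre {position.cadre!r} missing from the public salary scale"
        ) from None
    if isinstance(entry, (tuple, list)):
        base, allowances = float(entry[0]), float(entry[1])
    else:
        base, allowances = float(entry), position.annual_allowances
    return position.model_copy(
        update={"annual_base": base, "annual_allowances": allowances, "imputed": True}
    )


def annualize_assets(assets: Iterable[Asset]) -> float:
    """Total annual depreciation charge of an asset register [Ksh/year]."""
    return sum(straight_line_depreciation(a) for a in assets)


#: Label used for the synthetic fiscal year produced by annualization.
ANNUALIZED_YEAR = "annualized"


def annualize_record(
    record: FacilityRecord, inflation: float = DEFAULT_INFLATION
) -> FacilityRecord:
    """Collapse a two-year ledger into one annualized ledger and charge assets.

    Recurrent items are grouped by (target, category, traceability); the two
    fiscal years in ``record.year_order`` are averaged with the earlier year
    uplifted by ``inflation``.  A single-year ledger passes through unchanged.
    Each asset contributes an indirect fixed-cost item (its annual straight-line
    depreciation) against its cost centre.  Payroll and statistics carry over.
    """
    years = record.year_order or sorted({i.year for i in record.items})
    groups: dict[tuple[str, CostCategory, Traceability], dict[str, float]] = defaultdict(
        lambda: defaultdict(float)
    )
    for item in record.items:
        groups[(item.target, item.category, item.traceability)][item.year] += item.amount

    items: list[CostItem] = []
    for (target, category, trace), by_year in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
    ):
        if len(years) >= 2:
            y1, y2 = years[0], years[1]
            amount = inflation_average(by_year.get(y1, 0.0), by_year.get(y2, 0.0), inflation)
        else:
            amount = sum(by_year.values())
        items.append(
            CostItem(
                amount=amount,
                category=category,
                year=ANNUALIZED_YEAR,
                traceability=trace,
                target=target,
            )
        )

    for asset in record.assets:
        charge = straight_line_depreciation(asset)
        target = asset.centre_id
        trace = Traceability.indirect
        if not target:
            if record.centres:
                supports = record.support_centres
                target = supports[0].id if supports else record.centres[0].id
            else:  # centre-less (administrative) records: charge the first cost unit
                target = next(iter(record.cost_units))
                trace = Traceability.direct
        items.append(
            CostItem(
                amount=charge,
                category=CostCategory.fixed,
                year=ANNUALIZED_YEAR,
                traceability=trace,
                target=target,
            )
        )

    return record.model_copy(update={"items": items, "year_order": [ANNUALIZED_YEAR]})
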