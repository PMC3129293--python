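"""Essential-package (KEPH) episode costing and demand-side adjustment.

An episode's cost has two elements.  The *direct* component prices the
treatment recipe itself — drugs and supplies by age group, staff minutes by
cadre, laboratory tests.  The *indirect* component apportions facility
running costs: for an outpatient episode the indirect share of the cost per
visit, for an inpatient episode the indirect share of the cost per bed-day
times the length of stay.  Only the indirect share of the unit cost is used
as overhead, so drugs and staff time already priced directly are not counted
twice.

Treatment recipes come in two variants: *actual* (observed resource use,
including stock-outs) and *normative* (the expert standard treatment scheme).

Household (demand-side) spending recorded in exit interviews enters provider
unit costs only through drugs bought outside the facility; user fees and
transport are collected but deliberately not folded in.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from pydantic import BaseModel, Field, model_validator

from .annualize import PriceList
from .errors import CostingError
from .facility import Level, Trustee
from .stepdown import UnitCost, UnitCosts

logger = logging.getLogger(__name__)

#: The essential package covers this many priority conditions.
N_KEPH_CONDITIONS = 59

#: Age groups used for drug dosing in the schemes.
AGE_GROUPS = ("under5", "over5")


class Setting(str, enum.Enum):
    outpatient = "outpatient"
    inpatient = "inpatient"


class Variant(str, enum.Enum):
    actual = "actual"
    normative = "normative"


class KephScheme(BaseModel):
    """Resource recipe for treating one condition in one setting."""

    condition_id: int = Field(ge=1, le=N_KEPH_CONDITIONS)
    name: str = ""
    setting: Setting
    variant: Variant = Variant.actual
    #: age group -> {item code -> quantity}
    drug_quantities: dict[str, dict[str, float]] = Field(default_factory=dict)
    staff_minutes: dict[str, float] = Field(default_factory=dict)
    lab_tests: dict[str, float] = Field(default_factory=dict)
    length_of_stay: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "KephScheme":
        if self.setting is Setting.inpatient and self.length_of_stay is None:
            raise ValueError("inpatient scheme needs length_of_stay > 0")
        for group in self.drug_quantities.values():
            if any(q < 0 for q in group.values()):
                raise ValueError("drug quantities must be nonnegative")
        if any(m < 0 for m in self.staff_minutes.values()):
            raise ValueError("staff minutes must be nonnegative")
        if any(n < 0 for n in self.lab_tests.values()):
            raise ValueError("lab test counts must be nonnegative")
        return self


@dataclass(frozen=True)
class EpisodeCost:
    """Costed episode: total is direct + indirect by construction."""

    condition_id: int
    direct: float
    indirect: float
    variant: Variant = Variant.actual
    setting: Setting = Setting.outpatient
    stratum: str = ""

    @property
    def total(self) -> float:
        return self.direct + self.indirect


class PatientType(str, enum.Enum):
    outpatient = "outpatient"
    inpatient = "inpatient"


class ExitInterview(BaseModel):
    """One patient's reported household spending for the episode."""

    patient_type: PatientType
    outside_drug_cost: float = Field(default=0.0, ge=0)
    user_fees: float = Field(default=0.0, ge=0)
    transport_cost: float = Field(default=0.0, ge=0)
    level: Level
    trustee: Trustee


def episode_direct_cost(
    scheme: KephScheme,
    prices: PriceList,
    staff_rates: Mapping[str, float],
    age_group: str = "under5",
) -> float:
    """Price the recipe: drugs x unit price + staff minutes x per-minute rate + lab tests."""
    total = 0.0
    for code, qty in scheme.drug_quantities.get(age_group, {}).items():
        try:
            total += qty * prices.price(code)
        except Exception as exc:
            raise CostingError(f"condition {scheme.condition_id}: {exc}") from exc
    for cadre, minutes in scheme.staff_minutes.items():
        try:
            rate = staff_rates[cadre]
        except KeyError:
            raise CostingError(
                f"condition {scheme.condition_id}: no per-minute rate for cadre {cadre!r}"
            ) from None
        total += minutes * rate
    for code, count in scheme.lab_tests.items():
        try:
            total += count * prices.price(code)
        except Exception as exc:
            raise CostingError(f"condition {scheme.condition_id}: {exc}") from exc
    return total


def episode_overhead(scheme: KephScheme, unit_costs: UnitCosts) -> float:
    """Indirect overhead for one episode.

    Outpatient: the indirect share of the cost per visit.  Inpatient: the
    indirect share of the cost per bed-day times the length of stay.
    """
    if scheme.setting is Setting.outpatient:
        if unit_costs.per_visit is None:
            raise CostingError(
                f"condition {scheme.condition_id}: facility has no outpatient unit costs"
            )
        return unit_costs.per_visit.indirect
    if unit_costs.per_bed_day is None:
        raise CostingError(
            f"condition {scheme.condition_id}: inpatient scheme at a facility "
            "without inpatient unit costs"
        )
    return unit_costs.per_bed_day.indirect * float(scheme.length_of_stay)


def episode_total_cost(
    direct: float,
    unit_costs: UnitCosts,
    scheme: KephScheme,
    stratum: str = "",
) -> EpisodeCost:
    """Combine a priced recipe with the appropriate facility overhead."""
    return EpisodeCost(
        condition_id=scheme.condition_id,
        direct=direct,
        indirect=episode_overhead(scheme, unit_costs),
        variant=scheme.variant,
        setting=scheme.setting,
        stratum=stratum,
    )


def normative_episode_cost(
    normative_scheme: KephScheme,
    prices: PriceList,
    staff_rates: Mapping[str, float],
    unit_costs: UnitCosts,
    age_group: str = "under5",
    stratum: str = "",
) -> EpisodeCost:
    """Cost the expert standard treatment scheme against the same overheads."""
    direct = episode_direct_cost(normative_scheme, prices, staff_rates, age_group)
    cost = episode_total_cost(direct, unit_costs, normative_scheme, stratum)
    if cost.variant is not Variant.normative:
        cost = EpisodeCost(
            condition_id=cost.condition_id,
            direct=cost.direct,
            indirect=cost.indirect,
            variant=Variant.normative,
            setting=cost.setting,
            stratum=cost.stratum,
        )
    return cost


def _add_to(unit: UnitCost, extra: float) -> UnitCost:
    # outside drug purchases are direct, variable spending
    return UnitCost(
        total=unit.total + extra,
        fixed=unit.fixed,
        variable=unit.variable + extra,
        direct=unit.direct + extra,
        indirect=unit.indirect,
    )


def demand_side_adjust(
    unit_costs: UnitCosts,
    interviews: Iterable[ExitInterview],
    level: Level,
    trustee: Trustee,
) -> UnitCosts:
    """Fold mean outside-facility drug spending into provider unit costs.

    The mean over the stratum's outpatient interviews is added to the cost per
    visit; the inpatient mean to the cost per admission.  User fees and
    transport are not added.  An empty interview cell leaves the unit cost
    unchanged with a logged warning.
    """
    cell = [i for i in interviews if i.level == level and i.trustee == trustee]
    per_visit, per_admission = unit_costs.per_visit, unit_costs.per_admission

    for ptype, attr in (
        (PatientType.outpatient, "per_visit"),
        (PatientType.inpatient, "per_admission"),
    ):
        unit = unit_costs.per_visit if attr == "per_visit" else unit_costs.per_admission
        if unit is None:
            continue
        sub = [i.outside_drug_cost for i in cell if i.patient_type is ptype]
        if not sub:
            logger.warning(
                "no %s exit interviews for stratum (%s, %s); demand-side "
                "adjustment skipped",
                ptype.value,
                level.value,
                trustee.value,
            )
            continue
        adjusted = _add_to(unit, sum(sub) / len(sub))
        if attr == "per_visit":
            per_visit = adjusted
        else:
            per_admission = adjusted

    return UnitCosts(
        per_visit=per_visit,
        per_admission=per_admission,
        per_bed_day=unit_costs.per_bed_day,
    )
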