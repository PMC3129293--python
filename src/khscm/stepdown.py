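"""Step-down cost allocation and unit costs.

The engine implements classic one-pass step-down allocation: indirect costs
are collected on the cost centre where they occur; support centres are then
closed one at a time, each distributing its accumulated cost (its own plus
anything received from earlier closures) over all not-yet-closed centres in
proportion to an allocation basis.  A closed centre never receives cost back,
so reciprocal allocation is structurally impossible.  After the last support
centre closes, all indirect cost sits on final (patient-serving) centres and
unit costs follow by dividing each pool by its output measure.

Category identity is preserved through the cascade: an allocated drugs cost
stays a drugs cost, which is what later allows a fixed/variable decomposition
of unit costs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, Field

from .errors import AllocationError, ConfigError, UnitCostError
from .facility import (
    CentreKind,
    CostCategory,
    CostCentre,
    FacilityRecord,
    OutputMeasure,
    ServiceStatistics,
    Traceability,
)

CategoryTotals = dict[CostCategory, float]

_ZERO: CategoryTotals = {c: 0.0 for c in CostCategory}


def _zero() -> CategoryTotals:
    return dict(_ZERO)


class BasisKind(str, enum.Enum):
    direct_cost_share = "direct_cost_share"
    bed_days = "bed_days"
    patient_days = "patient_days"
    outpatient_visits = "outpatient_visits"
    staff_count = "staff_count"
    floor_area = "floor_area"
    explicit_weights = "explicit_weights"


class AllocationBasis(BaseModel):
    """How one support centre's pool is shared over receiving centres."""

    kind: BasisKind = BasisKind.direct_cost_share
    weights: Optional[dict[str, float]] = None


class OrderingPolicy(str, enum.Enum):
    descending_cost = "descending_cost"
    explicit_list = "explicit_list"


class AllocationConfig(BaseModel):
    """Step-down ordering policy and per-centre allocation bases.

    The default basis — each receiver weighted by its own pre-allocation
    indirect cost — is always computable and scale-free, and keeps results
    independent of floating-point accumulation order because weights are
    never updated mid-cascade.
    """

    ordering: OrderingPolicy = OrderingPolicy.descending_cost
    explicit_order: Optional[list[str]] = None
    basis_map: dict[str, AllocationBasis] = Field(default_factory=dict)
    default_basis: AllocationBasis = Field(default_factory=AllocationBasis)


@dataclass
class AllocationResult:
    """Outcome of one facility's step-down run."""

    final_totals: dict[str, CategoryTotals]
    direct_costs: dict[str, float]
    trace: list[tuple[str, str, float]] = field(default_factory=list)

    def final_total(self, centre_id: str) -> float:
        return sum(self.final_totals[centre_id].values())

    @property
    def total_final_cost(self) -> float:
        return sum(self.final_total(c) for c in self.final_totals)

    @property
    def total_direct_cost(self) -> float:
        return sum(self.direct_costs.values())

    def category_margins(self) -> CategoryTotals:
        out = _zero()
        for totals in self.final_totals.values():
            for cat, v in totals.items():
                out[cat] += v
        return out


@dataclass(frozen=True)
class UnitCost:
    """Cost of one output unit, decomposed two ways: fixed+variable and direct+indirect."""

    total: float
    fixed: float = 0.0
    variable: float = 0.0
    direct: float = 0.0
    indirect: float = 0.0


@dataclass(frozen=True)
class UnitCosts:
    """Per-visit, per-admission and per-bed-day unit costs of one facility.

    Inpatient entries are ``None`` for facilities without inpatient care.
    """

    per_visit: Optional[UnitCost] = None
    per_admission: Optional[UnitCost] = None
    per_bed_day: Optional[UnitCost] = None


def classify_costs(
    record: FacilityRecord,
) -> tuple[dict[str, float], dict[str, CategoryTotals]]:
    """Split the ledger into direct (per cost unit) and indirect (per centre) buckets."""
    direct: dict[str, float] = {}
    indirect: dict[str, CategoryTotals] = {}
    for item in record.items:
        if item.traceability is Traceability.direct:
            if not item.target:
                raise AllocationError("direct cost item without a cost-unit id")
            direct[item.target] = direct.get(item.target, 0.0) + item.amount
        else:
            indirect.setdefault(item.target, _zero())[item.category] += item.amount
    return direct, indirect


def order_support_centres(
    centres: Sequence[CostCentre],
    config: AllocationConfig,
    indirect_totals: Mapping[str, float],
) -> list[str]:
    """Closure order of support centres.

    ``descending_cost`` sorts by accumulated indirect cost, largest first,
    ties broken by centre id ascending; ``explicit_list`` returns the
    configured order after checking it covers every support centre exactly once.
    """
    support_ids = [c.id for c in centres if c.kind is CentreKind.support]
    if config.ordering is OrderingPolicy.explicit_list:
        order = config.explicit_order or []
        if sorted(order) != sorted(support_ids):
            raise ConfigError(
                f"explicit_order {order} must contain every support centre "
                f"{sorted(support_ids)} exactly once"
            )
        return list(order)
    return sorted(support_ids, key=lambda cid: (-indirect_totals.get(cid, 0.0), cid))


def _basis_weights(
    basis: AllocationBasis,
    receivers: Sequence[CostCentre],
    own_indirect: Mapping[str, float],
    source_id: str,
) -> dict[str, float]:
    kind = basis.kind
    if kind is BasisKind.explicit_weights or (
        basis.weights is not None and kind in (BasisKind.staff_count, BasisKind.floor_area)
    ):
        if not basis.weights:
            raise ConfigError(f"basis for centre {source_id!r} needs explicit weights")
        w = {c.id: float(basis.weights.get(c.id, 0.0)) for c in receivers}
    elif kind in (BasisKind.staff_count, BasisKind.floor_area):
        raise ConfigError(
            f"basis {kind.value!r} for centre {source_id!r} requires explicit weights"
        )
    elif kind in (BasisKind.bed_days, BasisKind.patient_days):
        w = {
            c.id: c.output_count if c.output_measure is OutputMeasure.bed_days else 0.0
            for c in receivers
        }
    elif kind is BasisKind.outpatient_visits:
        w = {
            c.id: c.output_count
            if c.output_measure is OutputMeasure.outpatient_visits
            else 0.0
            for c in receivers
        }
    else:  # direct_cost_share: receiver's own indirect cost before any allocation
        w = {c.id: own_indirect.get(c.id, 0.0) for c in receivers}
    if any(v < 0 for v in w.values()):
        raise ConfigError(f"negative basis weight for centre {source_id!r}")
    if sum(w.values()) <= 0:
        raise AllocationError(
            f"all-zero allocation basis for support centre {source_id!r} "
            f"over receivers {[c.id for c in receivers]}"
        )
    return w


def stepdown_allocate(
    record: FacilityRecord, config: AllocationConfig | None = None
) -> AllocationResult:
    """Run one-pass step-down allocation on a facility ledger.

    Support centres are closed in the configured order; each closed centre's
    accumulated per-category cost is distributed over all not-yet-closed
    centres (later supports and all finals) in proportion to its basis
    weights.  Conservation holds exactly: final totals plus direct costs equal
    the ledger total.
    """
    config = config or AllocationConfig()
    finals = record.final_centres
    if not finals:
        raise AllocationError(f"facility {record.id} declares no final cost centre")

    direct, indirect = classify_costs(record)
    pools: dict[str, CategoryTotals] = {c.id: _zero() for c in record.centres}
    for cid, cats in indirect.items():
        for cat, v in cats.items():
            pools[cid][cat] += v
    own_totals = {cid: sum(cats.values()) for cid, cats in pools.items()}

    order = order_support_centres(record.centres, config, own_totals)
    closed: set[str] = set()
    trace: list[tuple[str, str, float]] = []
    by_id = {c.id: c for c in record.centres}

    for pos, sid in enumerate(order):
        receivers = [by_id[cid] for cid in order[pos + 1 :]] + finals
        basis = config.basis_map.get(sid, config.default_basis)
        weights = _basis_weights(basis, receivers, own_totals, sid)
        wsum = sum(weights.values())
        pool = pools[sid]
        pool_total = sum(pool.values())
        for c in receivers:
            frac = weights[c.id] / wsum
            if frac == 0.0:
                continue
            for cat in CostCategory:
                pools[c.id][cat] += pool[cat] * frac
            trace.append((sid, c.id, pool_total * frac))
        pools[sid] = _zero()
        closed.add(sid)

    final_totals = {c.id: pools[c.id] for c in finals}
    return AllocationResult(final_totals=final_totals, direct_costs=direct, trace=trace)


class FixedSplitPolicy(str, enum.Enum):
    """Which input categories count as fixed when decomposing unit costs."""

    fixed_only = "fixed_only"
    fixed_plus_staffing = "fixed_plus_staffing"


def _fixed_categories(policy: FixedSplitPolicy) -> set[CostCategory]:
    cats = {CostCategory.fixed}
    if policy is FixedSplitPolicy.fixed_plus_staffing:
        cats.add(CostCategory.staffing)
    return cats


def unit_costs(
    result: AllocationResult,
    statistics: ServiceStatistics,
    record: FacilityRecord | None = None,
    policy: FixedSplitPolicy = FixedSplitPolicy.fixed_only,
) -> UnitCosts:
    """Divide allocated final-centre pools by output counts.

    Final centres measured in outpatient visits form the outpatient pool;
    centres measured in bed-days or admissions form the inpatient pool, which
    is divided by bed-days for the per-bed-day cost and by admissions for the
    per-admission cost (so their ratio is the average length of stay).  Direct
    costs are attributed through the facility's cost-unit registry.  A nonzero
    pool against a zero output raises :class:`~khscm.errors.UnitCostError`;
    callers exclude (and count) such facilities rather than dropping them
    silently.
    """
    if record is None:
        raise UnitCostError("unit_costs needs the facility record for centre metadata")
    fixed_cats = _fixed_categories(policy)
    by_id = {c.id: c for c in record.centres}

    def pool_for(measures: set[OutputMeasure]) -> tuple[float, float]:
        total = fixed = 0.0
        for cid, cats in result.final_totals.items():
            if by_id[cid].output_measure in measures:
                for cat, v in cats.items():
                    total += v
                    if cat in fixed_cats:
                        fixed += v
        return total, fixed

    def direct_for(measures: set[OutputMeasure]) -> float:
        return sum(
            v
            for unit, v in result.direct_costs.items()
            if record.cost_units.get(unit) in measures
        )

    op_total, op_fixed = pool_for({OutputMeasure.outpatient_visits})
    op_direct = direct_for({OutputMeasure.outpatient_visits})
    ip_total, ip_fixed = pool_for({OutputMeasure.bed_days, OutputMeasure.admissions})
    ip_direct = direct_for({OutputMeasure.bed_days, OutputMeasure.admissions})

    per_visit = per_admission = per_bed_day = None

    if op_total + op_direct > 0 or statistics.outpatient_visits > 0:
        if statistics.outpatient_visits <= 0:
            raise UnitCostError(
                f"facility {record.id}: outpatient cost {op_total + op_direct:.2f} "
                "against zero outpatient visits"
            )
        n = statistics.outpatient_visits
        per_visit = UnitCost(
            total=(op_total + op_direct) / n,
            fixed=op_fixed / n,
            variable=(op_total - op_fixed + op_direct) / n,
            direct=op_direct / n,
            indirect=op_total / n,
        )

    if ip_total + ip_direct > 0:
        if statistics.bed_days <= 0 or statistics.admissions <= 0:
            raise UnitCostError(
                f"facility {record.id}: inpatient cost {ip_total + ip_direct:.2f} "
                "against zero admissions or bed-days"
            )
        nb, na = statistics.bed_days, statistics.admissions
        per_bed_day = UnitCost(
            total=(ip_total + ip_direct) / nb,
            fixed=ip_fixed / nb,
            variable=(ip_total - ip_fixed + ip_direct) / nb,
            direct=ip_direct / nb,
            indirect=ip_total / nb,
        )
        per_admission = UnitCost(
            total=(ip_total + ip_direct) / na,
            fixed=ip_fixed / na,
            variable=(ip_total - ip_fixed + ip_direct) / na,
            direct=ip_direct / na,
            indirect=ip_total / na,
        )

    return UnitCosts(per_visit=per_visit, per_admission=per_admission, per_bed_day=per_bed_day)


def unit_cost_ratios(u: UnitCosts) -> tuple[Optional[float], Optional[float]]:
    """(admission/bed-day, bed-day/visit) cost ratios at 1 dp, half away from zero.

    The first ratio approximates the average length of stay.  A ratio whose
    inputs are missing is ``None``, never zero.
    """
    from .util import round_half_away

    admission_per_bedday = None
    bedday_per_visit = None
    if u.per_admission is not None and u.per_bed_day is not None and u.per_bed_day.total > 0:
        admission_per_bedday = round_half_away(u.per_admission.total / u.per_bed_day.total, 1)
    if u.per_bed_day is not None and u.per_visit is not None and u.per_visit.total > 0:
        bedday_per_visit = round_half_away(u.per_bed_day.total / u.per_visit.total, 1)
    return admission_per_bedday, bedday_per_visit
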