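"""What-if simulation: standard-occupancy unit costs and coverage response.

Two mechanisms drive every scenario:

*Standard occupancy.*  Because fixed and variable costs are tracked
separately, inpatient unit costs can be restated at a standard bed occupancy
(85% by default): the fixed cost per bed-day is rescaled by the ratio of
actual to standard bed-days while the variable cost per bed-day is
unchanged, and the cost per admission follows as the average length of stay
times the standard bed-day cost.  An under-utilized facility's standard unit
costs are therefore strictly below its actual ones.

*Coverage response.*  National cost as a function of coverage (the share of
theoretical need met by professional services, ~25% at baseline) is
subproportional: scaling demand by a factor m scales only the variable part,
giving a cost factor (F + mV)/(F + V) <= m.  Beyond a capacity-utilization
threshold, discrete capacity blocks are added at a configured step cost,
making the curve piecewise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ScenarioError
from .facility import CostCategory
from .reporting import CostMatrix
from .stepdown import FixedSplitPolicy, UnitCost, UnitCosts

__all__ = [
    "ScenarioSpec",
    "CoveragePoint",
    "CoverageCurve",
    "standard_occupancy_unit_costs",
    "fixed_variable_split",
    "demand_multiplier_factor",
    "coverage_response",
    "FixedSplitPolicy",
]


class ScenarioSpec(BaseModel):
    """Scenario parameters.

    ``standard_occupancy`` is the benchmark bed occupancy; ``baseline_coverage``
    the share of theoretical need currently met; ``capacity_threshold`` the
    capacity-utilization multiple (relative to baseline) beyond which capacity
    must expand, in blocks of ``capacity_block_size`` utilization units
    costing ``expansion_step_cost`` each.
    """

    standard_occupancy: float = Field(default=0.85, gt=0, le=1.5)
    demand_multipliers: list[float] = Field(default_factory=lambda: [1.0, 1.4, 2.0, 3.0])
    baseline_coverage: float = Field(default=0.25, gt=0, le=1.5)
    capacity_threshold: float = Field(default=1.4, gt=0)
    capacity_block_size: float = Field(default=0.2, gt=0)
    expansion_step_cost: float = Field(default=0.0, ge=0)
    fixed_split_policy: FixedSplitPolicy = FixedSplitPolicy.fixed_only

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSpec":
        if any(m <= 0 for m in self.demand_multipliers):
            raise ValueError("demand multipliers must be positive")
        return self


@dataclass(frozen=True)
class CoveragePoint:
    coverage: float
    total_cost: float
    cost_factor: float


@dataclass
class CoverageCurve:
    """Cost as a function of coverage; coverage strictly increasing, cost nondecreasing."""

    points: list[CoveragePoint]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.coverage, p.total_cost, p.cost_factor) for p in self.points],
            columns=["coverage", "total_cost", "cost_factor"],
        )


def fixed_variable_split(
    matrix: CostMatrix, policy: FixedSplitPolicy = FixedSplitPolicy.fixed_only
) -> tuple[float, float]:
    """Decompose a cost matrix into (fixed, variable) totals; F + V is the grand total.

    ``fixed_only`` counts the annualized capital column as fixed;
    ``fixed_plus_staffing`` additionally treats staffing as fixed (hiring is
    sticky), leaving drugs and other recurrent cost variable.
    """
    ct = matrix.column_totals
    fixed = float(ct[CostCategory.fixed.value])
    if policy is FixedSplitPolicy.fixed_plus_staffing:
        fixed += float(ct[CostCategory.staffing.value])
    return fixed, matrix.grand_total - fixed


def demand_multiplier_factor(fixed: float, variable: float, m: float) -> float:
    """Within-capacity cost factor (F + mV)/(F + V) for a demand multiplier m."""
    if fixed < 0 or variable < 0:
        raise ScenarioError("fixed and variable totals must be nonnegative")
    if fixed + variable <= 0:
        raise ScenarioError("baseline cost must be positive")
    if m <= 0:
        raise ScenarioError(f"demand multiplier must be positive, got {m}")
    return (fixed + m * variable) / (fixed + variable)


def standard_occupancy_unit_costs(
    u: UnitCosts, beds: float, actual_bed_days: float, spec: ScenarioSpec | None = None
) -> UnitCosts:
    """Restate inpatient unit costs at the standard occupancy rate.

    Standard bed-days = beds x 365 x standard occupancy.  The fixed component
    per bed-day is rescaled by actual/standard bed-days; the variable
    component is unchanged; the cost per admission is the actual average
    length of stay (admission/bed-day cost ratio) times the standard bed-day
    cost.  Outpatient unit costs pass through unchanged (occupancy is a bed
    concept).
    """
    spec = spec or ScenarioSpec()
    if beds <= 0 or actual_bed_days <= 0:
        raise ScenarioError("beds and actual_bed_days must be positive")
    if u.per_bed_day is None or u.per_admission is None:
        raise ScenarioError("standard-occupancy restatement needs inpatient unit costs")
    pbd = u.per_bed_day
    if pbd.total > 0 and pbd.fixed == 0.0 and pbd.variable == 0.0:
        raise ScenarioError("unit costs carry no fixed/variable split")

    standard_bed_days = beds * 365.0 * spec.standard_occupancy
    scale = actual_bed_days / standard_bed_days
    std_fixed = pbd.fixed * scale
    std_total = std_fixed + pbd.variable
    # the direct/indirect decomposition rescales the indirect (overhead) part only
    std_indirect = max(std_total - pbd.direct, 0.0)
    per_bed_day = UnitCost(
        total=std_total,
        fixed=std_fixed,
        variable=pbd.variable,
        direct=pbd.direct,
        indirect=std_indirect,
    )

    alos = u.per_admission.total / pbd.total if pbd.total > 0 else 0.0
    adm_total = alos * std_total
    ratio = adm_total / u.per_admission.total if u.per_admission.total > 0 else 0.0
    pa = u.per_admission
    per_admission = UnitCost(
        total=adm_total,
        fixed=pa.fixed * (std_fixed / pbd.fixed) if pbd.fixed > 0 else pa.fixed,
        variable=pa.variable,
        direct=pa.direct * ratio,
        indirect=pa.indirect * ratio,
    )
    return UnitCosts(per_visit=u.per_visit, per_admission=per_admission, per_bed_day=per_bed_day)


def coverage_response(
    matrix: CostMatrix,
    spec: ScenarioSpec,
    coverages: Optional[Sequence[float]] = None,
) -> CoverageCurve:
    """Total cost over a coverage grid via the fixed/variable decomposition.

    Utilization u = coverage / baseline scales the variable part; above the
    capacity threshold, ceil((u - threshold)/block) capacity blocks are added
    at the configured step cost.  Coverage below baseline is an error
    (capacity shrinkage is not modelled).
    """
    fixed, variable = fixed_variable_split(matrix, spec.fixed_split_policy)
    baseline_cost = fixed + variable
    if baseline_cost <= 0:
        raise ScenarioError("baseline cost must be positive")

    grid = (
        list(coverages)
        if coverages is not None
        else [m * spec.baseline_coverage for m in sorted(spec.demand_multipliers)]
    )
    if any(b >= a for a, b in zip(grid[1:], grid)):
        raise ScenarioError("coverage grid must be strictly increasing")

    points: list[CoveragePoint] = []
    for c in grid:
        if c < spec.baseline_coverage - 1e-12:
            raise ScenarioError(
                f"coverage {c} below baseline {spec.baseline_coverage}; "
                "shrinkage is not modelled"
            )
        u = c / spec.baseline_coverage
        cost = fixed + u * variable
        if u > spec.capacity_threshold:
            blocks = math.ceil((u - spec.capacity_threshold) / spec.capacity_block_size)
            cost += blocks * spec.expansion_step_cost
        points.append(CoveragePoint(coverage=c, total_cost=cost, cost_factor=cost / baseline_cost))

    for a, b in zip(points, points[1:]):
        if b.total_cost < a.total_cost - 1e-9:
            raise ScenarioError("coverage curve must be nondecreasing")
    return CoverageCurve(points=points)
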