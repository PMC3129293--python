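"""Facility domain model and fixture IO.

A :class:`FacilityRecord` is one institution's complete costing input: its
cost-centre structure, cost-item ledger (by fiscal year), asset register,
payroll and annual service statistics, tagged with the sampling stratum
(level of care, trustee, urban/rural location).

Cost items are either *direct* (attributable to a single costing unit such as
an outpatient visit or admission) or *indirect* (attached to the cost centre
where they occur); support centres (administration, laundry, kitchen) are
later emptied onto final, patient-serving centres by the step-down engine.

File formats (all UTF-8, plain text):

* ``facility.csv``   — one row per cost item:
  ``centre_id, cost_unit_id, category, year, amount_ksh, traceability``
* ``centres.csv``    — ``centre_id, name, kind, output_measure, output_count``
* ``statistics.json``— service statistics plus ``beds, level, trustee, location``
* ``assets.csv``     — asset register (see :mod:`khscm.annualize`)
* ``payroll.csv``    — staff positions (see :mod:`khscm.annualize`)
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import LedgerError

# --------------------------------------------------------------------------- enums


class CostCategory(str, enum.Enum):
    """The four national summary input categories."""

    drugs_supplies = "drugs_supplies"
    staffing = "staffing"
    other_recurrent = "other_recurrent"
    fixed = "fixed"


class Traceability(str, enum.Enum):
    direct = "direct"
    indirect = "indirect"


class CentreKind(str, enum.Enum):
    support = "support"
    final = "final"


class OutputMeasure(str, enum.Enum):
    outpatient_visits = "outpatient_visits"
    admissions = "admissions"
    bed_days = "bed_days"
    none = "none"


class Level(str, enum.Enum):
    """Level of care; 2=dispensary ... 6=tertiary hospital, plus non-clinical units."""

    dispensary = "2"
    health_centre = "3"
    district_hospital = "4"
    provincial_hospital = "5"
    tertiary_hospital = "6"
    nursing_home = "nursing_home"
    admin_district = "admin_district"
    admin_province = "admin_province"
    ministry = "ministry"


#: Levels that are administrative overhead units, not service facilities.
ADMIN_LEVELS = frozenset(
    {Level.admin_district, Level.admin_province, Level.ministry}
)


class Trustee(str, enum.Enum):
    public = "public"
    fbo_ngo = "fbo_ngo"
    private = "private"


class Location(str, enum.Enum):
    urban = "urban"
    rural = "rural"


# --------------------------------------------------------------------------- records


class CostItem(BaseModel):
    """One ledger line: an amount in Ksh against a centre (indirect) or cost unit (direct)."""

    amount: float = Field(ge=0)
    category: CostCategory
    year: str
    traceability: Traceability
    target: str

    @model_validator(mode="after")
    def _quantize(self) -> "CostItem":
        # ledger amounts are whole-cent figures; quantize on construction
        object.__setattr__(self, "amount", round(self.amount, 2))
        return self


class CostCentre(BaseModel):
    id: str
    name: str = ""
    kind: CentreKind
    output_measure: OutputMeasure = OutputMeasure.none
    output_count: float = Field(default=0.0, ge=0)


class ServiceStatistics(BaseModel):
    """Annual activity of one facility."""

    outpatient_visits: float = Field(default=0.0, ge=0)
    admissions: float = Field(default=0.0, ge=0)
    bed_days: float = Field(default=0.0, ge=0)
    catchment_population: float = Field(default=0.0, ge=0)


class Asset(BaseModel):
    """One asset-register line.

    Buildings may be given as ``floor_area`` x ``unit_build_cost`` instead of an
    initial value.  ``condition_adjustment`` multiplies the service life (a
    building in poor condition gets a shorter effective life with a factor
    below one).  ``centre_id`` names the cost centre that carries the annual
    depreciation charge.
    """

    asset_class: str  # general_equipment | medical_equipment | vehicle | building
    initial_value: Optional[float] = Field(default=None, gt=0)
    floor_area: Optional[float] = Field(default=None, gt=0)
    unit_build_cost: Optional[float] = Field(default=None, gt=0)
    lifetime_years: Optional[float] = Field(default=None, gt=0)
    condition_adjustment: float = Field(default=1.0, gt=0)
    centre_id: str = ""

    @model_validator(mode="after")
    def _check_valuation(self) -> "Asset":
        if self.asset_class == "building":
            if self.initial_value is None and not (
                self.floor_area and self.unit_build_cost
            ):
                raise ValueError(
                    "building asset needs initial_value or floor_area and unit_build_cost"
                )
        elif self.initial_value is None:
            raise ValueError(f"{self.asset_class} asset needs initial_value")
        return self


class StaffPosition(BaseModel):
    """One payroll line; pay may be missing (to be imputed from the public scale)."""

    cadre: str
    annual_base: Optional[float] = Field(default=None, ge=0)
    annual_allowances: float = Field(default=0.0, ge=0)
    working_days: float = Field(default=220.0, gt=0, le=365)
    direct_hours_per_day: float = Field(default=6.0, gt=0, le=24)
    imputed: bool = False


#: Default costing units and the output measure each is divided by.
DEFAULT_COST_UNITS: dict[str, OutputMeasure] = {
    "outpatient_visit": OutputMeasure.outpatient_visits,
    "admission": OutputMeasure.admissions,
    "bed_day": OutputMeasure.bed_days,
}


class FacilityRecord(BaseModel):
    """One institution's complete costing input."""

    id: str
    level: Level
    trustee: Trustee
    location: Location = Location.rural
    province: str = ""
    beds: float = Field(default=0.0, ge=0)
    centres: list[CostCentre] = Field(default_factory=list)
    items: list[CostItem] = Field(default_factory=list)
    assets: list[Asset] = Field(default_factory=list)
    payroll: list[StaffPosition] = Field(default_factory=list)
    statistics: ServiceStatistics = Field(default_factory=ServiceStatistics)
    cost_units: dict[str, OutputMeasure] = Field(
        default_factory=lambda: dict(DEFAULT_COST_UNITS)
    )
    #: fiscal-year labels in chronological order (earliest first); labels are opaque
    year_order: list[str] = Field(default_factory=list)

    @property
    def is_administrative(self) -> bool:
        return self.level in ADMIN_LEVELS

    def centre_by_id(self, cid: str) -> CostCentre:
        for c in self.centres:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def support_centres(self) -> list[CostCentre]:
        return [c for c in self.centres if c.kind is CentreKind.support]

    @property
    def final_centres(self) -> list[CostCentre]:
        return [c for c in self.centres if c.kind is CentreKind.final]

    def total_cost(self, year: str | None = None) -> float:
        return sum(i.amount for i in self.items if year is None or i.year == year)


# --------------------------------------------------------------------------- validation


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``severity`` is ``error`` or ``warning``."""

    field: str
    rule: str
    severity: str
    message: str


#: Occupancy above this multiple of capacity is flagged (over-100% occupancy is
#: a legal, observed state; 150% is an arbitrary sanity bound).
OCCUPANCY_WARNING_FACTOR = 1.5


def validate_facility(record: FacilityRecord) -> list[Violation]:
    """Cross-field invariant checks; violations are data, never exceptions."""
    out: list[Violation] = []
    stats = record.statistics

    if stats.admissions > 0 and record.beds == 0:
        out.append(
            Violation(
                "beds",
                "beds_iff_admissions",
                "error",
                f"facility {record.id} reports {stats.admissions:g} admissions but 0 beds",
            )
        )
    if record.beds > 0 and stats.admissions == 0 and not record.is_administrative:
        out.append(
            Violation(
                "statistics.admissions",
                "beds_iff_admissions",
                "warning",
                f"facility {record.id} has {record.beds:g} beds but no admissions",
            )
        )
    if record.beds > 0 and stats.bed_days > record.beds * 365 * OCCUPANCY_WARNING_FACTOR:
        out.append(
            Violation(
                "statistics.bed_days",
                "occupancy_sanity",
                "warning",
                f"occupancy {stats.bed_days / (record.beds * 365):.0%} exceeds "
                f"{OCCUPANCY_WARNING_FACTOR:.0%} of capacity",
            )
        )

    centre_ids = {c.id for c in record.centres}
    for n, item in enumerate(record.items):
        if item.traceability is Traceability.direct:
            if item.target not in record.cost_units:
                out.append(
                    Violation(
                        f"items[{n}].target",
                        "direct_target_is_cost_unit",
                        "error",
                        f"direct item targets unknown cost unit {item.target!r}",
                    )
                )
        else:
            if item.target not in centre_ids:
                out.append(
                    Violation(
                        f"items[{n}].target",
                        "indirect_target_is_centre",
                        "error",
                        f"indirect item targets undeclared centre {item.target!r}",
                    )
                )

    for c in record.centres:
        if c.kind is CentreKind.final and c.output_measure is OutputMeasure.none:
            out.append(
                Violation(
                    f"centres[{c.id}].output_measure",
                    "final_centre_has_output",
                    "error",
                    f"final centre {c.id!r} has no output measure",
                )
            )
        if c.kind is CentreKind.support and c.output_measure is not OutputMeasure.none:
            out.append(
                Violation(
                    f"centres[{c.id}].output_measure",
                    "support_centre_no_output",
                    "error",
                    f"support centre {c.id!r} declares output measure {c.output_measure.value}",
                )
            )

    for n, a in enumerate(record.assets):
        if a.centre_id and a.centre_id not in centre_ids:
            out.append(
                Violation(
                    f"assets[{n}].centre_id",
                    "asset_target_is_centre",
                    "error",
                    f"asset targets undeclared centre {a.centre_id!r}",
                )
            )
    return out


# --------------------------------------------------------------------------- IO

_LEDGER_COLUMNS = ["centre_id", "cost_unit_id", "category", "year", "amount_ksh", "traceability"]
_CENTRE_COLUMNS = ["centre_id", "name", "kind", "output_measure", "output_count"]
_ASSET_COLUMNS = [
    "asset_class",
    "initial_value_ksh",
    "floor_area_sqm",
    "unit_build_cost_ksh",
    "lifetime_years",
    "condition_adjustment",
    "centre_id",
]
_PAYROLL_COLUMNS = ["cadre", "annual_base_ksh", "annual_allowances_ksh", "working_days", "direct_hours"]


def _opt(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def load_facility_ledger(
    ledger_path: str | Path,
    statistics_path: str | Path | None = None,
    *,
    centres_path: str | Path | None = None,
    assets_path: str | Path | None = None,
    payroll_path: str | Path | None = None,
) -> FacilityRecord:
    """Load and validate one facility from its fixture files.

    ``ledger_path`` may be a directory holding the standard file names
    (``facility.csv``, ``centres.csv``, ``statistics.json`` and optionally
    ``assets.csv``, ``payroll.csv``) or the path to ``facility.csv`` itself
    with the companion paths given explicitly or resolved as siblings.

    Raises :class:`~khscm.errors.LedgerError` naming the offending row when a
    cost item references an undeclared centre or carries a negative amount.
    """
    ledger_path = Path(ledger_path)
    if ledger_path.is_dir():
        base = ledger_path
        ledger_file = base / "facility.csv"
    else:
        base = ledger_path.parent
        ledger_file = ledger_path
    centres_file = Path(centres_path) if centres_path else base / "centres.csv"
    stats_file = Path(statistics_path) if statistics_path else base / "statistics.json"
    assets_file = Path(assets_path) if assets_path else base / "assets.csv"
    payroll_file = Path(payroll_path) if payroll_path else base / "payroll.csv"

    for f in (ledger_file, centres_file, stats_file):
        if not f.exists():
            raise LedgerError(f"missing input file: {f}")

    centres_df = pd.read_csv(centres_file, dtype={"centre_id": str})
    if list(centres_df.columns) != _CENTRE_COLUMNS:
        raise LedgerError(f"{centres_file}: expected columns {_CENTRE_COLUMNS}")
    centres = [
        CostCentre(
            id=str(r.centre_id),
            name="" if pd.isna(r.name) else str(r.name),
            kind=CentreKind(r.kind),
            output_measure=OutputMeasure(r.output_measure),
            output_count=float(r.output_count),
        )
        for r in centres_df.itertuples()
    ]
    centre_ids = {c.id for c in centres}

    meta = json.loads(stats_file.read_text())
    stats = ServiceStatistics(
        **{k: meta.get(k, 0.0) for k in ServiceStatistics.model_fields}
    )

    ledger_df = pd.read_csv(ledger_file, dtype={"centre_id": str, "cost_unit_id": str})
    if list(ledger_df.columns) != _LEDGER_COLUMNS:
        raise LedgerError(f"{ledger_file}: expected columns {_LEDGER_COLUMNS}")
    cost_units = {
        k: OutputMeasure(v)
        for k, v in meta.get(
            "cost_units", {k: m.value for k, m in DEFAULT_COST_UNITS.items()}
        ).items()
    }

    items: list[CostItem] = []
    for n, r in enumerate(ledger_df.itertuples(), start=2):  # header is line 1
        amount = float(r.amount_ksh)
        if amount < 0:
            raise LedgerError(f"{ledger_file} line {n}: negative amount {amount}")
        trace = Traceability(r.traceability)
        if trace is Traceability.direct:
            target = "" if pd.isna(r.cost_unit_id) else str(r.cost_unit_id)
            if target not in cost_units:
                raise LedgerError(
                    f"{ledger_file} line {n}: direct item references unknown cost unit {target!r}"
                )
        else:
            target = "" if pd.isna(r.centre_id) else str(r.centre_id)
            if target not in centre_ids:
                raise LedgerError(
                    f"{ledger_file} line {n}: indirect item references undeclared centre {target!r}"
                )
        items.append(
            CostItem(
                amount=amount,
                category=CostCategory(r.category),
                year=str(r.year),
                traceability=trace,
                target=target,
            )
        )

    assets: list[Asset] = []
    if assets_file.exists():
        adf = pd.read_csv(assets_file, dtype={"centre_id": str})
        if list(adf.columns) != _ASSET_COLUMNS:
            raise LedgerError(f"{assets_file}: expected columns {_ASSET_COLUMNS}")
        for n, r in enumerate(adf.itertuples(), start=2):
            try:
                assets.append(
                    Asset(
                        asset_class=str(r.asset_class),
                        initial_value=_opt(r.initial_value_ksh),
                        floor_area=_opt(r.floor_area_sqm),
                        unit_build_cost=_opt(r.unit_build_cost_ksh),
                        lifetime_years=_opt(r.lifetime_years),
                        condition_adjustment=_opt(r.condition_adjustment) or 1.0,
                        centre_id="" if pd.isna(r.centre_id) else str(r.centre_id),
                    )
                )
            except ValueError as exc:
                raise LedgerError(f"{assets_file} line {n}: {exc}") from exc

    payroll: list[StaffPosition] = []
    if payroll_file.exists():
        pdf = pd.read_csv(payroll_file)
        if list(pdf.columns) != _PAYROLL_COLUMNS:
            raise LedgerError(f"{payroll_file}: expected columns {_PAYROLL_COLUMNS}")
        for r in pdf.itertuples():
            payroll.append(
                StaffPosition(
                    cadre=str(r.cadre),
                    annual_base=_opt(r.annual_base_ksh),
                    annual_allowances=_opt(r.annual_allowances_ksh) or 0.0,
                    working_days=_opt(r.working_days) or 220.0,
                    direct_hours_per_day=_opt(r.direct_hours) or 6.0,
                )
            )

    years = meta.get("year_order") or sorted({i.year for i in items})
    return FacilityRecord(
        id=str(meta.get("id", base.name)),
        level=Level(str(meta["level"])),
        trustee=Trustee(meta["trustee"]),
        location=Location(meta.get("location", "rural")),
        province=meta.get("province", ""),
        beds=float(meta.get("beds", 0)),
        centres=centres,
        items=items,
        assets=assets,
        payroll=payroll,
        statistics=stats,
        cost_units=cost_units,
        year_order=list(years),
    )


def write_facility(record: FacilityRecord, out_dir: str | Path) -> Path:
    """Write a record back to the fixture file layout (inverse of the loader)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "centre_id": i.target if i.traceability is Traceability.indirect else "",
                "cost_unit_id": i.target if i.traceability is Traceability.direct else "",
                "category": i.category.value,
                "year": i.year,
                "amount_ksh": i.amount,
                "traceability": i.traceability.value,
            }
            for i in record.items
        ],
        columns=_LEDGER_COLUMNS,
    ).to_csv(out / "facility.csv", index=False)

    pd.DataFrame(
        [
            {
                "centre_id": c.id,
                "name": c.name,
                "kind": c.kind.value,
                "output_measure": c.output_measure.value,
                "output_count": c.output_count,
            }
            for c in record.centres
        ],
        columns=_CENTRE_COLUMNS,
    ).to_csv(out / "centres.csv", index=False)

    pd.DataFrame(
        [
            {
                "asset_class": a.asset_class,
                "initial_value_ksh": a.initial_value,
                "floor_area_sqm": a.floor_area,
                "unit_build_cost_ksh": a.unit_build_cost,
                "lifetime_years": a.lifetime_years,
                "condition_adjustment": a.condition_adjustment,
                "centre_id": a.centre_id,
            }
            for a in record.assets
        ],
        columns=_ASSET_COLUMNS,
    ).to_csv(out / "assets.csv", index=False)

    pd.DataFrame(
        [
            {
                "cadre": p.cadre,
                "annual_base_ksh": p.annual_base,
                "annual_allowances_ksh": p.annual_allowances,
                "working_days": p.working_days,
                "direct_hours": p.direct_hours_per_day,
            }
            for p in record.payroll
        ],
        columns=_PAYROLL_COLUMNS,
    ).to_csv(out / "payroll.csv", index=False)

    meta = {
        "id": record.id,
        "level": record.level.value,
        "trustee": record.trustee.value,
        "location": record.location.value,
        "province": record.province,
        "beds": record.beds,
        "year_order": record.year_order,
        "cost_units": {k: m.value for k, m in record.cost_units.items()},
        **record.statistics.model_dump(),
    }
    (out / "statistics.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out
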