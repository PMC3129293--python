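"""Seeded synthetic facility-sample generator.

The generator emulates the inputs of a stratified national costing survey:
facility ledgers over two fiscal years, cost-centre structures, asset
registers, payrolls, service statistics, patient exit interviews, and
essential-package treatment schemes (actual and normative variants).

Study conditions are built in as defaults.  The stratum plan mirrors the
published sample composition (85 government, 35 faith-based/NGO, 34 private
facilities — 154 in total, plus the central ministry as a separate
super-overhead record).  Per-stratum cost scales default to the published
national summary cells divided by the stratum's facility count, so the
expected national aggregate of a generated sample matches the published
matrix; private strata draw with a wider log-normal dispersion than public
strata, reproducing the wide private-sector cost spreads the survey found.
Occupancy defaults encode the observed pattern: public district hospitals
over capacity (mean 107%), provincial hospitals at 90%, private hospitals
heavily under-utilized.

Every monetary draw is a mean-one log-normal multiplier times a per-stratum
category scale, and all random-number consumption is independent of the
scales.  Calibration to a target matrix is therefore a deterministic
rescaling: regenerating with the same seed after multiplying each stratum's
scales by target/actual reproduces the target cells to floating-point
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .annualize import PriceList, annualize_record
from .errors import CalibrationError, ConfigError
from .facility import (
    Asset,
    CentreKind,
    CostCategory,
    CostCentre,
    CostItem,
    FacilityRecord,
    Level,
    Location,
    OutputMeasure,
    ServiceStatistics,
    StaffPosition,
    Traceability,
    Trustee,
    write_facility,
)
from .keph import (
    N_KEPH_CONDITIONS,
    ExitInterview,
    KephScheme,
    PatientType,
    Setting,
    Variant,
)
from .reporting import CostMatrix, SamplingWeights, load_published_matrix, national_totals
from .util import KSH_PER_EUR

CATEGORIES = list(CostCategory)

#: Fiscal years emitted by the generator (earlier first).
YEARS = ("2005/2006", "2006/2007")


# --------------------------------------------------------------------- stratum plan


def stratum_label(level: Level, trustee: Trustee) -> str:
    """Published summary-row label for a (level, trustee) stratum."""
    if level is Level.admin_district:
        return "District Administration"
    if level is Level.admin_province:
        return "Provincial Administration"
    if level is Level.ministry:
        return "Ministry of Health"
    if level is Level.nursing_home:
        if trustee is Trustee.public:
            return "Nursing Home/Enhanced HC (Public)"
        if trustee is Trustee.fbo_ngo:
            return "Nursing Home/Enhanced HC (FBO/NGO)"
        return "Nursing Home/Enhanced HC"
    suffix = {Trustee.public: "Public", Trustee.fbo_ngo: "FBO/NGO", Trustee.private: "Private"}[
        trustee
    ]
    if trustee in (Trustee.fbo_ngo, Trustee.private) and level in (
        Level.dispensary,
        Level.health_centre,
    ):
        return f"Dispensary, Health Centre ({suffix})"
    name = {
        Level.dispensary: "Dispensary",
        Level.health_centre: "Health Centre",
        Level.district_hospital: "District Hospital",
        Level.provincial_hospital: "Provincial Hospital",
        Level.tertiary_hospital: "Tertiary Hospital",
    }[level]
    return f"{name} ({suffix})"


class StratumConfig(BaseModel):
    """One sampling stratum: its facility count and cost-scale parameters."""

    level: Level
    trustee: Trustee
    count: int = Field(ge=0)
    #: mean annual cost [Ksh] per facility by category (the log-normal location)
    category_scale: dict[CostCategory, float] = Field(default_factory=dict)
    #: log-normal sigma by category (spread; private strata default wider)
    sigma: float = Field(default=0.3, gt=0)
    occupancy_mean: float = Field(default=0.7, gt=0)
    occupancy_sd: float = Field(default=0.08, ge=0)
    beds: float = Field(default=0.0, ge=0)
    visits_mean: float = Field(default=20_000.0, ge=0)
    alos_days: float = Field(default=5.0, gt=0)
    urban_fraction: float = Field(default=0.3, ge=0, le=1)

    @property
    def label(self) -> str:
        return stratum_label(self.level, self.trustee)


class InterviewParams(BaseModel):
    """Exit-interview generation parameters.

    Outside-drug means are higher for public facilities (stock-outs push
    patients to private pharmacies) than for FBO/NGO or private ones.
    """

    n: int = Field(default=1369, ge=0)
    outside_drug_mean: dict[Trustee, float] = Field(
        default_factory=lambda: {
            Trustee.public: 300.0,
            Trustee.fbo_ngo: 150.0,
            Trustee.private: 80.0,
        }
    )
    sigma: float = Field(default=0.5, gt=0)
    inpatient_fraction: float = Field(default=0.3, ge=0, le=1)
    user_fee_mean: float = Field(default=120.0, ge=0)
    transport_mean: float = Field(default=60.0, ge=0)


class GeneratorConfig(BaseModel):
    """Full generator configuration; identical seed + config => identical output."""

    seed: int = 42
    strata: list[StratumConfig] = Field(default_factory=list)
    ministry: Optional[StratumConfig] = None
    interviews: InterviewParams = Field(default_factory=InterviewParams)
    inflation: float = 0.05
    #: sanity band for each facility stratum's fixed-cost share of total
    fixed_share_band: tuple[float, float] = (0.05, 0.55)


# structural defaults per level (bed complements, throughput, stay lengths)
_LEVEL_STRUCT = {
    Level.dispensary: dict(beds=0.0, visits=15_000.0, alos=2.0),
    Level.health_centre: dict(beds=20.0, visits=20_000.0, alos=1.0),
    Level.district_hospital: dict(beds=120.0, visits=60_000.0, alos=5.0),
    Level.provincial_hospital: dict(beds=300.0, visits=80_000.0, alos=7.0),
    Level.tertiary_hospital: dict(beds=600.0, visits=120_000.0, alos=10.0),
    Level.nursing_home: dict(beds=15.0, visits=2_000.0, alos=20.0),
    Level.admin_district: dict(beds=0.0, visits=0.0, alos=1.0),
    Level.admin_province: dict(beds=0.0, visits=0.0, alos=1.0),
    Level.ministry: dict(beds=0.0, visits=0.0, alos=1.0),
}

_SIGMA = {Trustee.public: 0.25, Trustee.fbo_ngo: 0.5, Trustee.private: 0.7}

_OCCUPANCY = {
    (Level.district_hospital, Trustee.public): 1.07,
    (Level.provincial_hospital, Trustee.public): 0.90,
    (Level.tertiary_hospital, Trustee.public): 0.95,
}


def _default_occupancy(level: Level, trustee: Trustee) -> float:
    if (level, trustee) in _OCCUPANCY:
        return _OCCUPANCY[(level, trustee)]
    if trustee is Trustee.private:
        return 0.45
    if trustee is Trustee.fbo_ngo:
        return 0.60
    return 0.80


#: Default facility counts per (level, trustee) — the published sample plan:
#: 85 government + 35 FBO/NGO + 34 private = 154 analysed facilities, with the
#: 9 district/provincial administration units split 7 + 2 (not split in print).
DEFAULT_PLAN: list[tuple[Level, Trustee, int]] = [
    (Level.dispensary, Trustee.public, 20),
    (Level.health_centre, Trustee.public, 27),
    (Level.district_hospital, Trustee.public, 20),
    (Level.provincial_hospital, Trustee.public, 7),
    (Level.tertiary_hospital, Trustee.public, 2),
    (Level.admin_district, Trustee.public, 7),
    (Level.admin_province, Trustee.public, 2),
    (Level.dispensary, Trustee.fbo_ngo, 24),
    (Level.district_hospital, Trustee.fbo_ngo, 10),
    (Level.nursing_home, Trustee.fbo_ngo, 1),
    (Level.dispensary, Trustee.private, 10),
    (Level.district_hospital, Trustee.private, 11),
    (Level.tertiary_hospital, Trustee.private, 1),
    (Level.nursing_home, Trustee.private, 12),
]


def default_config(
    seed: int = 42, include_public_nursing_home: bool = False
) -> GeneratorConfig:
    """Generator configuration encoding the study conditions.

    Per-stratum category scales are the published national summary cells
    (converted to Ksh) divided by the stratum's facility count, so a generated
    sample's expected aggregate matches the published matrix.  With
    ``include_public_nursing_home`` one public nursing home is added (a row
    present in the published summary but absent from the sample plan; used for
    full-coverage calibration, not for sample accounting).
    """
    matrix, _ = load_published_matrix()
    plan = list(DEFAULT_PLAN)
    if include_public_nursing_home:
        plan.append((Level.nursing_home, Trustee.public, 1))

    def scales_for(label: str, count: int) -> dict[CostCategory, float]:
        if label not in matrix.frame.index:
            return {c: 0.0 for c in CATEGORIES}
        row = matrix.frame.loc[label]
        return {c: float(row[c.value]) * KSH_PER_EUR / count for c in CATEGORIES}

    strata = []
    for level, trustee, count in plan:
        struct = _LEVEL_STRUCT[level]
        strata.append(
            StratumConfig(
                level=level,
                trustee=trustee,
                count=count,
                category_scale=scales_for(stratum_label(level, trustee), count),
                sigma=0.1 if level.value.startswith("admin") else _SIGMA[trustee],
                occupancy_mean=_default_occupancy(level, trustee),
                beds=struct["beds"],
                visits_mean=struct["visits"],
                alos_days=struct["alos"],
            )
        )
    ministry = StratumConfig(
        level=Level.ministry,
        trustee=Trustee.public,
        count=1,
        category_scale=scales_for("Ministry of Health", 1),
        sigma=0.1,
        beds=0.0,
        visits_mean=0.0,
    )
    return GeneratorConfig(seed=seed, strata=strata, ministry=ministry)


# --------------------------------------------------------------------- generation


@dataclass
class Sample:
    """A generated study sample."""

    facilities: list[FacilityRecord]
    ministry: Optional[FacilityRecord]
    interviews: list[ExitInterview]
    schemes: list[KephScheme]
    price_list: PriceList
    public_salary_scale: dict[str, float] = dfield(default_factory=dict)

    @property
    def all_records(self) -> list[FacilityRecord]:
        return self.facilities + ([self.ministry] if self.ministry else [])

    def counts_by_trustee(self) -> dict[Trustee, int]:
        out = {t: 0 for t in Trustee}
        for f in self.facilities:
            out[f.trustee] += 1
        return out


_CADRES = ["doctor", "clinical_officer", "nurse", "lab_technician", "support_staff"]
_CADRE_PAY_SHARE = [0.25, 0.15, 0.35, 0.10, 0.15]

#: Public-sector annual base salaries [Ksh] by cadre (fallback scale).
PUBLIC_SALARY_SCALE: dict[str, float] = {
    "doctor": 1_200_000.0,
    "clinical_officer": 600_000.0,
    "nurse": 420_000.0,
    "lab_technician": 360_000.0,
    "support_staff": 180_000.0,
}


def default_price_list() -> PriceList:
    """Ministry-style price list: drug and lab codes plus per-level equipment bundles."""
    prices = {f"drug_{k:02d}": float(5 + 25 * k) for k in range(1, 21)}
    prices.update({f"lab_{k:02d}": float(50 + 100 * k) for k in range(1, 6)})
    bundles = {
        "2": {"drug_01": 1.0},
        "3": {"drug_01": 1.0, "lab_01": 1.0},
        "4": {"drug_01": 1.0, "lab_01": 1.0, "lab_02": 1.0},
    }
    return PriceList(prices=prices, equipment_bundles=bundles)


def _lognormal_multiplier(rng: np.random.Generator, sigma: float) -> float:
    # mean-one log-normal: E[exp(N(-s^2/2, s^2))] = 1
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _centre_plan(level: Level, has_inpatient: bool) -> tuple[list[str], list[str]]:
    """(support centre ids, final centre ids) for a facility type."""
    if level in (Level.admin_district, Level.admin_province, Level.ministry):
        return [], []
    supports = ["administration"]
    finals = ["opd"]
    if has_inpatient:
        supports.append("laundry")
        finals.append("wards")
    if level in (Level.district_hospital, Level.provincial_hospital, Level.tertiary_hospital):
        supports.append("kitchen")
        finals.append("maternity")
    return supports, finals


# fraction of each category placed on each centre (direct share handled separately)
def _centre_shares(
    category: CostCategory, supports: list[str], finals: list[str]
) -> dict[str, float]:
    shares: dict[str, float] = {}
    if category is CostCategory.staffing:
        base = {"administration": 0.15, "laundry": 0.05, "kitchen": 0.05}
    elif category is CostCategory.drugs_supplies:
        base = {"administration": 0.02, "laundry": 0.03, "kitchen": 0.05}
    else:
        base = {"administration": 0.30, "laundry": 0.10, "kitchen": 0.10}
    shares.update({s: base[s] for s in supports})
    rest = 1.0 - sum(shares.values())
    per_final = rest / len(finals)
    for f in finals:
        shares[f] = per_final
    return shares


_DIRECT_FRACTION = {
    CostCategory.drugs_supplies: 0.10,
    CostCategory.staffing: 0.05,
    CostCategory.other_recurrent: 0.0,
    CostCategory.fixed: 0.0,
}

# annual depreciation split across asset classes (building/medical/general/vehicle)
_ASSET_MIX = [
    ("building", 0.60, 30.0),
    ("medical_equipment", 0.25, 8.0),
    ("general_equipment", 0.10, 10.0),
    ("vehicle", 0.05, 8.0),
]


def _make_facility(
    rng: np.random.Generator, stratum: StratumConfig, index: int
) -> FacilityRecord:
    """Generate one facility; consumes a fixed number of draws regardless of scales."""
    level, trustee = stratum.level, stratum.trustee
    fid = f"{level.value}-{trustee.value}-{index:03d}"

    # structural draws (fixed count and order; never conditioned on scales)
    mult = {
        (cat, y): _lognormal_multiplier(rng, stratum.sigma)
        for cat in CATEGORIES
        for y in YEARS
    }
    occ = max(0.05, float(rng.normal(stratum.occupancy_mean, stratum.occupancy_sd)))
    visit_mult = _lognormal_multiplier(rng, 0.3)
    staff_jitter = int(rng.integers(0, 4))
    urban = bool(rng.random() < stratum.urban_fraction)

    is_admin = level in (Level.admin_district, Level.admin_province, Level.ministry)
    beds = stratum.beds
    has_inpatient = beds > 0
    visits = 0.0 if is_admin else stratum.visits_mean * visit_mult
    bed_days = beds * 365.0 * occ if has_inpatient else 0.0
    admissions = bed_days / stratum.alos_days if has_inpatient else 0.0

    stats = ServiceStatistics(
        outpatient_visits=round(visits),
        admissions=round(admissions),
        bed_days=round(bed_days),
        catchment_population=round(max(visits, 1.0) * 4),
    )

    # annual cost level per category: scale x multiplier; the two ledger years
    # are chosen so their inflation-uplifted average equals that level
    annual = {
        cat: {
            YEARS[0]: stratum.category_scale.get(cat, 0.0) * mult[(cat, YEARS[0])] / 1.05,
            YEARS[1]: stratum.category_scale.get(cat, 0.0) * mult[(cat, YEARS[1])],
        }
        for cat in CATEGORIES
    }

    items: list[CostItem] = []
    centres: list[CostCentre] = []
    assets: list[Asset] = []
    payroll: list[StaffPosition] = []
    cost_units: dict[str, OutputMeasure]

    if is_admin:
        cost_units = {"administration": OutputMeasure.none}
        for cat in CATEGORIES:
            if cat is CostCategory.fixed:
                continue  # admin rows carry no annualized capital in the summary
            for y in YEARS:
                if annual[cat][y] > 0:
                    items.append(
                        CostItem(
                            amount=annual[cat][y],
                            category=cat,
                            year=y,
                            traceability=Traceability.direct,
                            target="administration",
                        )
                    )
    else:
        supports, finals = _centre_plan(level, has_inpatient)
        for sid in supports:
            centres.append(CostCentre(id=sid, name=sid, kind=CentreKind.support))
        for fin in finals:
            if fin == "opd":
                centres.append(
                    CostCentre(
                        id=fin,
                        name="outpatient department",
                        kind=CentreKind.final,
                        output_measure=OutputMeasure.outpatient_visits,
                        output_count=stats.outpatient_visits,
                    )
                )
            else:
                centres.append(
                    CostCentre(
                        id=fin,
                        name=fin,
                        kind=CentreKind.final,
                        output_measure=OutputMeasure.bed_days,
                        output_count=stats.bed_days / (len(finals) - 1),
                    )
                )
        cost_units = {"outpatient_visit": OutputMeasure.outpatient_visits}
        if has_inpatient:
            cost_units["admission"] = OutputMeasure.admissions

        for cat in (CostCategory.drugs_supplies, CostCategory.staffing, CostCategory.other_recurrent):
            direct_frac = _DIRECT_FRACTION[cat] if not is_admin else 0.0
            shares = _centre_shares(cat, supports, finals)
            for y in YEARS:
                total = annual[cat][y]
                if total <= 0:
                    continue
                direct_total = total * direct_frac
                if direct_total > 0:
                    if has_inpatient:
                        items.append(
                            CostItem(
                                amount=direct_total / 2,
                                category=cat,
                                year=y,
                                traceability=Traceability.direct,
                                target="outpatient_visit",
                            )
                        )
                        items.append(
                            CostItem(
                                amount=direct_total / 2,
                                category=cat,
                                year=y,
                                traceability=Traceability.direct,
                                target="admission",
                            )
                        )
                    else:
                        items.append(
                            CostItem(
                                amount=direct_total,
                                category=cat,
                                year=y,
                                traceability=Traceability.direct,
                                target="outpatient_visit",
                            )
                        )
                indirect_total = total - direct_total
                for cid, frac in shares.items():
                    if frac > 0:
                        items.append(
                            CostItem(
                                amount=indirect_total * frac,
                                category=cat,
                                year=y,
                                traceability=Traceability.indirect,
                                target=cid,
                            )
                        )

        # capital: asset register whose straight-line charge equals the drawn
        # annual fixed cost (inflation-averaged across the two year draws)
        annual_fixed = (annual[CostCategory.fixed][YEARS[0]] * 1.05
                        + annual[CostCategory.fixed][YEARS[1]]) / 2.0
        if annual_fixed > 0:
            floor_area = max(50.0, beds * 25.0 + 120.0)
            for asset_class, frac, life in _ASSET_MIX:
                charge = annual_fixed * frac
                if asset_class == "building":
                    assets.append(
                        Asset(
                            asset_class="building",
                            floor_area=floor_area,
                            unit_build_cost=charge * life / floor_area,
                            centre_id="administration",
                        )
                    )
                else:
                    assets.append(
                        Asset(
                            asset_class=asset_class,
                            initial_value=charge * life,
                            centre_id="administration",
                        )
                    )

        # payroll consistent with the year-2 staffing ledger total
        staffing_total = annual[CostCategory.staffing][YEARS[1]]
        n_staff = max(2, int(beds / 4) + 2 + staff_jitter)
        if staffing_total > 0:
            weights = np.array([_CADRE_PAY_SHARE[k % 5] for k in range(n_staff)])
            weights /= weights.sum()
            for k in range(n_staff):
                pay = staffing_total * float(weights[k])
                payroll.append(
                    StaffPosition(
                        cadre=_CADRES[k % 5],
                        annual_base=pay * (2.0 / 3.0),
                        annual_allowances=pay / 3.0,
                    )
                )

    return FacilityRecord(
        id=fid,
        level=level,
        trustee=trustee,
        location=Location.urban if urban else Location.rural,
        beds=beds,
        centres=centres,
        items=items,
        assets=assets,
        payroll=payroll,
        statistics=stats,
        cost_units=cost_units,
        year_order=list(YEARS),
    )


def _make_schemes(rng: np.random.Generator, prices: PriceList) -> list[KephScheme]:
    """Actual and normative treatment recipes for all conditions.

    Every third condition is an inpatient scheme.  Actual drug quantities are
    the normative ones times a drawn availability factor (stock-outs), so
    normative direct cost >= actual direct cost condition by condition.
    """
    drug_codes = sorted(c for c in prices.prices if c.startswith("drug_"))
    lab_codes = sorted(c for c in prices.prices if c.startswith("lab_"))
    schemes: list[KephScheme] = []
    for cid in range(1, N_KEPH_CONDITIONS + 1):
        setting = Setting.inpatient if cid % 3 == 0 else Setting.outpatient
        codes = [drug_codes[(cid + k) % len(drug_codes)] for k in range(2)]
        base_qty = {codes[0]: float(1 + cid % 3), codes[1]: float(2)}
        normative_drugs = {
            "under5": {c: q * 0.6 for c, q in base_qty.items()},
            "over5": dict(base_qty),
        }
        availability = float(rng.uniform(0.6, 1.0))
        actual_drugs = {
            g: {c: q * availability for c, q in qs.items()}
            for g, qs in normative_drugs.items()
        }
        staff = {"nurse": 15.0 + (cid % 4) * 5.0, "clinical_officer": 10.0}
        labs = {lab_codes[cid % len(lab_codes)]: 1.0} if cid % 2 == 0 else {}
        los = float(3 + cid % 8) if setting is Setting.inpatient else None
        common = dict(
            condition_id=cid,
            name=f"condition_{cid:02d}",
            setting=setting,
            staff_minutes=staff,
            lab_tests=labs,
            length_of_stay=los,
        )
        schemes.append(
            KephScheme(variant=Variant.normative, drug_quantities=normative_drugs, **common)
        )
        schemes.append(
            KephScheme(variant=Variant.actual, drug_quantities=actual_drugs, **common)
        )
    return schemes


def generate_exit_interviews(
    n: int,
    params: InterviewParams | None = None,
    seed: int = 0,
    strata: Sequence[tuple[Level, Trustee]] = (
        (Level.district_hospital, Trustee.public),
        (Level.health_centre, Trustee.public),
        (Level.district_hospital, Trustee.fbo_ngo),
        (Level.district_hospital, Trustee.private),
    ),
) -> list[ExitInterview]:
    """Draw n exit-interview records cycling over the given strata."""
    params = params or InterviewParams()
    rng = np.random.default_rng(seed)
    out: list[ExitInterview] = []
    for k in range(n):
        level, trustee = strata[k % len(strata)]
        inpatient = rng.random() < params.inpatient_fraction
        mean = params.outside_drug_mean[trustee]
        out.append(
            ExitInterview(
                patient_type=PatientType.inpatient if inpatient else PatientType.outpatient,
                outside_drug_cost=mean * _lognormal_multiplier(rng, params.sigma),
                user_fees=params.user_fee_mean * _lognormal_multiplier(rng, params.sigma),
                transport_cost=params.transport_mean * _lognormal_multiplier(rng, params.sigma),
                level=level,
                trustee=trustee,
            )
        )
    return out


def generate_sample(config: GeneratorConfig | None = None) -> Sample:
    """Generate a full study sample from a seeded configuration."""
    config = config or default_config()
    rng = np.random.default_rng(config.seed)

    facilities: list[FacilityRecord] = []
    for stratum in config.strata:
        for i in range(stratum.count):
            facilities.append(_make_facility(rng, stratum, i))

    ministry = None
    if config.ministry is not None and config.ministry.count > 0:
        ministry = _make_facility(rng, config.ministry, 0)
        ministry = ministry.model_copy(update={"id": "ministry"})

    prices = default_price_list()
    schemes = _make_schemes(rng, prices)
    interview_strata = sorted(
        {(s.level, s.trustee) for s in config.strata if not s.level.value.startswith("admin")},
        key=lambda lt: (lt[0].value, lt[1].value),
    )
    interviews = generate_exit_interviews(
        config.interviews.n,
        config.interviews,
        seed=int(rng.integers(0, 2**31 - 1)),
        strata=interview_strata,
    )
    return Sample(
        facilities=facilities,
        ministry=ministry,
        interviews=interviews,
        schemes=schemes,
        price_list=prices,
        public_salary_scale=dict(PUBLIC_SALARY_SCALE),
    )


# --------------------------------------------------------------------- aggregation


def facility_category_costs(
    record: FacilityRecord, inflation: float = 0.05
) -> dict[CostCategory, float]:
    """Annualized per-category cost of one record [Ksh/year]."""
    ann = annualize_record(record, inflation)
    out = {c: 0.0 for c in CATEGORIES}
    for item in ann.items:
        out[item.category] += item.amount
    return out


def aggregate_sample(
    sample: Sample,
    weights: SamplingWeights | None = None,
    inflation: float = 0.05,
    rate: float = KSH_PER_EUR,
) -> CostMatrix:
    """National stratum x category matrix [EUR] of a generated sample."""
    results = []
    for rec in sample.all_records:
        cats = facility_category_costs(rec, inflation)
        results.append(
            (stratum_label(rec.level, rec.trustee), {c: v / rate for c, v in cats.items()})
        )
    return national_totals(results, weights, currency="EUR")


def fixed_share_by_stratum(matrix: CostMatrix) -> dict[str, float]:
    """Fixed-cost share of each row's total (rows with positive totals)."""
    out = {}
    for s in matrix.strata:
        row = matrix.frame.loc[s]
        total = float(row.sum())
        if total > 0:
            out[s] = float(row[CostCategory.fixed.value]) / total
    return out


# --------------------------------------------------------------------- calibration


def calibrate_to_matrix(
    config: GeneratorConfig,
    target: CostMatrix,
    tolerance: float = 0.01,
    ignore_rows: Sequence[str] = (),
) -> GeneratorConfig:
    """Rescale per-stratum category scales so the generated aggregate hits the target.

    Because draws are scale-independent, multiplying each stratum's scales by
    target/actual and regenerating with the same seed reproduces the target
    cells deterministically.  Rows in ``target`` that no configured stratum
    maps to must be listed in ``ignore_rows``.  Raises
    :class:`~khscm.errors.CalibrationError` with the achieved residuals when
    any covered row or column margin misses the tolerance (a tolerance of 0 is
    unattainable for stochastic draws at floating-point precision).
    """
    actual = aggregate_sample(generate_sample(config), inflation=config.inflation)
    strata_all = list(config.strata) + ([config.ministry] if config.ministry else [])
    covered = {s.label for s in strata_all if s.count > 0}

    uncovered = [
        r for r in target.strata if r not in covered and r not in set(ignore_rows)
    ]
    if uncovered:
        raise CalibrationError(
            f"no configured stratum generates target rows {uncovered}; "
            "extend the plan or pass ignore_rows"
        )

    ratios: dict[str, dict[CostCategory, float]] = {}
    for row in target.strata:
        if row in set(ignore_rows) or row not in covered:
            continue
        r: dict[CostCategory, float] = {}
        for cat in CATEGORIES:
            t = float(target.frame.loc[row, cat.value])
            a = float(actual.frame.loc[row, cat.value]) if row in actual.frame.index else 0.0
            if t > 0 and a <= 0:
                raise CalibrationError(
                    f"target row {row!r} needs {cat.value} cost but the generated "
                    "sample produces none; adjust the stratum scales"
                )
            r[cat] = (t / a) if a > 0 else 0.0
        ratios[row] = r

    def rescaled(s: StratumConfig) -> StratumConfig:
        if s.label not in ratios:
            return s
        new_scale = {
            cat: s.category_scale.get(cat, 0.0) * ratios[s.label][cat] for cat in CATEGORIES
        }
        return s.model_copy(update={"category_scale": new_scale})

    new_config = config.model_copy(
        update={
            "strata": [rescaled(s) for s in config.strata],
            "ministry": rescaled(config.ministry) if config.ministry else None,
        }
    )

    achieved = aggregate_sample(generate_sample(new_config), inflation=config.inflation)
    residuals = calibration_residuals(achieved, target, ignore_rows=ignore_rows)
    worst = max(residuals.values()) if residuals else 0.0
    if worst > tolerance:
        raise CalibrationError(
            f"calibration residuals exceed tolerance {tolerance}: "
            + ", ".join(f"{k}={v:.3%}" for k, v in sorted(residuals.items()) if v > tolerance)
        )
    return new_config


def calibration_residuals(
    achieved: CostMatrix, target: CostMatrix, ignore_rows: Sequence[str] = ()
) -> dict[str, float]:
    """Relative margin residuals |achieved-target|/target over covered rows and columns."""
    rows = [r for r in target.strata if r not in set(ignore_rows)]
    sub_t = target.frame.loc[rows]
    sub_a = achieved.frame.reindex(rows).fillna(0.0)
    out: dict[str, float] = {}
    for r in rows:
        t = float(sub_t.loc[r].sum())
        if t > 0:
            out[f"row:{r}"] = abs(float(sub_a.loc[r].sum()) - t) / t
    for c in sub_t.columns:
        t = float(sub_t[c].sum())
        if t > 0:
            out[f"col:{c}"] = abs(float(sub_a[c].sum()) - t) / t
    t = float(sub_t.to_numpy().sum())
    out["grand_total"] = abs(float(sub_a.to_numpy().sum()) - t) / t
    return out


# --------------------------------------------------------------------- serialization


def write_sample(sample: Sample, out_dir: str | Path) -> Path:
    """Write a sample to the fixture-directory layout the other stages consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fac_dir = out / "facilities"
    for rec in sample.all_records:
        write_facility(rec, fac_dir / rec.id)

    pd.DataFrame(
        [
            {
                "patient_type": i.patient_type.value,
                "outside_drug_cost": i.outside_drug_cost,
                "user_fees": i.user_fees,
                "transport_cost": i.transport_cost,
                "level": i.level.value,
                "trustee": i.trustee.value,
            }
            for i in sample.interviews
        ],
        columns=["patient_type", "outside_drug_cost", "user_fees", "transport_cost", "level", "trustee"],
    ).to_csv(out / "exit_interviews.csv", index=False)

    import json

    (out / "keph_schemes.json").write_text(
        json.dumps([s.model_dump(mode="json") for s in sample.schemes], indent=1, sort_keys=True)
    )
    (out / "price_list.json").write_text(
        json.dumps(sample.price_list.model_dump(mode="json"), indent=1, sort_keys=True)
    )
    (out / "public_salary_scale.json").write_text(
        json.dumps(sample.public_salary_scale, indent=1, sort_keys=True)
    )
    return out


def load_sample(in_dir: str | Path) -> Sample:
    """Load a sample previously written by :func:`write_sample`."""
    import json

    from .facility import load_facility_ledger

    base = Path(in_dir)
    fac_dir = base / "facilities"
    if not fac_dir.is_dir():
        raise ConfigError(f"{fac_dir} is not a sample directory")
    facilities: list[FacilityRecord] = []
    ministry = None
    for sub in sorted(fac_dir.iterdir()):
        if not sub.is_dir():
            continue
        rec = load_facility_ledger(sub)
        if rec.level is Level.ministry:
            ministry = rec
        else:
            facilities.append(rec)

    interviews: list[ExitInterview] = []
    ipath = base / "exit_interviews.csv"
    if ipath.exists():
        for r in pd.read_csv(ipath).itertuples():
            interviews.append(
                ExitInterview(
                    patient_type=PatientType(r.patient_type),
                    outside_drug_cost=float(r.outside_drug_cost),
                    user_fees=float(r.user_fees),
                    transport_cost=float(r.transport_cost),
                    level=Level(str(r.level)),
                    trustee=Trustee(r.trustee),
                )
            )

    schemes = []
    spath = base / "keph_schemes.json"
    if spath.exists():
        schemes = [KephScheme(**d) for d in json.loads(spath.read_text())]
    ppath = base / "price_list.json"
    prices = (
        PriceList(**json.loads(ppath.read_text())) if ppath.exists() else default_price_list()
    )
    scale_path = base / "public_salary_scale.json"
    scale = (
        json.loads(scale_path.read_text()) if scale_path.exists() else dict(PUBLIC_SALARY_SCALE)
    )
    return Sample(
        facilities=facilities,
        ministry=ministry,
        interviews=interviews,
        schemes=schemes,
        price_list=prices,
        public_salary_scale=scale,
    )
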