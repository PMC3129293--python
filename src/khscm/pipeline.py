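"""End-to-end pipeline: ingest -> annualize -> step-down -> episode costing ->
demand-side adjustment -> national aggregation -> scenarios -> report.

Every stage exchanges plain CSV/JSON so analysts can inspect each
intermediate; a run writes a manifest (input hashes, seed, version) for
auditability.  A stage failure aborts with the stage name and leaves earlier
outputs in place next to a ``FAILED`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from statistics import fmean
from typing import Optional

import pandas as pd

from . import __version__
from .annualize import annualize_record, fallback_salary, staff_minute_cost
from .errors import KhscmError, UnitCostError
from .facility import FacilityRecord, validate_facility
from .keph import (
    Setting,
    demand_side_adjust,
    episode_direct_cost,
    episode_total_cost,
)
from .reporting import CostMatrix, render_tables
from .scenarios import ScenarioSpec, coverage_response
from .stepdown import (
    AllocationConfig,
    UnitCost,
    UnitCosts,
    stepdown_allocate,
    unit_costs,
)
from .synthetic import Sample, aggregate_sample, load_sample, stratum_label

logger = logging.getLogger(__name__)

STAGES = ("ingest", "annualize", "stepdown", "keph", "report", "scenario", "render")


class StageError(KhscmError):
    """A pipeline stage failed; ``stage`` names it for the exit code."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    out_dir: Path
    matrix: CostMatrix
    unit_costs_by_stratum: dict[str, UnitCosts]
    excluded_facilities: list[str] = field(default_factory=list)
    paths: dict[str, Path] = field(default_factory=dict)


def _mean_unit(units: list[Optional[UnitCost]]) -> Optional[UnitCost]:
    present = [u for u in units if u is not None]
    if not present:
        return None
    return UnitCost(
        total=fmean(u.total for u in present),
        fixed=fmean(u.fixed for u in present),
        variable=fmean(u.variable for u in present),
        direct=fmean(u.direct for u in present),
        indirect=fmean(u.indirect for u in present),
    )


def stratum_unit_costs(
    per_facility: dict[str, tuple[str, UnitCosts]]
) -> dict[str, UnitCosts]:
    """Unweighted stratum means of per-facility unit costs."""
    by_stratum: dict[str, list[UnitCosts]] = {}
    for _, (stratum, u) in per_facility.items():
        by_stratum.setdefault(stratum, []).append(u)
    return {
        s: UnitCosts(
            per_visit=_mean_unit([u.per_visit for u in us]),
            per_admission=_mean_unit([u.per_admission for u in us]),
            per_bed_day=_mean_unit([u.per_bed_day for u in us]),
        )
        for s, us in sorted(by_stratum.items())
    }


def stratum_staff_rates(sample: Sample) -> dict[str, dict[str, float]]:
    """Per-stratum mean staff minute cost by cadre, with public-scale fallback."""
    rates: dict[str, dict[str, list[float]]] = {}
    for rec in sample.facilities:
        stratum = stratum_label(rec.level, rec.trustee)
        cell = rates.setdefault(stratum, {})
        for pos in rec.payroll:
            if pos.annual_base is None:
                pos = fallback_salary(pos, sample.public_salary_scale)
            cell.setdefault(pos.cadre, []).append(staff_minute_cost(pos))
    return {
        s: {cadre: fmean(v) for cadre, v in cadres.items()}
        for s, cadres in rates.items()
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    sample_dir: str | Path,
    allocation_config: AllocationConfig | None = None,
    scenario_spec: ScenarioSpec | None = None,
    out_dir: str | Path = "out",
    seed: int | None = None,
    schemes_path: str | Path | None = None,
) -> PipelineResult:
    """Run the full costing pipeline on a sample fixture directory.

    Writes ``matrix.csv``, ``unit_costs.csv``, ``episodes.csv``, ``curve.csv``
    and ``manifest.json`` under ``out_dir``.  Facilities whose unit costs are
    undefined (nonzero cost over zero output) are excluded and counted,
    mirroring the survey's handling of unusable facilities.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    allocation_config = allocation_config or AllocationConfig()
    scenario_spec = scenario_spec or ScenarioSpec()

    stage = "ingest"
    try:
        sample = load_sample(sample_dir)
        for rec in sample.all_records:
            errors = [v for v in validate_facility(rec) if v.severity == "error"]
            if errors:
                raise KhscmError(
                    f"facility {rec.id} fails validation: {[v.message for v in errors]}"
                )

        stage = "annualize"
        annualized: dict[str, FacilityRecord] = {
            rec.id: annualize_record(rec) for rec in sample.facilities
        }

        stage = "stepdown"
        per_facility: dict[str, tuple[str, UnitCosts]] = {}
        excluded: list[str] = []
        for rec in sample.facilities:
            if rec.is_administrative:
                continue
            ann = annualized[rec.id]
            result = stepdown_allocate(ann, allocation_config)
            try:
                u = unit_costs(result, ann.statistics, record=ann)
            except UnitCostError as exc:
                logger.warning("excluding facility %s: %s", rec.id, exc)
                excluded.append(rec.id)
                continue
            per_facility[rec.id] = (stratum_label(rec.level, rec.trustee), u)
        by_stratum = stratum_unit_costs(per_facility)

        stage = "keph"
        episode_rows = []
        if schemes_path is not None:
            schemes_file = Path(schemes_path)
            if not schemes_file.exists():
                raise KhscmError(f"schemes file not found: {schemes_file}")
            from .keph import KephScheme

            sample.schemes = [
                KephScheme(**d) for d in json.loads(schemes_file.read_text())
            ]
        if sample.schemes:
            staff_rates = stratum_staff_rates(sample)
            for stratum, u in by_stratum.items():
                rates = staff_rates.get(stratum, {})
                if not rates:
                    continue
                for scheme in sample.schemes:
                    if scheme.setting is Setting.inpatient and u.per_bed_day is None:
                        continue
                    if scheme.setting is Setting.outpatient and u.per_visit is None:
                        continue
                    direct = episode_direct_cost(
                        scheme, sample.price_list, rates, age_group="under5"
                    )
                    ep = episode_total_cost(direct, u, scheme, stratum=stratum)
                    episode_rows.append(
                        {
                            "stratum": stratum,
                            "condition_id": ep.condition_id,
                            "setting": ep.setting.value,
                            "variant": ep.variant.value,
                            "direct": round(ep.direct, 2),
                            "indirect": round(ep.indirect, 2),
                            "total": round(ep.total, 2),
                        }
                    )

        # demand-side adjustment of stratum unit costs
        adjusted = {}
        strata_keys = {
            stratum_label(r.level, r.trustee): (r.level, r.trustee)
            for r in sample.facilities
        }
        for stratum, u in by_stratum.items():
            level, trustee = strata_keys[stratum]
            adjusted[stratum] = demand_side_adjust(u, sample.interviews, level, trustee)

        stage = "report"
        matrix = aggregate_sample(sample)
        unit_rows = pd.DataFrame(
            {
                "cost_per_visit": {
                    s: u.per_visit.total if u.per_visit else float("nan")
                    for s, u in adjusted.items()
                },
                "cost_per_admission": {
                    s: u.per_admission.total if u.per_admission else float("nan")
                    for s, u in adjusted.items()
                },
                "cost_per_bed_day": {
                    s: u.per_bed_day.total if u.per_bed_day else float("nan")
                    for s, u in adjusted.items()
                },
            }
        ).sort_index()

        stage = "scenario"
        curve = coverage_response(matrix, scenario_spec)

        stage = "render"
        paths = render_tables(
            matrix, unit_rows, pd.DataFrame(episode_rows), out
        )
        curve_path = out / "curve.csv"
        curve.to_frame().to_csv(curve_path, index=False)
        paths["curve"] = curve_path

        manifest = {
            "tool_version": __version__,
            "seed": seed,
            "sample_dir": str(sample_dir),
            "allocation_config": allocation_config.model_dump(mode="json"),
            "scenario_spec": scenario_spec.model_dump(mode="json"),
            "excluded_facilities": excluded,
            "n_facilities": len(sample.facilities),
            "input_hashes": {
                p.name: _sha256(p)
                for p in sorted(Path(sample_dir).glob("*.json"))
            },
            "outputs": {k: str(v) for k, v in sorted(paths.items())},
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        paths["manifest"] = manifest_path
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc

    return PipelineResult(
        out_dir=out,
        matrix=matrix,
        unit_costs_by_stratum=adjusted,
        excluded_facilities=excluded,
        paths=paths,
    )
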