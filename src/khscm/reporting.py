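"""National aggregation and report surfaces.

The central container is the :class:`CostMatrix`: facility strata (level x
trustee, plus district/provincial administration and ministry rows) by the
four input categories (drugs and other supplies, staffing, other recurrent
cost, fixed cost), in one currency.  From it the module derives trustee and
category shares, per-capita figures and the rendered report tables.

A published national summary matrix for Kenya FY2006/07 ships with the
package (``khscm.reporting.load_published_matrix``) and is the fixture behind
the worked examples: grand total 694,947,102 EUR, staffing 37% of total and
52% of recurrent spending, drugs 22%, and trustee shares of 17% (FBO/NGO)
and 23% (private).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import AggregationError, DataError
from .facility import CostCategory
from .util import round_half_away

CATEGORY_ORDER = [c.value for c in CostCategory]

#: Row-grouping label for administration rows in the published matrix.
ADMIN_GROUP = "administration"


@dataclass
class CostMatrix:
    """Stratum x input-category cost table with exact margins."""

    frame: pd.DataFrame  # index: stratum label; columns: CATEGORY_ORDER
    currency: str = "EUR"

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORY_ORDER if c not in self.frame.columns]
        if missing:
            raise AggregationError(f"cost matrix missing category columns {missing}")
        self.frame = self.frame[CATEGORY_ORDER].astype(float)

    @property
    def strata(self) -> list[str]:
        return list(self.frame.index)

    @property
    def row_totals(self) -> pd.Series:
        return self.frame.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.frame.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.frame.to_numpy().sum())

    @property
    def recurrent_total(self) -> float:
        """Recurrent base: everything except annualized fixed (capital) cost."""
        ct = self.column_totals
        return float(ct.sum() - ct[CostCategory.fixed.value])

    def with_margins(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["total"] = self.row_totals
        out.loc["Total"] = out.sum(axis=0)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.with_margins().to_csv(path, index_label="stratum")

    @classmethod
    def from_csv(cls, path: str | Path, currency: str = "EUR") -> "CostMatrix":
        df = pd.read_csv(path, index_col="stratum")
        df = df.drop(index=[i for i in ("Total",) if i in df.index])
        df = df.drop(columns=[c for c in ("total", "group") if c in df.columns])
        return cls(frame=df, currency=currency)


@dataclass
class SamplingWeights:
    """Stratum expansion factors (national count / sampled count); default 1."""

    factors: dict[str, float] = field(default_factory=dict)
    default: Optional[float] = 1.0

    def factor(self, stratum: str) -> float:
        if stratum in self.factors:
            f = self.factors[stratum]
        elif self.default is not None:
            f = self.default
        else:
            raise AggregationError(f"no sampling weight for stratum {stratum!r}")
        if f < 1:
            raise AggregationError(f"expansion factor {f} for {stratum!r} is below 1")
        return f


def national_totals(
    facility_results: Iterable[tuple[str, Mapping[CostCategory, float]]],
    weights: SamplingWeights | None = None,
    currency: str = "EUR",
) -> CostMatrix:
    """Weight per-facility category costs up to a stratum x category matrix.

    ``facility_results`` yields (stratum label, category -> cost) pairs.
    """
    weights = weights or SamplingWeights()
    cells: dict[str, dict[str, float]] = {}
    for stratum, cats in facility_results:
        w = weights.factor(stratum)
        row = cells.setdefault(stratum, {c: 0.0 for c in CATEGORY_ORDER})
        for cat, v in cats.items():
            key = cat.value if isinstance(cat, CostCategory) else str(cat)
            row[key] += float(v) * w
    frame = pd.DataFrame.from_dict(cells, orient="index").fillna(0.0)
    for c in CATEGORY_ORDER:
        if c not in frame.columns:
            frame[c] = 0.0
    return CostMatrix(frame=frame.sort_index(), currency=currency)


def share_by_trustee(
    matrix: CostMatrix, grouping: Mapping[str, Optional[str]]
) -> dict[str, int]:
    """Row-group shares of the grand total, in integer percent.

    ``grouping`` maps every stratum to a group label, or to ``None`` to keep
    the row in the denominator but out of every group (used for the
    nursing-home row whose trustee the source table leaves unlabelled).
    """
    missing = [s for s in matrix.strata if s not in grouping]
    if missing:
        raise AggregationError(f"grouping does not cover rows {missing}")
    total = matrix.grand_total
    row_totals = matrix.row_totals
    sums: dict[str, float] = {}
    for stratum, group in grouping.items():
        if group is None or stratum not in row_totals.index:
            continue
        sums[group] = sums.get(group, 0.0) + float(row_totals[stratum])
    return {g: int(round_half_away(v / total * 100.0)) for g, v in sums.items()}


def share_by_category(matrix: CostMatrix) -> dict[str, int]:
    """Category shares of total spending, plus recurrent-base shares, integer percent.

    Keys: each category name (share of grand total) and
    ``<category>_of_recurrent`` for the three recurrent categories.
    """
    total = matrix.grand_total
    recurrent = matrix.recurrent_total
    ct = matrix.column_totals
    out: dict[str, int] = {}
    for c in CATEGORY_ORDER:
        out[c] = int(round_half_away(float(ct[c]) / total * 100.0))
    for c in CATEGORY_ORDER:
        if c != CostCategory.fixed.value:
            out[f"{c}_of_recurrent"] = int(
                round_half_away(float(ct[c]) / recurrent * 100.0)
            )
    return out


def per_capita(total: float, population: float) -> float:
    """Cost per person, reported at 2 dp."""
    if population <= 0:
        raise DataError(f"population must be positive, got {population}")
    return round_half_away(total / population, 2)


def analysed_facility_count(sampled: int, excluded: int) -> int:
    """Facilities remaining in the analysis after exclusions."""
    if excluded > sampled:
        raise DataError(f"excluded ({excluded}) exceeds sampled ({sampled})")
    return sampled - excluded


# ----------------------------------------------------------------- bundled fixture


def _data_path(name: str):
    return resources.files("khscm.data").joinpath(name)


def load_published_matrix() -> tuple[CostMatrix, dict[str, Optional[str]]]:
    """The bundled Kenya FY2006/07 national summary matrix and its row grouping.

    Returns the matrix (EUR) and a stratum -> group mapping with groups
    ``public``, ``fbo_ngo``, ``private`` and ``administration``; the
    nursing-home row printed without a trustee label maps to ``None`` (in the
    denominator, outside every group — the convention under which the
    published 17%/23% trustee shares reproduce).

    One cell differs by 1 EUR from the source print to reconcile its internal
    rounding (the printed cells, column margin and grand total disagree at the
    1-EUR level); see the methods note.
    """
    with resources.as_file(_data_path("national_cost_matrix.csv")) as p:
        df = pd.read_csv(p, index_col="stratum")
    grouping = {
        s: (None if pd.isna(g) or g == "" else str(g)) for s, g in df["group"].items()
    }
    matrix = CostMatrix(frame=df.drop(columns=["group"]), currency="EUR")
    return matrix, grouping


def load_published_unit_costs() -> pd.DataFrame:
    """Bundled published average unit costs [Ksh] by stratum.

    Columns: ``cost_per_visit``, ``cost_per_admission``, ``cost_per_bed_day``
    (missing where a stratum has no inpatient care).
    """
    with resources.as_file(_data_path("published_unit_costs.csv")) as p:
        return pd.read_csv(p, index_col="stratum")


# ----------------------------------------------------------------- rendering


def render_tables(
    matrix: CostMatrix,
    unit_cost_rows: pd.DataFrame | None,
    episode_rows: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the report tables: national matrix, unit costs with ratio
    columns, and episode costs, plus a plain-text summary.

    Output is deterministic byte-for-byte for fixed input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["matrix"] = out / "matrix.csv"
    matrix.to_csv(paths["matrix"])

    paths["unit_costs"] = out / "unit_costs.csv"
    if unit_cost_rows is None or unit_cost_rows.empty:
        cols = [
            "stratum",
            "cost_per_visit",
            "cost_per_admission",
            "cost_per_bed_day",
            "admission_per_bed_day",
            "bed_day_per_visit",
        ]
        pd.DataFrame(columns=cols).to_csv(paths["unit_costs"], index=False)
    else:
        df = unit_cost_rows.copy()
        with pd.option_context("mode.chained_assignment", None):
            df["admission_per_bed_day"] = [
                round_half_away(a / b, 1) if b and a == a and b == b else None
                for a, b in zip(df["cost_per_admission"], df["cost_per_bed_day"])
            ]
            df["bed_day_per_visit"] = [
                round_half_away(b / v, 1) if v and b == b and v == v else None
                for b, v in zip(df["cost_per_bed_day"], df["cost_per_visit"])
            ]
        df.to_csv(paths["unit_costs"], index_label="stratum")

    paths["episodes"] = out / "episodes.csv"
    ep_cols = ["stratum", "condition_id", "setting", "variant", "direct", "indirect", "total"]
    if episode_rows is None or episode_rows.empty:
        pd.DataFrame(columns=ep_cols).to_csv(paths["episodes"], index=False)
    else:
        episode_rows.to_csv(paths["episodes"], index=False)

    summary = out / "summary.txt"
    cat = share_by_category(matrix)
    lines = [
        f"Grand total: {matrix.grand_total:,.0f} {matrix.currency}",
        f"Recurrent total: {matrix.recurrent_total:,.0f} {matrix.currency}",
        "Category shares of total (%): "
        + ", ".join(f"{c}={cat[c]}" for c in CATEGORY_ORDER),
        "Staffing share of recurrent (%): "
        + str(cat[f"{CostCategory.staffing.value}_of_recurrent"]),
    ]
    summary.write_text("\n".join(lines) + "\n")
    paths["summary"] = summary
    return paths
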