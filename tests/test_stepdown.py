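"""Step-down engine: classification, ordering, allocation, unit costs.

The allocation is checked against an independent brute-force oracle that
walks the closure order distributing scalar pools — no shared code with the
engine beyond the weight definition.
"""

import numpy as np
import pytest

from khscm.errors import AllocationError, ConfigError, UnitCostError
from khscm.facility import (
    CentreKind,
    CostCategory,
    CostCentre,
    CostItem,
    FacilityRecord,
    Level,
    OutputMeasure,
    ServiceStatistics,
    Traceability,
    Trustee,
)
from khscm.stepdown import (
    AllocationBasis,
    AllocationConfig,
    BasisKind,
    OrderingPolicy,
    UnitCost,
    UnitCosts,
    classify_costs,
    order_support_centres,
    stepdown_allocate,
    unit_cost_ratios,
    unit_costs,
)

# ---------------------------------------------------------------- helpers


def build_record(support_costs, final_costs, direct=None, stats=None):
    """Facility with given own indirect costs (all drugs category for simplicity)."""
    centres, items = [], []
    for cid, cost in support_costs.items():
        centres.append(CostCentre(id=cid, kind=CentreKind.support))
        if cost:
            items.append(
                CostItem(
                    amount=cost,
                    category=CostCategory.drugs_supplies,
                    year="y",
                    traceability=Traceability.indirect,
                    target=cid,
                )
            )
    for cid, cost in final_costs.items():
        centres.append(
            CostCentre(
                id=cid,
                kind=CentreKind.final,
                output_measure=OutputMeasure.outpatient_visits,
                output_count=100,
            )
        )
        if cost:
            items.append(
                CostItem(
                    amount=cost,
                    category=CostCategory.drugs_supplies,
                    year="y",
                    traceability=Traceability.indirect,
                    target=cid,
                )
            )
    for unit, cost in (direct or {}).items():
        items.append(
            CostItem(
                amount=cost,
                category=CostCategory.drugs_supplies,
                year="y",
                traceability=Traceability.direct,
                target=unit,
            )
        )
    return FacilityRecord(
        id="t",
        level=Level.health_centre,
        trustee=Trustee.public,
        beds=10,
        centres=centres,
        items=items,
        statistics=stats or ServiceStatistics(outpatient_visits=100),
        year_order=["y"],
    )


def oracle_stepdown(order, own, finals, weight_fn):
    """Independent sequential-distribution oracle on scalar pools.

    ``own`` maps every centre id to its own indirect cost; ``weight_fn``
    returns the basis weight of a receiver.  Returns final-centre totals.
    """
    pool = dict(own)
    open_ids = list(order) + list(finals)
    for sid in order:
        open_ids.remove(sid)
        weights = {r: weight_fn(r) for r in open_ids}
        total_w = sum(weights.values())
        for r in open_ids:
            pool[r] += pool[sid] * weights[r] / total_w
        pool[sid] = 0.0
    return {f: pool[f] for f in finals}


# ---------------------------------------------------------------- classification


class TestClassify:
    def test_buckets_conserve_total(self, toy_record):
        direct, indirect = classify_costs(toy_record)
        total = sum(direct.values()) + sum(
            v for cats in indirect.values() for v in cats.values()
        )
        assert total == pytest.approx(toy_record.total_cost())
        assert set(direct) == {"outpatient_visit"}
        assert set(indirect) == {"admin", "opd", "ward"}

    def test_all_direct_ledger_has_empty_indirect(self):
        rec = build_record({}, {"opd": 0}, direct={"outpatient_visit": 500})
        direct, indirect = classify_costs(rec)
        assert indirect == {} and direct == {"outpatient_visit": 500}


class TestOrdering:
    def test_descending_cost(self):
        rec = build_record({"A": 500, "B": 700}, {"F": 1})
        order = order_support_centres(rec.centres, AllocationConfig(), {"A": 500, "B": 700})
        assert order == ["B", "A"]

    def test_tie_broken_by_id(self):
        rec = build_record({"B": 500, "A": 500}, {"F": 1})
        order = order_support_centres(rec.centres, AllocationConfig(), {"A": 500, "B": 500})
        assert order == ["A", "B"]

    def test_explicit_list_wins(self):
        rec = build_record({"A": 500, "B": 700}, {"F": 1})
        cfg = AllocationConfig(
            ordering=OrderingPolicy.explicit_list, explicit_order=["A", "B"]
        )
        assert order_support_centres(rec.centres, cfg, {"A": 500, "B": 700}) == ["A", "B"]

    def test_explicit_list_must_cover_all_supports(self):
        rec = build_record({"A": 1, "B": 1}, {"F": 1})
        cfg = AllocationConfig(ordering=OrderingPolicy.explicit_list, explicit_order=["A"])
        with pytest.raises(ConfigError):
            order_support_centres(rec.centres, cfg, {})


# ---------------------------------------------------------------- allocation


class TestAllocate:
    def test_single_support_two_to_one_split(self):
        rec = build_record({"S": 600}, {"F1": 0, "F2": 0})
        cfg = AllocationConfig(
            basis_map={
                "S": AllocationBasis(
                    kind=BasisKind.explicit_weights, weights={"F1": 2, "F2": 1}
                )
            }
        )
        res = stepdown_allocate(rec, cfg)
        assert res.final_total("F1") == pytest.approx(400)
        assert res.final_total("F2") == pytest.approx(200)

    def test_two_support_cascade_conserves_total(self):
        # S1 (300) closes first, half to S2 and half to the final centre;
        # S2 then passes its own 100 plus the received 150 on, so the single
        # final centre ends with its own 300 + 150 + 250 = 700 = ledger total
        rec = build_record({"S1": 300, "S2": 100}, {"F": 300})
        cfg = AllocationConfig(
            ordering=OrderingPolicy.explicit_list,
            explicit_order=["S1", "S2"],
            basis_map={
                "S1": AllocationBasis(
                    kind=BasisKind.explicit_weights, weights={"S2": 1, "F": 1}
                ),
                "S2": AllocationBasis(kind=BasisKind.explicit_weights, weights={"F": 1}),
            },
        )
        res = stepdown_allocate(rec, cfg)
        assert res.final_total("F") == pytest.approx(700)
        received = [amt for src, dst, amt in res.trace if dst == "F"]
        assert received == [pytest.approx(150), pytest.approx(250)]

    def test_no_support_centres_is_identity(self):
        rec = build_record({}, {"F1": 123, "F2": 77})
        res = stepdown_allocate(rec)
        assert res.final_total("F1") == 123 and res.final_total("F2") == 77

    def test_all_zero_basis_rejected(self):
        rec = build_record({"S": 100}, {"F1": 0, "F2": 0})  # default basis: own cost
        with pytest.raises(AllocationError, match="S"):
            stepdown_allocate(rec)

    def test_no_final_centre_rejected(self):
        rec = build_record({"S": 100}, {"F": 1})
        rec = rec.model_copy(update={"centres": rec.centres[:1]})
        with pytest.raises(AllocationError):
            stepdown_allocate(rec)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n_sup = int(rng.integers(1, 5))
            n_fin = int(rng.integers(1, 4))
            sup = {f"S{i}": float(rng.integers(1, 1000)) for i in range(n_sup)}
            fin = {f"F{i}": float(rng.integers(1, 1000)) for i in range(n_fin)}
            rec = build_record(sup, fin)
            res = stepdown_allocate(rec)
            order = sorted(sup, key=lambda c: (-sup[c], c))
            own = {**sup, **fin}
            expected = oracle_stepdown(order, own, list(fin), lambda r: own[r])
            for f in fin:
                assert res.final_total(f) == pytest.approx(expected[f], rel=1e-12)

    def test_order_changes_distribution_but_not_total(self):
        # with heterogeneous per-centre bases the closure order shifts cost
        # between final centres, but their sum is always the ledger total
        import itertools

        sup = {"S1": 300.0, "S2": 200.0}
        fin = {"F1": 50.0, "F2": 50.0}
        rec = build_record(sup, fin)
        basis_map = {
            "S1": AllocationBasis(
                kind=BasisKind.explicit_weights, weights={"S2": 1, "F1": 1, "F2": 0}
            ),
            "S2": AllocationBasis(
                kind=BasisKind.explicit_weights, weights={"S1": 1, "F1": 0, "F2": 1}
            ),
        }
        totals = set()
        per_final = []
        for perm in itertools.permutations(sup):
            cfg = AllocationConfig(
                ordering=OrderingPolicy.explicit_list,
                explicit_order=list(perm),
                basis_map=basis_map,
            )
            res = stepdown_allocate(rec, cfg)
            totals.add(round(res.total_final_cost, 6))
            per_final.append(tuple(round(res.final_total(f), 6) for f in fin))
        assert totals == {600.0}  # order-invariant sum
        assert len(set(per_final)) == 2  # but order-sensitive distribution

    def test_uniform_static_weights_make_order_irrelevant(self):
        # a telescoping identity of the static direct-cost-share basis: with
        # one shared weight vector, every closure order yields the same split
        import itertools

        rng = np.random.default_rng(7)
        sup = {f"S{i}": float(rng.integers(1, 500)) for i in range(3)}
        fin = {f"F{i}": float(rng.integers(1, 500)) for i in range(2)}
        rec = build_record(sup, fin)
        results = set()
        for perm in itertools.permutations(sup):
            cfg = AllocationConfig(
                ordering=OrderingPolicy.explicit_list, explicit_order=list(perm)
            )
            res = stepdown_allocate(rec, cfg)
            results.add(tuple(round(res.final_total(f), 6) for f in fin))
        assert len(results) == 1

    def test_category_conservation_on_generated_facilities(self, sample42):
        from khscm.annualize import annualize_record

        checked = 0
        for rec in sample42.facilities:
            if rec.is_administrative:
                continue
            ann = annualize_record(rec)
            res = stepdown_allocate(ann)
            ledger = {c: 0.0 for c in CostCategory}
            for item in ann.items:
                if item.traceability is Traceability.indirect:
                    ledger[item.category] += item.amount
            margins = res.category_margins()
            for cat in CostCategory:
                assert margins[cat] == pytest.approx(ledger[cat], rel=1e-9, abs=1e-6)
            assert res.total_final_cost + res.total_direct_cost == pytest.approx(
                ann.total_cost(), rel=1e-9
            )
            checked += 1
            if checked >= 30:
                break
        assert checked == 30


# ---------------------------------------------------------------- unit costs


class TestUnitCosts:
    def test_outpatient_division(self):
        rec = build_record(
            {}, {"F": 10_000}, stats=ServiceStatistics(outpatient_visits=50)
        )
        res = stepdown_allocate(rec)
        u = unit_costs(res, rec.statistics, record=rec)
        assert u.per_visit.total == pytest.approx(200)
        assert u.per_admission is None and u.per_bed_day is None

    def test_homogeneity_in_outputs(self, toy_record):
        res = stepdown_allocate(toy_record)
        u1 = unit_costs(res, toy_record.statistics, record=toy_record)
        doubled = toy_record.statistics.model_copy(
            update={
                "outpatient_visits": toy_record.statistics.outpatient_visits * 2,
                "admissions": toy_record.statistics.admissions * 2,
                "bed_days": toy_record.statistics.bed_days * 2,
            }
        )
        u2 = unit_costs(res, doubled, record=toy_record)
        assert u2.per_visit.total == pytest.approx(u1.per_visit.total / 2)
        assert u2.per_bed_day.total == pytest.approx(u1.per_bed_day.total / 2)

    def test_zero_output_with_cost_rejected(self):
        rec = build_record(
            {}, {"F": 10_000}, stats=ServiceStatistics(outpatient_visits=0)
        )
        res = stepdown_allocate(rec)
        with pytest.raises(UnitCostError):
            unit_costs(res, rec.statistics, record=rec)

    def test_fixed_variable_components_sum_to_total(self, toy_record):
        res = stepdown_allocate(toy_record)
        u = unit_costs(res, toy_record.statistics, record=toy_record)
        for unit in (u.per_visit, u.per_admission, u.per_bed_day):
            assert unit.fixed + unit.variable == pytest.approx(unit.total)
            assert unit.direct + unit.indirect == pytest.approx(unit.total)


class TestRatios:
    @pytest.mark.parametrize(
        "admission, bed_day, expected",
        [(48_474, 4_921, 9.9), (12_970, 2_186, 5.9), (12_953, 1_885, 6.9), (100, 100, 1.0)],
    )
    def test_admission_per_bed_day(self, admission, bed_day, expected):
        u = UnitCosts(
            per_admission=UnitCost(total=admission), per_bed_day=UnitCost(total=bed_day)
        )
        assert unit_cost_ratios(u)[0] == expected

    def test_bed_day_per_visit(self):
        u = UnitCosts(per_visit=UnitCost(total=223), per_bed_day=UnitCost(total=3_500))
        assert unit_cost_ratios(u)[1] == 15.7

    def test_missing_inpatient_gives_none_not_zero(self):
        u = UnitCosts(per_visit=UnitCost(total=174))
        assert unit_cost_ratios(u) == (None, None)
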