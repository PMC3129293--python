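"""Annualization rules: depreciation, inflation averaging, currency, staff time."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from khscm.annualize import (
    DEFAULT_LIFETIMES,
    InKindSupply,
    PriceList,
    annualize_record,
    building_initial_cost,
    convert_currency,
    fallback_salary,
    impute_inkind,
    inflation_average,
    staff_minute_cost,
    straight_line_depreciation,
)
from khscm.errors import ImputationError, ParameterError
from khscm.facility import Asset, CostCategory, CostItem, StaffPosition, Traceability
from khscm.util import KSH_PER_EUR, round_to_nearest

money = st.floats(min_value=0.01, max_value=1e9, allow_nan=False)


class TestDepreciation:
    @pytest.mark.parametrize(
        "asset, expected",
        [
            (Asset(asset_class="medical_equipment", initial_value=80_000), 10_000.0),
            (Asset(asset_class="general_equipment", initial_value=100_000), 10_000.0),
            (Asset(asset_class="vehicle", initial_value=800_000), 100_000.0),
            (
                Asset(asset_class="building", floor_area=300, unit_build_cost=2_000),
                20_000.0,
            ),
            (
                Asset(asset_class="medical_equipment", initial_value=80_000, lifetime_years=4),
                20_000.0,
            ),
            (
                # condition adjustment halves the remaining life
                Asset(
                    asset_class="building",
                    initial_value=600_000,
                    condition_adjustment=0.5,
                ),
                40_000.0,
            ),
        ],
    )
    def test_straight_line(self, asset, expected):
        assert straight_line_depreciation(asset) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(value=money, cls=st.sampled_from(sorted(DEFAULT_LIFETIMES)))
    def test_telescoping_recovers_initial_value(self, value, cls):
        asset = Asset(asset_class=cls, initial_value=value)
        if cls == "building":
            asset = Asset(asset_class=cls, floor_area=10.0, unit_build_cost=value / 10.0)
        charge = straight_line_depreciation(asset)
        assert charge * DEFAULT_LIFETIMES[cls] == pytest.approx(value, rel=1e-6)

    def test_unknown_class_without_override_errors(self):
        with pytest.raises(ParameterError):
            straight_line_depreciation(Asset(asset_class="helipad", initial_value=1.0))


class TestBuildingCost:
    @pytest.mark.parametrize(
        "area, unit, expected", [(100, 1_500, 150_000), (1, 1, 1), (250.5, 2_000, 501_000)]
    )
    def test_product(self, area, unit, expected):
        assert building_initial_cost(area, unit) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            building_initial_cost(0, 100)


class TestInflationAverage:
    def test_stated_rule(self):
        assert inflation_average(100, 110) == pytest.approx(107.5)

    def test_zero_case(self):
        assert inflation_average(0, 0) == 0

    def test_identity_without_inflation(self):
        assert inflation_average(42.0, 42.0, inflation=0.0) == 42.0

    @settings(max_examples=50, derandomize=True)
    @given(a=money, b=money, k=st.floats(min_value=0.0, max_value=1.0))
    def test_linearity(self, a, b, k):
        assert inflation_average(k * a, b) + inflation_average((1 - k) * a, 0) == (
            pytest.approx(inflation_average(a, b))
        )
        assert inflation_average(a * k, b * k) == pytest.approx(k * inflation_average(a, b))

    def test_inflation_below_minus_one_rejected(self):
        with pytest.raises(ParameterError):
            inflation_average(1, 1, inflation=-1.5)


class TestCurrency:
    def test_unit_rate(self):
        assert convert_currency(KSH_PER_EUR) == pytest.approx(1.0)

    def test_headline_total_rounds_to_690_million(self):
        eur = convert_currency(63e9)
        assert eur == pytest.approx(63e9 / 90.66)
        assert round_to_nearest(eur, 10e6) == 690e6

    def test_zero(self):
        assert convert_currency(0) == 0

    @settings(max_examples=50, derandomize=True)
    @given(amount=money, rate=st.floats(min_value=0.01, max_value=1e4))
    def test_round_trip_identity(self, amount, rate):
        assert convert_currency(amount, rate) * rate == pytest.approx(amount, rel=1e-9)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ParameterError):
            convert_currency(100, rate=0)


class TestStaffMinuteCost:
    def test_default_denominator_is_79200_minutes(self):
        pos = StaffPosition(cadre="nurse", annual_base=792_000, annual_allowances=0)
        assert staff_minute_cost(pos) == pytest.approx(10.0)

    def test_allowances_equal_to_base_double_the_rate(self):
        base = StaffPosition(cadre="n", annual_base=500_000)
        full = StaffPosition(cadre="n", annual_base=500_000, annual_allowances=500_000)
        assert staff_minute_cost(full) == pytest.approx(2 * staff_minute_cost(base))

    def test_half_working_days_doubles_the_rate(self):
        pos = StaffPosition(cadre="n", annual_base=100_000)
        half = pos.model_copy(update={"working_days": 110.0})
        assert staff_minute_cost(half) == pytest.approx(2 * staff_minute_cost(pos))

    def test_missing_pay_rejected(self):
        with pytest.raises(ParameterError):
            staff_minute_cost(StaffPosition(cadre="nurse"))


class TestImputation:
    prices = PriceList(prices={"para": 5.0, "amox": 12.0})

    def test_single_record(self):
        items = impute_inkind([InKindSupply(item_code="para", quantity=100)], self.prices)
        assert len(items) == 1
        assert items[0].amount == 500.0
        assert items[0].category is CostCategory.drugs_supplies

    def test_empty(self):
        assert impute_inkind([], self.prices) == []

    def test_two_records_sum_matches_brute_force(self):
        recs = [
            InKindSupply(item_code="para", quantity=30, centre_id="opd"),
            InKindSupply(item_code="amox", quantity=7, centre_id="opd"),
        ]
        items = impute_inkind(recs, self.prices)
        expected = sum(r.quantity * self.prices.prices[r.item_code] for r in recs)
        assert sum(i.amount for i in items) == pytest.approx(expected)

    def test_unpriced_code_named_in_error(self):
        with pytest.raises(ImputationError, match="quinine"):
            impute_inkind([InKindSupply(item_code="quinine", quantity=1)], self.prices)


class TestFallbackSalary:
    scale = {"nurse": 420_000.0}

    def test_missing_pay_filled_and_flagged(self):
        pos = StaffPosition(cadre="nurse")
        out = fallback_salary(pos, self.scale)
        assert out.annual_base == 420_000.0
        assert out.imputed

    def test_present_pay_unchanged(self):
        pos = StaffPosition(cadre="nurse", annual_base=999.0)
        assert fallback_salary(pos, self.scale) is pos

    def test_unknown_cadre_rejected(self):
        with pytest.raises(ImputationError, match="astronaut"):
            fallback_salary(StaffPosition(cadre="astronaut"), self.scale)


class TestAnnualizeRecord:
    def test_two_year_ledger_averaged_with_uplift(self, toy_record):
        rec = toy_record.model_copy(
            update={
                "items": [
                    CostItem(
                        amount=100,
                        category=CostCategory.drugs_supplies,
                        year="2005/2006",
                        traceability=Traceability.indirect,
                        target="opd",
                    ),
                    CostItem(
                        amount=110,
                        category=CostCategory.drugs_supplies,
                        year="2006/2007",
                        traceability=Traceability.indirect,
                        target="opd",
                    ),
                ],
                "year_order": ["2005/2006", "2006/2007"],
            }
        )
        ann = annualize_record(rec)
        assert [i.amount for i in ann.items] == [107.5]

    def test_assets_become_fixed_indirect_items(self, toy_record):
        rec = toy_record.model_copy(
            update={
                "assets": [
                    Asset(asset_class="vehicle", initial_value=80_000, centre_id="admin")
                ]
            }
        )
        ann = annualize_record(rec)
        fixed = [i for i in ann.items if i.category is CostCategory.fixed]
        # the toy's own 100 fixed plus the 10,000/year vehicle charge
        assert sum(i.amount for i in fixed) == pytest.approx(100 + 10_000)
        assert all(i.traceability is Traceability.indirect for i in fixed)
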