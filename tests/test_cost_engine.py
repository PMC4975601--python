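"""Annual cost breakdown, CoG/g, staffing and cost-model shape properties."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biocogs import fixtures
from biocogs.cost_engine import (
    CostModel,
    StaffingPlan,
    annual_costs,
    material_cost_multiplier,
    staffing_from_labor_share,
)
from biocogs.errors import ConfigurationError, MissingPriceError
from biocogs.process_model import ProcessParameters


class TestMaterialCostMultiplier:
    @pytest.mark.parametrize(
        "deviation, item, dominant, expected",
        [
            (0.0, "anything", {"anything"}, 1.0),
            (25.0, "ufdf_membrane", {"ufdf_membrane", "production_media"}, 1.25),
            (-25.0, "fill_bags", {"ufdf_membrane"}, 1.0),
            (-100.0, "production_media", {"production_media"}, 0.0),
        ],
    )
    def test_examples(self, deviation, item, dominant, expected):
        assert material_cost_multiplier(deviation, item, dominant) == pytest.approx(expected)

    def test_below_minus_100_rejected(self):
        with pytest.raises(ConfigurationError):
            material_cost_multiplier(-101.0, "x", {"x"})


class TestAnnualCosts:
    def test_tiny_target_means_one_batch_of_consumables(self, model):
        params = fixtures.base_parameters().replace(target_output=1e-6)
        bd = model.breakdown(params)
        assert bd.batches == 1
        one_batch = sum(
            qty * model.prices.consumable_prices[item]
            for op in model.flowsheet.operations
            for item, qty in op.consumable_demands
        )
        assert bd.by_category["consumables"] == pytest.approx(one_batch, rel=1e-9)

    def test_doubling_consumable_prices_doubles_only_that_category(self, model, base):
        import dataclasses

        bd = model.breakdown(base)
        doubled = dataclasses.replace(
            model.prices,
            consumable_prices={k: 2 * v for k, v in model.prices.consumable_prices.items()},
        )
        bd2 = annual_costs(
            base, model.flowsheet_at(base.dsp_yield), doubled, model.staffing,
            dominant_items=model.dominant_items,
        )
        assert bd2.by_category["consumables"] == pytest.approx(
            2 * bd.by_category["consumables"], rel=1e-9)
        for cat in ("capital", "materials", "labor"):
            assert bd2.by_category[cat] == pytest.approx(bd.by_category[cat], rel=1e-9)

    def test_missing_price_names_the_item(self, model, base):
        import dataclasses

        prices = dataclasses.replace(model.prices, material_prices={})
        with pytest.raises(MissingPriceError) as exc:
            annual_costs(base, model.flowsheet_at(base.dsp_yield), prices, model.staffing)
        assert "production_media" in str(exc.value)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        titer=st.floats(0.05, 6.0),
        dsp_yield=st.floats(0.90, 0.975),
        target=st.floats(1.0, 60.0),
        deviation=st.floats(-50.0, 50.0),
    )
    def test_category_conservation(self, model, titer, dsp_yield, target, deviation):
        """Categories sum to the total and per-operation attribution sums to
        consumables+materials, for randomized valid inputs (the CostBreakdown
        constructor enforces both to 1e-6 relative)."""
        params = ProcessParameters(
            titer=titer, dsp_yield=dsp_yield, target_output=target,
            material_cost_deviation=deviation,
        )
        bd = model.breakdown(params, allow_capacity_expansion=True)
        assert sum(bd.by_category.values()) == pytest.approx(bd.total, rel=1e-9)
        assert sum(bd.by_unit_operation.values()) == pytest.approx(
            bd.by_category["consumables"] + bd.by_category["materials"], rel=1e-9)
        assert bd.cog_per_gram == pytest.approx(bd.total / bd.annual_mass, rel=1e-12)


@pytest.fixture(scope="module")
def target_basis_model(calibrated):
    return fixtures.build_model(calibrated.constants, output_basis="target")


class TestCogMonotonicity:
    """Scale-economy shape of the cost surface (matches the observed ranking
    directions: better titer/yield and larger targets never raise CoG/g)."""

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(titer=st.floats(0.1, 5.0), bump=st.floats(1.01, 1.5))
    def test_nonincreasing_in_titer(self, target_basis_model, titer, bump):
        base = fixtures.base_parameters()
        lo = target_basis_model.cog(base.replace(titer=titer * bump),
                                    allow_capacity_expansion=True)
        hi = target_basis_model.cog(base.replace(titer=titer),
                                    allow_capacity_expansion=True)
        assert lo <= hi * (1 + 1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(dsp_yield=st.floats(0.90, 0.96), bump=st.floats(1.001, 1.02))
    def test_nonincreasing_in_dsp_yield(self, target_basis_model, dsp_yield, bump):
        base = fixtures.base_parameters()
        lo = target_basis_model.cog(base.replace(dsp_yield=min(0.978, dsp_yield * bump)),
                                    allow_capacity_expansion=True)
        hi = target_basis_model.cog(base.replace(dsp_yield=dsp_yield),
                                    allow_capacity_expansion=True)
        assert lo <= hi * (1 + 1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(target=st.floats(1.0, 35.0), bump=st.floats(1.01, 1.15))
    def test_nonincreasing_per_gram_in_target(self, model, target, bump):
        # within the configured train count: fixed costs spread over more grams
        base = fixtures.base_parameters()
        lo = model.cog(base.replace(target_output=target * bump))
        hi = model.cog(base.replace(target_output=target))
        assert lo <= hi * (1 + 1e-12)

    def test_titer_asymmetry(self, model, base):
        """A one-sd titer shortfall hurts more than a one-sd gain helps."""
        worse = model.cog(base.replace(titer=fixtures.BASE_TITER - fixtures.TITER_SD),
                          allow_capacity_expansion=True)
        better = model.cog(base.replace(titer=fixtures.BASE_TITER + fixtures.TITER_SD))
        mid = model.cog(base)
        assert worse - mid > mid - better

    def test_marginal_material_sensitivity_falls_with_titer(self, model, base):
        """d CoG / d deviation shrinks as titer rises (variable-cost share
        falls), the mechanism behind the significance flip."""

        def slope(titer):
            p = base.replace(titer=titer)
            up = model.cog(p.replace(material_cost_deviation=5.0),
                           allow_capacity_expansion=True)
            down = model.cog(p.replace(material_cost_deviation=-5.0),
                             allow_capacity_expansion=True)
            return (up - down) / 10.0

        slopes = [slope(t) for t in (0.12, 0.242, 1.0, 5.44)]
        assert all(a > b > 0 for a, b in zip(slopes, slopes[1:]))


class TestStaffing:
    def test_closed_form_share_no_overhead(self):
        # target 13% of total with 870k non-labor and no coupling -> 130k labor
        assert 0.13 / (1 - 0.13) * 870_000 == pytest.approx(130_000, rel=1e-3)

    def test_zero_share_is_empty(self, model, base):
        plan = staffing_from_labor_share(
            0.0, base, model.flowsheet, model.prices,
            fixtures.WAGE_SCHEDULES["UK"], dominant_items=model.dominant_items)
        assert plan.headcounts == {}
        assert plan.labor_cost() == 0.0

    def test_base_share_within_half_point(self, model, base):
        bd = model.breakdown(base)
        share = bd.by_category["labor"] / bd.total
        assert abs(share - fixtures.LABOR_SHARE) <= 0.005

    def test_unreachable_share_raises(self, model, base):
        import dataclasses

        prices = dataclasses.replace(model.prices, other_overhead_rate=10.0)
        with pytest.raises(ConfigurationError):
            staffing_from_labor_share(
                0.5, base, model.flowsheet, prices, fixtures.WAGE_SCHEDULES["UK"])

    def test_wage_swap_changes_labor_only(self, model, base):
        us = model.breakdown(base.replace(wage_schedule=fixtures.WAGE_SCHEDULES["US"]))
        uk = model.breakdown(base)
        assert us.by_category["labor"] > uk.by_category["labor"]
        for cat in ("capital", "consumables", "materials"):
            assert us.by_category[cat] == pytest.approx(uk.by_category[cat], rel=1e-12)

    def test_staffed_role_requires_wage(self):
        with pytest.raises(ConfigurationError):
            StaffingPlan({"production_operator": 2}, {})
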