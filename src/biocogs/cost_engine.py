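"""Annual cost model and CoG/g.

Cost categories
---------------
capital
    Straight-line amortization of installed equipment cost times a Lang-type
    facility multiplier, scaled by the number of parallel trains actually
    needed to schedule the year's batches.
consumables / materials
    batches x per-batch demand x unit price, with the material-cost deviation
    applied to the designated dominant items only (fermentation media and
    UF/DF filters for this process).
labor
    headcount x wage summed over roles; plant-level, independent of batch
    count.
other
    QC cost per batch plus an overhead rate applied to direct cost
    (consumables + materials + labor).

CoG/g divides total annual cost by annual product mass.  Two denominators are
supported: ``"produced"`` (batches x per-batch output, the default) and
``"target"`` (the nominal annual target).  They differ only by the ceiling
slack of the batch count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigurationError, MissingPriceError
from .process_model import (
    Flowsheet,
    ProcessParameters,
    batches_per_year,
    per_batch_output,
    required_trains,
)

__all__ = [
    "PriceTable",
    "StaffingPlan",
    "CostBreakdown",
    "CostModel",
    "material_cost_multiplier",
    "annual_costs",
    "staffing_from_labor_share",
]

CATEGORIES = ("capital", "consumables", "materials", "labor", "other")

#: headcount allocation used when sizing staff from a labor share
DEFAULT_ROLE_RATIO = {
    "production_operator": 8,
    "production_supervisor": 1,
    "quality_assurance": 2,
    "quality_control": 2,
}


@dataclass(frozen=True)
class PriceTable:
    consumable_prices: Mapping[str, float]
    material_prices: Mapping[str, float]
    equipment_costs: Mapping[str, float]  # installed cost per operation name
    amortization_years: float = 10.0
    facility_multiplier: float = 4.0
    qc_cost_per_batch: float = 0.0
    other_overhead_rate: float = 0.0  # fraction of direct cost

    def __post_init__(self):
        object.__setattr__(self, "consumable_prices", dict(self.consumable_prices))
        object.__setattr__(self, "material_prices", dict(self.material_prices))
        object.__setattr__(self, "equipment_costs", dict(self.equipment_costs))
        for name, table in (
            ("consumable_prices", self.consumable_prices),
            ("material_prices", self.material_prices),
            ("equipment_costs", self.equipment_costs),
        ):
            for item, price in table.items():
                if price < 0:
                    raise ConfigurationError(f"{name}[{item!r}] must be >= 0, got {price}")
        if self.amortization_years < 1:
            raise ConfigurationError("amortization_years must be >= 1")
        if self.facility_multiplier <= 0:
            raise ConfigurationError("facility_multiplier must be > 0")
        if self.qc_cost_per_batch < 0 or self.other_overhead_rate < 0:
            raise ConfigurationError("qc_cost_per_batch and other_overhead_rate must be >= 0")


@dataclass(frozen=True)
class StaffingPlan:
    """Headcount and wage per role; labor cost is their inner product."""

    headcounts: Mapping[str, int]
    wages: Mapping[str, float]  # currency/yr per role

    def __post_init__(self):
        object.__setattr__(self, "headcounts", dict(self.headcounts))
        object.__setattr__(self, "wages", dict(self.wages))
        for role, n in self.headcounts.items():
            if n < 0:
                raise ConfigurationError(f"headcount for {role!r} must be >= 0")
            if role not in self.wages:
                raise ConfigurationError(f"no wage for staffed role {role!r}")

    def labor_cost(self, wages: Mapping[str, float] | None = None) -> float:
        wages = self.wages if wages is None else wages
        missing = [r for r in self.headcounts if r not in wages]
        if missing:
            raise ConfigurationError(f"wage schedule missing roles: {missing}")
        return float(sum(n * wages[r] for r, n in self.headcounts.items()))

    def with_wages(self, wages: Mapping[str, float]) -> "StaffingPlan":
        return StaffingPlan(self.headcounts, wages)


@dataclass(frozen=True)
class CostBreakdown:
    by_category: Mapping[str, float]  # currency/yr
    by_unit_operation: Mapping[str, float]  # consumables+materials, currency/yr
    total: float  # currency/yr
    annual_mass: float  # g/yr
    cog_per_gram: float
    batches: int
    trains_used: int
    capacity_expanded: bool

    def __post_init__(self):
        object.__setattr__(self, "by_category", dict(self.by_category))
        object.__setattr__(self, "by_unit_operation", dict(self.by_unit_operation))
        cat_sum = sum(self.by_category.values())
        if not math.isclose(cat_sum, self.total, rel_tol=1e-6):
            raise ConfigurationError(
                f"category sum {cat_sum} != total {self.total} (conservation violated)"
            )
        attributable = self.by_category["consumables"] + self.by_category["materials"]
        op_sum = sum(self.by_unit_operation.values())
        if not math.isclose(op_sum, attributable, rel_tol=1e-6):
            raise ConfigurationError(
                f"per-operation sum {op_sum} != consumables+materials {attributable}"
            )


def material_cost_multiplier(deviation: float, item: str, dominant_set: Iterable[str]) -> float:
    """(1 + deviation/100) for items in the dominant set, 1 otherwise."""
    if deviation < -100:
        raise ConfigurationError(f"deviation must be >= -100, got {deviation}")
    return 1.0 + deviation / 100.0 if item in set(dominant_set) else 1.0


def _priced_demand(demands, prices, deviation, dominant, missing):
    total = 0.0
    for item, qty in demands:
        if item not in prices:
            missing.add(item)
            continue
        total += qty * prices[item] * material_cost_multiplier(deviation, item, dominant)
    return total


def annual_costs(
    params: ProcessParameters,
    flowsheet: Flowsheet,
    prices: PriceTable,
    staffing: StaffingPlan,
    *,
    dominant_items: Iterable[str] = (),
    output_basis: str = "produced",
    allow_capacity_expansion: bool = False,
) -> CostBreakdown:
    """Annual cost by category and unit operation, and CoG/g.

    ``output_basis`` selects the CoG/g denominator: ``"produced"`` uses the
    mass actually made (batches x per-batch output); ``"target"`` uses the
    nominal annual target.
    """
    if output_basis not in ("produced", "target"):
        raise ConfigurationError(f"unknown output_basis {output_basis!r}")
    dominant = set(dominant_items)
    dev = params.material_cost_deviation

    n_batches = batches_per_year(
        params, flowsheet, allow_capacity_expansion=allow_capacity_expansion
    )
    trains_needed = required_trains(flowsheet, n_batches)
    trains_used = max(flowsheet.parallel_trains, trains_needed)
    expanded = trains_needed > flowsheet.parallel_trains

    missing: set[str] = set()
    by_op: dict[str, float] = {}
    consumables = materials = 0.0
    for op in flowsheet.operations:
        c = _priced_demand(op.consumable_demands, prices.consumable_prices, dev, dominant, missing)
        m = _priced_demand(op.material_demands, prices.material_prices, dev, dominant, missing)
        by_op[op.name] = (c + m) * n_batches
        consumables += c * n_batches
        materials += m * n_batches
    if missing:
        raise MissingPriceError(missing)

    equipment = sum(prices.equipment_costs.get(op.name, 0.0) for op in flowsheet.operations)
    capital = equipment * prices.facility_multiplier / prices.amortization_years * trains_used

    wages = params.wage_schedule  # None -> staffing's own wage table
    labor = staffing.labor_cost(wages)

    direct = consumables + materials + labor
    other = prices.qc_cost_per_batch * n_batches + prices.other_overhead_rate * direct

    by_category = {
        "capital": capital,
        "consumables": consumables,
        "materials": materials,
        "labor": labor,
        "other": other,
    }
    total = sum(by_category.values())

    produced = n_batches * per_batch_output(params, flowsheet)
    annual_mass = produced if output_basis == "produced" else params.target_output * 1000.0
    return CostBreakdown(
        by_category=by_category,
        by_unit_operation=by_op,
        total=total,
        annual_mass=annual_mass,
        cog_per_gram=total / annual_mass,
        batches=n_batches,
        trains_used=trains_used,
        capacity_expanded=expanded,
    )


def staffing_from_labor_share(
    target_share: float,
    params: ProcessParameters,
    flowsheet: Flowsheet,
    prices: PriceTable,
    wages: Mapping[str, float],
    *,
    dominant_items: Iterable[str] = (),
    role_ratio: Mapping[str, float] | None = None,
) -> StaffingPlan:
    """Size the staff so labor is ``target_share`` of total annual cost.

    With overhead rate r coupling labor into the ``other`` category, the fixed
    point ``labor = share x total`` has the closed form

        labor* = share x non_labor / (1 - share x (1 + r)),

    where ``non_labor`` is every annual cost that does not depend on labor.
    Headcount is then allocated across roles in a fixed ratio and rounded,
    so the achieved share matches the target up to rounding granularity.
    """
    if not 0 <= target_share < 1:
        raise ConfigurationError(f"target_share must be in [0, 1), got {target_share}")
    role_ratio = dict(DEFAULT_ROLE_RATIO if role_ratio is None else role_ratio)
    if target_share == 0:
        return StaffingPlan({}, wages)

    empty = StaffingPlan({}, wages)
    base = annual_costs(
        params, flowsheet, prices, empty,
        dominant_items=dominant_items, allow_capacity_expansion=True,
    )
    non_labor = base.total
    r = prices.other_overhead_rate
    denom = 1.0 - target_share * (1.0 + r)
    if denom <= 0:
        raise ConfigurationError(
            f"labor share {target_share} unreachable with overhead rate {r} "
            "(overhead coupling >= 1 - share)"
        )
    labor_target = target_share * non_labor / denom

    unit_cost = sum(role_ratio[role] * wages[role] for role in role_ratio)
    if unit_cost <= 0:
        raise ConfigurationError("role ratio x wages must have positive cost")
    units = labor_target / unit_cost
    headcounts = {
        role: int(math.floor(units * weight + 0.5)) for role, weight in role_ratio.items()
    }
    return StaffingPlan(headcounts, wages)


@dataclass
class CostModel:
    """Bundle of flowsheet, prices, staffing and conventions.

    This is the evaluation context used by the sensitivity, Monte Carlo and
    regression layers: ``breakdown(params)`` rebuilds the flowsheet at the
    requested DSP yield (the ATPS step absorbs the overall yield) and prices
    the year.
    """

    flowsheet: Flowsheet
    prices: PriceTable
    staffing: StaffingPlan
    dominant_items: frozenset[str] = frozenset()
    wage_schedules: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    output_basis: str = "produced"
    yield_adjust_step: str = "atps_extraction"

    def flowsheet_at(self, dsp_yield: float) -> Flowsheet:
        return self.flowsheet.with_overall_yield(dsp_yield, self.yield_adjust_step)

    def breakdown(
        self, params: ProcessParameters, *, allow_capacity_expansion: bool = False
    ) -> CostBreakdown:
        fs = self.flowsheet_at(params.dsp_yield)
        return annual_costs(
            params, fs, self.prices, self.staffing,
            dominant_items=self.dominant_items,
            output_basis=self.output_basis,
            allow_capacity_expansion=allow_capacity_expansion,
        )

    def cog(self, params: ProcessParameters, **kw) -> float:
        return self.breakdown(params, **kw).cog_per_gram
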