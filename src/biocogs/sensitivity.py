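"""One-at-a-time scenario (tornado) analysis.

Each parameter is moved on its own to its worst- and best-case value while
everything else stays at base, and the resulting CoG/g deltas rank the
parameters by influence.  Worst/best are defined by effect direction, not
numeric order (a +25% material cost is the worst case; the US wage table is
the worst location).  Scenarios that overflow the schedule are evaluated with
extra parallel trains priced in and flagged on their row rather than failing
the whole table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .cost_engine import CostModel
from .errors import ConfigurationError
from .process_model import ProcessParameters

__all__ = ["Scenario", "ScenarioTable", "TornadoRow", "build_scenarios", "tornado"]

#: ProcessParameters fields a scenario may perturb
_PARAM_FIELDS = {"titer", "dsp_yield", "target_output", "material_cost_deviation"}

WAGE_PARAMETER = "operator_wage_location"


@dataclass(frozen=True)
class Scenario:
    worst: object
    base: object
    best: object


@dataclass(frozen=True)
class ScenarioTable:
    """Per-parameter (worst, base, best) values, plus named wage-location
    scenarios that swap the whole four-role wage schedule atomically."""

    parameters: Mapping[str, Scenario]
    wage_scenarios: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    wage_order: Scenario | None = None  # worst/base/best location names

    def __post_init__(self):
        object.__setattr__(self, "parameters", dict(self.parameters))
        object.__setattr__(self, "wage_scenarios", dict(self.wage_scenarios))
        if self.wage_order is not None:
            for loc in (self.wage_order.worst, self.wage_order.base, self.wage_order.best):
                if loc not in self.wage_scenarios:
                    raise ConfigurationError(f"wage scenario {loc!r} not provided")


def build_scenarios(
    base: ProcessParameters,
    titer_sd: float,
    yield_sd: float,
    material_swing: float,
    output_factor: float,
    wage_scenarios: Mapping[str, Mapping[str, float]] | None = None,
    wage_order: Scenario | None = None,
) -> ScenarioTable:
    """Scenario bounds from the standard rules.

    Titer and DSP yield move to mean -/+ one standard deviation; material
    cost swings by ``-/+material_swing`` percent; target output is divided or
    multiplied by ``output_factor``.
    """
    if titer_sd < 0 or yield_sd < 0:
        raise ConfigurationError("standard deviations must be >= 0")
    if not output_factor > 1:
        raise ConfigurationError("output_factor must be > 1")
    params = {
        "titer": Scenario(base.titer - titer_sd, base.titer, base.titer + titer_sd),
        "dsp_yield": Scenario(
            base.dsp_yield - yield_sd, base.dsp_yield, base.dsp_yield + yield_sd
        ),
        "material_cost_deviation": Scenario(+material_swing, 0.0, -material_swing),
        "target_output": Scenario(
            base.target_output / output_factor,
            base.target_output,
            base.target_output * output_factor,
        ),
    }
    return ScenarioTable(params, wage_scenarios or {}, wage_order)


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    cog_worst: float
    cog_base: float
    cog_best: float
    expanded_worst: bool = False
    expanded_best: bool = False

    @property
    def delta_worst(self) -> float:
        return self.cog_worst - self.cog_base

    @property
    def delta_best(self) -> float:
        return self.cog_best - self.cog_base

    @property
    def max_abs_delta(self) -> float:
        return max(abs(self.delta_worst), abs(self.delta_best))

    @property
    def range(self) -> float:
        return abs(self.cog_worst - self.cog_best)


def _evaluate(model: CostModel, params: ProcessParameters):
    bd = model.breakdown(params, allow_capacity_expansion=True)
    return bd.cog_per_gram, bd.capacity_expanded


def tornado(
    base: ProcessParameters,
    table: ScenarioTable,
    model: CostModel,
    *,
    metric: str = "max_abs",
) -> list[TornadoRow]:
    """Evaluate every scenario one-at-a-time and rank parameters by impact.

    ``metric`` is ``"max_abs"`` (largest one-sided |delta|, the default) or
    ``"range"`` (worst-to-best span).  Rows are sorted by decreasing impact;
    ties and the base CoG are identical across rows by construction.
    """
    if metric not in ("max_abs", "range"):
        raise ConfigurationError(f"unknown ranking metric {metric!r}")
    cog_base, _ = _evaluate(model, base)

    rows: list[TornadoRow] = []
    for name in sorted(table.parameters):
        scen = table.parameters[name]
        if name in _PARAM_FIELDS:
            cw, ew = _evaluate(model, base.replace(**{name: scen.worst}))
            cb, eb = _evaluate(model, base.replace(**{name: scen.best}))
        else:
            # parameter not consumed by the cost model: zero delta by definition
            cw, ew = cog_base, False
            cb, eb = cog_base, False
        rows.append(TornadoRow(name, cw, cog_base, cb, ew, eb))

    if table.wage_order is not None:
        ww = table.wage_scenarios[table.wage_order.worst]
        wb = table.wage_scenarios[table.wage_order.best]
        cw, ew = _evaluate(model, base.replace(wage_schedule=ww))
        cb, eb = _evaluate(model, base.replace(wage_schedule=wb))
        rows.append(TornadoRow(WAGE_PARAMETER, cw, cog_base, cb, ew, eb))

    key = (lambda r: r.max_abs_delta) if metric == "max_abs" else (lambda r: r.range)
    rows.sort(key=lambda r: (-key(r), r.parameter))
    return rows
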