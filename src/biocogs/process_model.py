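"""Flowsheet representation, mass balance and batch scheduling.

The modelled process is a fed-batch *Pichia pastoris* fermentation producing
Royalactin (major royal jelly protein 1), followed by cell removal, selective
recovery into the light phase of an aqueous two-phase system (ATPS),
ultrafiltration/diafiltration (UF/DF) for concentration and buffer exchange,
and bulk fill.  The flowsheet is purely descriptive: each unit operation
carries an occupancy time, in/out volumes, a step yield and per-batch
consumable and material demands.  Product mass balance is

    per-batch output (g) = titer (g/L) x fermenter working volume (L)
                           x overall DSP yield,

and the annual batch count is the smallest integer covering the target output.
Scheduling assumes staggered trains, so plant throughput is limited by the
longest single stage occupancy, not the sum of stage times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import ConfigurationError, InfeasibleScheduleError

__all__ = [
    "ProcessParameters",
    "UnitOperation",
    "Flowsheet",
    "overall_yield",
    "per_batch_output",
    "batches_per_year",
]


@dataclass(frozen=True)
class ProcessParameters:
    """The analyzed process inputs.

    Parameters
    ----------
    titer : float
        Product concentration at the end of production fermentation, g/L.
    dsp_yield : float
        Overall downstream recovery, fraction in (0, 1].
    target_output : float
        Required annual product mass, kg/yr.
    material_cost_deviation : float
        Signed percentage applied to the designated dominant cost items
        (fermentation media and UF/DF filters); e.g. ``+25`` means those
        items cost 25% more.  Must be >= -100.
    wage_schedule : mapping or None
        Annual salary per labor role (currency/yr).  ``None`` means use the
        wage table of the active cost model.
    """

    titer: float
    dsp_yield: float
    target_output: float
    material_cost_deviation: float = 0.0
    wage_schedule: Mapping[str, float] | None = None

    def __post_init__(self):
        if not self.titer > 0:
            raise ConfigurationError(f"ProcessParameters.titer must be > 0, got {self.titer}")
        if not 0 < self.dsp_yield <= 1:
            raise ConfigurationError(
                f"ProcessParameters.dsp_yield must be in (0, 1], got {self.dsp_yield}"
            )
        if not self.target_output > 0:
            raise ConfigurationError(
                f"ProcessParameters.target_output must be > 0, got {self.target_output}"
            )
        if self.material_cost_deviation < -100:
            raise ConfigurationError(
                "ProcessParameters.material_cost_deviation must be >= -100, "
                f"got {self.material_cost_deviation}"
            )

    def replace(self, **changes) -> "ProcessParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class UnitOperation:
    """One stage of the flowsheet.

    ``consumable_demands`` and ``material_demands`` are per-batch
    (item id, quantity) pairs; quantities are in the item's natural unit
    (L of medium, kg of polymer, membrane cassettes, ...).
    """

    name: str
    duration: float  # batch occupancy, h
    volume_in: float  # L
    volume_out: float  # L
    step_yield: float  # fraction of product retained
    consumable_demands: tuple[tuple[str, float], ...] = ()
    material_demands: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if not self.duration > 0:
            raise ConfigurationError(f"{self.name}: duration must be > 0")
        if not (self.volume_in > 0 and self.volume_out > 0):
            raise ConfigurationError(f"{self.name}: volumes must be > 0")
        if not 0 < self.step_yield <= 1:
            raise ConfigurationError(
                f"{self.name}: step_yield must be in (0, 1], got {self.step_yield}"
            )
        object.__setattr__(self, "consumable_demands", tuple(map(tuple, self.consumable_demands)))
        object.__setattr__(self, "material_demands", tuple(map(tuple, self.material_demands)))


@dataclass(frozen=True)
class Flowsheet:
    """Ordered unit operations plus plant-level scheduling data."""

    operations: tuple[UnitOperation, ...]
    fermenter_working_volume: float  # L
    plant_available_days: float = 330.0
    parallel_trains: int = 1

    def __post_init__(self):
        object.__setattr__(self, "operations", tuple(self.operations))
        if not self.operations:
            raise ConfigurationError("Flowsheet must contain at least one operation")
        if not self.fermenter_working_volume > 0:
            raise ConfigurationError("fermenter_working_volume must be > 0")
        if not self.plant_available_days > 0:
            raise ConfigurationError("plant_available_days must be > 0")
        if not (isinstance(self.parallel_trains, int) and self.parallel_trains >= 1):
            raise ConfigurationError("parallel_trains must be an integer >= 1")

    @property
    def overall_yield(self) -> float:
        return math.prod(op.step_yield for op in self.operations)

    @property
    def batch_occupancy_hours(self) -> float:
        # staggered trains: the slowest stage paces the plant
        return max(op.duration for op in self.operations)

    def max_batches_per_year(self, trains: int | None = None) -> int:
        """Scheduling capacity, batches/yr, for ``trains`` parallel trains."""
        if trains is None:
            trains = self.parallel_trains
        per_train = math.floor(self.plant_available_days * 24.0 / self.batch_occupancy_hours)
        return per_train * trains

    def with_overall_yield(self, dsp_yield: float, adjust_step: str) -> "Flowsheet":
        """Rescale the yield of ``adjust_step`` so the product of step yields
        equals ``dsp_yield`` exactly (the recovery step absorbs the overall
        yield; fixed handling losses stay on the other steps)."""
        if not 0 < dsp_yield <= 1:
            raise ConfigurationError(f"dsp_yield must be in (0, 1], got {dsp_yield}")
        others = math.prod(
            op.step_yield for op in self.operations if op.name != adjust_step
        )
        if not any(op.name == adjust_step for op in self.operations):
            raise ConfigurationError(f"no operation named {adjust_step!r} to adjust")
        new_yield = dsp_yield / others
        if not 0 < new_yield <= 1:
            raise ConfigurationError(
                f"cannot reach overall yield {dsp_yield}: step {adjust_step!r} "
                f"would need yield {new_yield:.4f}"
            )
        ops = tuple(
            replace(op, step_yield=new_yield) if op.name == adjust_step else op
            for op in self.operations
        )
        return replace(self, operations=ops)


def overall_yield(flowsheet: Flowsheet) -> float:
    """Product of all step yields, in (0, 1]."""
    return flowsheet.overall_yield


def per_batch_output(params: ProcessParameters, flowsheet: Flowsheet) -> float:
    """Product mass recovered per batch, g."""
    return params.titer * flowsheet.fermenter_working_volume * flowsheet.overall_yield


def required_trains(flowsheet: Flowsheet, n_batches: int) -> int:
    """Minimum number of parallel trains that can schedule ``n_batches``/yr."""
    per_train = flowsheet.max_batches_per_year(trains=1)
    return max(1, math.ceil(n_batches / per_train))


def batches_per_year(
    params: ProcessParameters,
    flowsheet: Flowsheet,
    *,
    allow_capacity_expansion: bool = False,
) -> int:
    """Smallest batch count covering the annual target (at least one batch).

    Raises :class:`InfeasibleScheduleError` when the count exceeds the
    configured scheduling capacity, unless ``allow_capacity_expansion`` is
    set (the caller then prices in extra parallel trains).
    """
    per_batch = per_batch_output(params, flowsheet)
    if not per_batch > 0:
        raise ConfigurationError("per-batch output must be > 0")
    n = max(1, math.ceil(params.target_output * 1000.0 / per_batch))
    # guard against float ceiling overshoot on exact multiples
    if (n - 1) * per_batch >= params.target_output * 1000.0:
        n -= 1
    available = flowsheet.max_batches_per_year()
    if n > available and not allow_capacity_expansion:
        raise InfeasibleScheduleError(required=n, available=available)
    return n
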