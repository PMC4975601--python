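"""Synthetic configuration fixtures.

The published study was run in a closed commercial cost database, so every
configuration input here — the flowsheet geometry, equipment costs, unit
prices, QC and overhead constants — is a synthetic, openly documented
stand-in designed so the open model reproduces the study's printed anchors
(base CoG/g, labor share, category ordering) and qualitative structure.  The
process parameters, scenario bounds and wage tables, by contrast, are the
published values verbatim.

Everything is generated programmatically; :func:`generate_fixtures` writes
the whole set as versioned YAML (``schema: biocogs/1``) so the pipeline runs
with no external data.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import yaml

from .cost_engine import (
    CostModel,
    PriceTable,
    StaffingPlan,
    staffing_from_labor_share,
)
from .process_model import Flowsheet, ProcessParameters, UnitOperation
from .sensitivity import Scenario, ScenarioTable, build_scenarios
from .uncertainty import MCConfig, TriangularDist

__all__ = [
    "base_parameters",
    "base_flowsheet",
    "default_constants",
    "build_price_table",
    "build_model",
    "wage_schedules",
    "scenario_table",
    "mc_config_before",
    "mc_config_after",
    "generate_fixtures",
    "DOMINANT_ITEMS",
    "LABOR_SHARE",
]

SCHEMA = "biocogs/1"

# ---------------------------------------------------------------- published
# Base process parameters and scenario rules (published values, verbatim).
BASE_TITER = 0.242  # g/L
TITER_SD = 0.134  # g/L
BASE_DSP_YIELD = 0.958
DSP_YIELD_SD = 0.011
BASE_TARGET_OUTPUT = 25.6  # kg/yr
MATERIAL_SWING = 25.0  # percent
OUTPUT_FACTOR = 2.0  # target halves / doubles
LABOR_SHARE = 0.13
ANCHOR_COG = 843.0  # US$/g, deterministic base case

# Optimized titer range (mean +/- sd) from stacking a 3-fold strain-selection
# gain with a 7.5-fold gene-copy-number gain.
OPTIMIZED_TITER_MEAN = 5.44
OPTIMIZED_TITER_SD = 2.44
TITER_FOLD_FACTORS = (3.0, 7.5)

#: Annual wages per role by location; the UK table is the base case.
WAGE_SCHEDULES: dict[str, dict[str, float]] = {
    "US": {
        "production_operator": 41_872.0,
        "production_supervisor": 52_337.0,
        "quality_assurance": 70_149.0,
        "quality_control": 39_101.0,
    },
    "UK": {
        "production_operator": 32_935.0,
        "production_supervisor": 38_490.0,
        "quality_assurance": 56_176.0,
        "quality_control": 31_400.0,
    },
    "Mexico": {
        "production_operator": 37_689.0,
        "production_supervisor": 37_689.0,
        "quality_assurance": 35_995.0,
        "quality_control": 35_995.0,
    },
}
WAGE_ORDER = Scenario(worst="US", base="UK", best="Mexico")

#: Items whose price the material-cost deviation applies to: the fermentation
#: media (buffered glycerol-complex medium, seed and production) and the
#: UF/DF filters, the dominant variable-cost items of this flowsheet.
DOMINANT_ITEMS = frozenset({"seed_media", "production_media", "ufdf_membrane"})

# ---------------------------------------------------------------- synthetic
#: Free constants the calibration module may move (synthetic stand-ins).
DEFAULT_CONSTANTS: dict[str, float] = {
    "equipment_scale": 1.0,  # multiplies all installed equipment costs
    "media_price_per_l": 8.0,  # US$/L, seed and production media
    "ufdf_membrane_price": 10_000.0,  # US$/cassette
    "qc_cost_per_batch": 26_000.0,  # US$/batch
    "fermenter_volume_l": 2_000.0,  # production working volume
}

#: Installed equipment cost per operation at equipment_scale = 1 (synthetic).
_EQUIPMENT_COSTS: dict[str, float] = {
    "seed_fermentation": 800_000.0,
    "production_fermentation": 9_000_000.0,
    "cell_removal": 2_200_000.0,
    "atps_extraction": 3_000_000.0,
    "ufdf": 4_500_000.0,
    "bulk_fill": 1_750_000.0,
}

AMORTIZATION_YEARS = 10.0
FACILITY_MULTIPLIER = 4.0
OVERHEAD_RATE = 0.05


def base_parameters(wage_schedule: Mapping[str, float] | None = None) -> ProcessParameters:
    """Published base-case process parameters."""
    return ProcessParameters(
        titer=BASE_TITER,
        dsp_yield=BASE_DSP_YIELD,
        target_output=BASE_TARGET_OUTPUT,
        material_cost_deviation=0.0,
        wage_schedule=wage_schedule,
    )


def default_constants() -> dict[str, float]:
    return dict(DEFAULT_CONSTANTS)


def base_flowsheet(
    fermenter_volume: float = DEFAULT_CONSTANTS["fermenter_volume_l"],
    dsp_yield: float = BASE_DSP_YIELD,
) -> Flowsheet:
    """Canonical six-stage flowsheet (synthetic stand-in geometry).

    Volumes, durations and per-batch demands scale linearly with the
    production fermenter working volume; the ATPS step absorbs the overall
    DSP yield so the step-yield product equals ``dsp_yield`` exactly.
    """
    s = fermenter_volume / 2000.0  # linear scale factor vs reference geometry
    ops = (
        UnitOperation(
            "seed_fermentation", duration=24.0, volume_in=100.0 * s, volume_out=100.0 * s,
            step_yield=1.0,
            material_demands=(("seed_media", 100.0 * s),),
        ),
        UnitOperation(
            "production_fermentation", duration=90.0,
            volume_in=2000.0 * s, volume_out=2000.0 * s, step_yield=1.0,
            consumable_demands=(("fermentation_filter", 2.0),),
            material_demands=(("production_media", 2000.0 * s),),
        ),
        UnitOperation(
            "cell_removal", duration=6.0, volume_in=2000.0 * s, volume_out=1900.0 * s,
            step_yield=0.99,
        ),
        UnitOperation(
            "atps_extraction", duration=8.0, volume_in=1900.0 * s, volume_out=600.0 * s,
            step_yield=0.98,  # placeholder; normalized below
            consumable_demands=(("atps_disposables", 6.0),),
            material_demands=(("peg_4000", 300.0 * s), ("phosphate_salt", 400.0 * s)),
        ),
        UnitOperation(
            "ufdf", duration=12.0, volume_in=600.0 * s, volume_out=50.0 * s,
            step_yield=0.99,
            consumable_demands=(("ufdf_membrane", 8.0 * s),),
            material_demands=(("diafiltration_buffer", 4000.0 * s),),
        ),
        UnitOperation(
            "bulk_fill", duration=4.0, volume_in=50.0 * s, volume_out=50.0 * s,
            step_yield=1.0,
            consumable_demands=(("fill_bags", 5.0),),
        ),
    )
    fs = Flowsheet(
        operations=ops,
        fermenter_working_volume=fermenter_volume,
        plant_available_days=330.0,
        parallel_trains=1,
    )
    return fs.with_overall_yield(dsp_yield, "atps_extraction")


def build_price_table(constants: Mapping[str, float] | None = None) -> PriceTable:
    """Price table from the (possibly calibrated) free constants."""
    c = {**DEFAULT_CONSTANTS, **(constants or {})}
    consumable_prices = {
        "fermentation_filter": 500.0,
        "atps_disposables": 4_000.0,
        "ufdf_membrane": c["ufdf_membrane_price"],
        "fill_bags": 400.0,
    }
    material_prices = {
        "seed_media": c["media_price_per_l"],
        "production_media": c["media_price_per_l"],
        "peg_4000": 50.0,
        "phosphate_salt": 20.0,
        "diafiltration_buffer": 1.2,
    }
    equipment = {
        name: cost * c["equipment_scale"] for name, cost in _EQUIPMENT_COSTS.items()
    }
    return PriceTable(
        consumable_prices=consumable_prices,
        material_prices=material_prices,
        equipment_costs=equipment,
        amortization_years=AMORTIZATION_YEARS,
        facility_multiplier=FACILITY_MULTIPLIER,
        qc_cost_per_batch=c["qc_cost_per_batch"],
        other_overhead_rate=OVERHEAD_RATE,
    )


def wage_schedules() -> dict[str, dict[str, float]]:
    return {loc: dict(t) for loc, t in WAGE_SCHEDULES.items()}


def build_model(
    constants: Mapping[str, float] | None = None,
    *,
    wage_location: str = "UK",
    labor_share: float = LABOR_SHARE,
    output_basis: str = "produced",
) -> CostModel:
    """Assemble the full cost model: flowsheet, prices and a staffing plan
    sized so labor is ``labor_share`` of base-case total cost."""
    c = {**DEFAULT_CONSTANTS, **(constants or {})}
    flowsheet = base_flowsheet(c["fermenter_volume_l"])
    prices = build_price_table(c)
    wages = WAGE_SCHEDULES[wage_location]
    staffing = staffing_from_labor_share(
        labor_share, base_parameters(), flowsheet, prices, wages,
        dominant_items=DOMINANT_ITEMS,
    )
    return CostModel(
        flowsheet=flowsheet,
        prices=prices,
        staffing=staffing,
        dominant_items=DOMINANT_ITEMS,
        wage_schedules=wage_schedules(),
        output_basis=output_basis,
    )


def scenario_table() -> ScenarioTable:
    """Worst/base/best scenario table built from the published rules."""
    return build_scenarios(
        base_parameters(),
        titer_sd=TITER_SD,
        yield_sd=DSP_YIELD_SD,
        material_swing=MATERIAL_SWING,
        output_factor=OUTPUT_FACTOR,
        wage_scenarios=wage_schedules(),
        wage_order=WAGE_ORDER,
    )


def _target_dist() -> TriangularDist:
    return TriangularDist(
        BASE_TARGET_OUTPUT / OUTPUT_FACTOR, BASE_TARGET_OUTPUT,
        BASE_TARGET_OUTPUT * OUTPUT_FACTOR,
    )


def _material_dist() -> TriangularDist:
    return TriangularDist(-MATERIAL_SWING, 0.0, MATERIAL_SWING)


def mc_config_before(seed: int = 0, max_runs: int = 300) -> MCConfig:
    """Joint Monte Carlo config at the unoptimized titer (scenario-table
    bounds as triangular min/mode/max)."""
    return MCConfig(
        distributions={
            "titer": TriangularDist(BASE_TITER - TITER_SD, BASE_TITER, BASE_TITER + TITER_SD),
            "target_output": _target_dist(),
            "material_cost_deviation": _material_dist(),
        },
        max_runs=max_runs, ma_window=50, ma_tolerance=0.01, seed=seed,
    )


def mc_config_after(seed: int = 0, max_runs: int = 300) -> MCConfig:
    """As :func:`mc_config_before` but with the optimized titer range
    (mode 5.44, min/max one reported sd either side)."""
    return MCConfig(
        distributions={
            "titer": TriangularDist(
                OPTIMIZED_TITER_MEAN - OPTIMIZED_TITER_SD,
                OPTIMIZED_TITER_MEAN,
                OPTIMIZED_TITER_MEAN + OPTIMIZED_TITER_SD,
            ),
            "target_output": _target_dist(),
            "material_cost_deviation": _material_dist(),
        },
        max_runs=max_runs, ma_window=50, ma_tolerance=0.01, seed=seed,
    )


# --------------------------------------------------------------- YAML dump

def _q(value: float, unit: str) -> dict:
    return {"value": float(value), "unit": unit}


def _flowsheet_doc(fs: Flowsheet) -> dict:
    return {
        "schema": SCHEMA,
        "kind": "flowsheet",
        "fermenter_working_volume": _q(fs.fermenter_working_volume, "L"),
        "plant_available_days": _q(fs.plant_available_days, "day/yr"),
        "parallel_trains": fs.parallel_trains,
        "operations": [
            {
                "name": op.name,
                "duration": _q(op.duration, "h"),
                "volume_in": _q(op.volume_in, "L"),
                "volume_out": _q(op.volume_out, "L"),
                "step_yield": _q(op.step_yield, "fraction"),
                "consumable_demands": [
                    {"item": i, "quantity": _q(q, "unit/batch")} for i, q in op.consumable_demands
                ],
                "material_demands": [
                    {"item": i, "quantity": _q(q, "unit/batch")} for i, q in op.material_demands
                ],
            }
            for op in fs.operations
        ],
    }


def _prices_doc(pt: PriceTable) -> dict:
    return {
        "schema": SCHEMA,
        "kind": "prices",
        "consumable_prices": {i: _q(p, "USD/unit") for i, p in sorted(pt.consumable_prices.items())},
        "material_prices": {i: _q(p, "USD/unit") for i, p in sorted(pt.material_prices.items())},
        "equipment_costs": {i: _q(p, "USD") for i, p in sorted(pt.equipment_costs.items())},
        "amortization_years": _q(pt.amortization_years, "yr"),
        "facility_multiplier": _q(pt.facility_multiplier, "dimensionless"),
        "qc_cost_per_batch": _q(pt.qc_cost_per_batch, "USD/batch"),
        "other_overhead_rate": _q(pt.other_overhead_rate, "fraction"),
    }


def _parameters_doc(p: ProcessParameters) -> dict:
    return {
        "schema": SCHEMA,
        "kind": "parameters",
        "titer": _q(p.titer, "g/L"),
        "dsp_yield": _q(p.dsp_yield, "fraction"),
        "target_output": _q(p.target_output, "kg/yr"),
        "material_cost_deviation": _q(p.material_cost_deviation, "percent"),
        "dominant_items": sorted(DOMINANT_ITEMS),
        "labor_share": _q(LABOR_SHARE, "fraction"),
        "wage_location": "UK",
    }


def _scenarios_doc(t: ScenarioTable) -> dict:
    units = {
        "titer": "g/L",
        "dsp_yield": "fraction",
        "target_output": "kg/yr",
        "material_cost_deviation": "percent",
    }
    return {
        "schema": SCHEMA,
        "kind": "scenarios",
        "parameters": {
            name: {
                "worst": _q(s.worst, units[name]),
                "base": _q(s.base, units[name]),
                "best": _q(s.best, units[name]),
            }
            for name, s in sorted(t.parameters.items())
        },
        "wage_scenarios": {
            loc: {role: _q(w, "USD/yr") for role, w in sorted(tab.items())}
            for loc, tab in sorted(t.wage_scenarios.items())
        },
        "wage_order": {
            "worst": t.wage_order.worst, "base": t.wage_order.base, "best": t.wage_order.best,
        },
    }


def _mc_doc(cfg: MCConfig) -> dict:
    units = {"titer": "g/L", "dsp_yield": "fraction", "target_output": "kg/yr",
             "material_cost_deviation": "percent"}
    return {
        "schema": SCHEMA,
        "kind": "mc",
        "distributions": {
            name: {
                "min": _q(d.min, units[name]),
                "mode": _q(d.mode, units[name]),
                "max": _q(d.max, units[name]),
            }
            for name, d in sorted(cfg.distributions.items())
        },
        "max_runs": cfg.max_runs,
        "ma_window": cfg.ma_window,
        "ma_tolerance": cfg.ma_tolerance,
        "seed": cfg.seed,
    }


def generate_fixtures(seed: int, outdir: str | Path) -> list[Path]:
    """Write the full fixture set as YAML; byte-identical for a given seed.

    The seed is recorded in the Monte Carlo configs (before: seed, after:
    seed + 1) and is the only seed-dependent content.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    docs = {
        "flowsheet.yaml": _flowsheet_doc(base_flowsheet()),
        "prices.yaml": _prices_doc(build_price_table()),
        "parameters.yaml": _parameters_doc(base_parameters()),
        "scenarios.yaml": _scenarios_doc(scenario_table()),
        "mc_before.yaml": _mc_doc(mc_config_before(seed=seed)),
        "mc_after.yaml": _mc_doc(mc_config_after(seed=seed + 1)),
    }
    written = []
    for name, doc in docs.items():
        path = outdir / name
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)
        written.append(path)
    return written
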