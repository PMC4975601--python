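"""Declarative configuration: schema-versioned YAML with explicit units.

Every fixture file carries ``schema: biocogs/1`` and a ``kind`` key
(flowsheet / prices / parameters / scenarios / mc).  Numeric quantities are
written as ``{value: <number>, unit: "<unit>"}`` pairs and the validator
checks the unit string against the expected one, so a config written in the
wrong unit fails loudly instead of silently mispricing the plant.
Validation collects every problem it finds rather than stopping at the
first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .cost_engine import PriceTable
from .errors import ConfigurationError
from .process_model import Flowsheet, ProcessParameters, UnitOperation
from .sensitivity import Scenario, ScenarioTable
from .uncertainty import MCConfig, TriangularDist

__all__ = ["ConfigIssue", "validate_config", "load_config", "load_fixture_set", "FixtureSet"]

SCHEMA = "biocogs/1"
KINDS = ("flowsheet", "prices", "parameters", "scenarios", "mc")


@dataclass(frozen=True)
class ConfigIssue:
    path: str  # dotted location inside the file
    message: str

    def __str__(self):
        return f"{self.path}: {self.message}"


class _Checker:
    def __init__(self):
        self.issues: list[ConfigIssue] = []

    def error(self, path: str, message: str):
        self.issues.append(ConfigIssue(path, message))

    def quantity(self, doc: Any, path: str, unit: str, *, minimum=None, maximum=None):
        """Check a {value, unit} pair; returns the value or None."""
        if not isinstance(doc, dict) or set(doc) != {"value", "unit"}:
            self.error(path, "expected a {value, unit} mapping")
            return None
        if doc["unit"] != unit:
            self.error(path, f"expected unit {unit!r}, got {doc['unit']!r}")
        v = doc["value"]
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            self.error(path, f"value must be numeric, got {v!r}")
            return None
        if minimum is not None and v < minimum:
            self.error(path, f"value {v} below minimum {minimum}")
        if maximum is not None and v > maximum:
            self.error(path, f"value {v} above maximum {maximum}")
        return float(v)


def _check_header(doc: dict, kind: str | None, chk: _Checker):
    if doc.get("schema") != SCHEMA:
        chk.error("schema", f"expected {SCHEMA!r}, got {doc.get('schema')!r}")
    k = doc.get("kind")
    if k not in KINDS:
        chk.error("kind", f"unknown kind {k!r}; expected one of {KINDS}")
    elif kind is not None and k != kind:
        chk.error("kind", f"expected kind {kind!r}, got {k!r}")
    return k


_PARAM_UNITS = {
    "titer": ("g/L", 1e-12, None),
    "dsp_yield": ("fraction", 1e-12, 1.0),
    "target_output": ("kg/yr", 1e-12, None),
    "material_cost_deviation": ("percent", -100.0, None),
}


def _validate_parameters(doc: dict, chk: _Checker):
    for key, (unit, lo, hi) in _PARAM_UNITS.items():
        if key not in doc:
            chk.error(key, "missing")
            continue
        chk.quantity(doc[key], key, unit, minimum=lo, maximum=hi)
    known = {"schema", "kind", "dominant_items", "labor_share", "wage_location", *_PARAM_UNITS}
    for key in doc:
        if key not in known:
            chk.error(key, "unknown key")
    if "labor_share" in doc:
        chk.quantity(doc["labor_share"], "labor_share", "fraction", minimum=0.0, maximum=0.99)


def _validate_flowsheet(doc: dict, chk: _Checker):
    chk.quantity(doc.get("fermenter_working_volume"), "fermenter_working_volume", "L", minimum=1e-9)
    chk.quantity(doc.get("plant_available_days"), "plant_available_days", "day/yr", minimum=1e-9)
    trains = doc.get("parallel_trains")
    if not (isinstance(trains, int) and trains >= 1):
        chk.error("parallel_trains", f"must be an integer >= 1, got {trains!r}")
    ops = doc.get("operations")
    if not isinstance(ops, list) or not ops:
        chk.error("operations", "must be a non-empty list")
        return
    for i, op in enumerate(ops):
        loc = f"operations[{i}]"
        if not isinstance(op, dict) or "name" not in op:
            chk.error(loc, "each operation needs a name")
            continue
        chk.quantity(op.get("duration"), f"{loc}.duration", "h", minimum=1e-9)
        chk.quantity(op.get("volume_in"), f"{loc}.volume_in", "L", minimum=1e-9)
        chk.quantity(op.get("volume_out"), f"{loc}.volume_out", "L", minimum=1e-9)
        chk.quantity(op.get("step_yield"), f"{loc}.step_yield", "fraction",
                     minimum=1e-12, maximum=1.0)
        for kind in ("consumable_demands", "material_demands"):
            for j, d in enumerate(op.get(kind, []) or []):
                chk.quantity(d.get("quantity"), f"{loc}.{kind}[{j}].quantity",
                             "unit/batch", minimum=0.0)


def _validate_prices(doc: dict, chk: _Checker):
    for section, unit in (
        ("consumable_prices", "USD/unit"),
        ("material_prices", "USD/unit"),
        ("equipment_costs", "USD"),
    ):
        table = doc.get(section)
        if not isinstance(table, dict):
            chk.error(section, "must be a mapping")
            continue
        for item, q in table.items():
            chk.quantity(q, f"{section}.{item}", unit, minimum=0.0)
    chk.quantity(doc.get("amortization_years"), "amortization_years", "yr", minimum=1.0)
    chk.quantity(doc.get("facility_multiplier"), "facility_multiplier", "dimensionless",
                 minimum=1e-9)
    chk.quantity(doc.get("qc_cost_per_batch"), "qc_cost_per_batch", "USD/batch", minimum=0.0)
    chk.quantity(doc.get("other_overhead_rate"), "other_overhead_rate", "fraction", minimum=0.0)


def _validate_scenarios(doc: dict, chk: _Checker):
    params = doc.get("parameters")
    if not isinstance(params, dict):
        chk.error("parameters", "must be a mapping")
    else:
        for name, scen in params.items():
            unit = _PARAM_UNITS.get(name, (None,))[0]
            for which in ("worst", "base", "best"):
                if which not in scen:
                    chk.error(f"parameters.{name}.{which}", "missing")
                elif unit is not None:
                    chk.quantity(scen[which], f"parameters.{name}.{which}", unit)
    roles = {"production_operator", "production_supervisor",
             "quality_assurance", "quality_control"}
    wages = doc.get("wage_scenarios", {})
    for loc, table in wages.items():
        missing = roles - set(table)
        if missing:
            chk.error(f"wage_scenarios.{loc}", f"missing roles: {sorted(missing)}")
        for role, q in table.items():
            chk.quantity(q, f"wage_scenarios.{loc}.{role}", "USD/yr", minimum=0.0)
    order = doc.get("wage_order")
    if order is not None:
        for which in ("worst", "base", "best"):
            if order.get(which) not in wages:
                chk.error(f"wage_order.{which}",
                          f"location {order.get(which)!r} not in wage_scenarios")


def _validate_mc(doc: dict, chk: _Checker):
    dists = doc.get("distributions")
    if not isinstance(dists, dict) or not dists:
        chk.error("distributions", "must be a non-empty mapping")
    else:
        for name, d in dists.items():
            unit = _PARAM_UNITS.get(name, (None,))[0]
            if unit is None:
                chk.error(f"distributions.{name}", "not a samplable parameter")
                continue
            vals = {}
            for which in ("min", "mode", "max"):
                vals[which] = chk.quantity(d.get(which), f"distributions.{name}.{which}", unit)
            if None not in vals.values() and not vals["min"] <= vals["mode"] <= vals["max"]:
                chk.error(f"distributions.{name}", "need min <= mode <= max")
    for key, lo in (("max_runs", 2), ("ma_window", 2)):
        v = doc.get(key)
        if not (isinstance(v, int) and v >= lo):
            chk.error(key, f"must be an integer >= {lo}, got {v!r}")
    tol = doc.get("ma_tolerance")
    if not (isinstance(tol, (int, float)) and tol > 0):
        chk.error("ma_tolerance", f"must be > 0, got {tol!r}")
    if not isinstance(doc.get("seed"), int):
        chk.error("seed", "must be an integer")


_VALIDATORS = {
    "flowsheet": _validate_flowsheet,
    "prices": _validate_prices,
    "parameters": _validate_parameters,
    "scenarios": _validate_scenarios,
    "mc": _validate_mc,
}


def validate_config(file: str | Path, kind: str | None = None) -> list[ConfigIssue]:
    """Validate one YAML config file; returns all problems found (empty when
    valid).  Does not raise on invariant violations — callers decide."""
    path = Path(file)
    chk = _Checker()
    try:
        doc = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        chk.error(str(path), f"unreadable: {exc}")
        return chk.issues
    if not isinstance(doc, dict):
        chk.error(str(path), "top level must be a mapping")
        return chk.issues
    k = _check_header(doc, kind, chk)
    if k in _VALIDATORS:
        _VALIDATORS[k](doc, chk)
    return chk.issues


def _v(doc):
    return doc["value"]


def _build_flowsheet(doc: dict) -> Flowsheet:
    ops = tuple(
        UnitOperation(
            name=op["name"],
            duration=_v(op["duration"]),
            volume_in=_v(op["volume_in"]),
            volume_out=_v(op["volume_out"]),
            step_yield=_v(op["step_yield"]),
            consumable_demands=tuple(
                (d["item"], _v(d["quantity"])) for d in op.get("consumable_demands", []) or []
            ),
            material_demands=tuple(
                (d["item"], _v(d["quantity"])) for d in op.get("material_demands", []) or []
            ),
        )
        for op in doc["operations"]
    )
    return Flowsheet(
        operations=ops,
        fermenter_working_volume=_v(doc["fermenter_working_volume"]),
        plant_available_days=_v(doc["plant_available_days"]),
        parallel_trains=doc["parallel_trains"],
    )


def _build_prices(doc: dict) -> PriceTable:
    return PriceTable(
        consumable_prices={i: _v(q) for i, q in doc["consumable_prices"].items()},
        material_prices={i: _v(q) for i, q in doc["material_prices"].items()},
        equipment_costs={i: _v(q) for i, q in doc["equipment_costs"].items()},
        amortization_years=_v(doc["amortization_years"]),
        facility_multiplier=_v(doc["facility_multiplier"]),
        qc_cost_per_batch=_v(doc["qc_cost_per_batch"]),
        other_overhead_rate=_v(doc["other_overhead_rate"]),
    )


def _build_parameters(doc: dict) -> ProcessParameters:
    return ProcessParameters(
        titer=_v(doc["titer"]),
        dsp_yield=_v(doc["dsp_yield"]),
        target_output=_v(doc["target_output"]),
        material_cost_deviation=_v(doc["material_cost_deviation"]),
    )


def _build_scenarios(doc: dict) -> ScenarioTable:
    order = doc.get("wage_order")
    return ScenarioTable(
        parameters={
            name: Scenario(_v(s["worst"]), _v(s["base"]), _v(s["best"]))
            for name, s in doc["parameters"].items()
        },
        wage_scenarios={
            loc: {role: _v(q) for role, q in table.items()}
            for loc, table in doc.get("wage_scenarios", {}).items()
        },
        wage_order=Scenario(**order) if order else None,
    )


def _build_mc(doc: dict) -> MCConfig:
    return MCConfig(
        distributions={
            name: TriangularDist(_v(d["min"]), _v(d["mode"]), _v(d["max"]))
            for name, d in doc["distributions"].items()
        },
        max_runs=doc["max_runs"],
        ma_window=doc["ma_window"],
        ma_tolerance=doc["ma_tolerance"],
        seed=doc["seed"],
    )


_BUILDERS = {
    "flowsheet": _build_flowsheet,
    "prices": _build_prices,
    "parameters": _build_parameters,
    "scenarios": _build_scenarios,
    "mc": _build_mc,
}


def load_config(file: str | Path, kind: str | None = None):
    """Validate and build the domain object for one config file."""
    issues = validate_config(file, kind)
    if issues:
        raise ConfigurationError(
            f"{file}: " + "; ".join(str(i) for i in issues)
        )
    doc = yaml.safe_load(Path(file).read_text())
    return _BUILDERS[doc["kind"]](doc)


@dataclass(frozen=True)
class FixtureSet:
    """The domain objects of a fixtures directory, plus the extra plumbing
    recorded in parameters.yaml (dominant items, labor share)."""

    flowsheet: Flowsheet
    prices: PriceTable
    parameters: ProcessParameters
    scenarios: ScenarioTable
    mc_before: MCConfig
    mc_after: MCConfig
    dominant_items: frozenset[str]
    labor_share: float
    wage_location: str


def load_fixture_set(directory: str | Path) -> FixtureSet:
    d = Path(directory)
    params_doc = yaml.safe_load((d / "parameters.yaml").read_text())
    return FixtureSet(
        flowsheet=load_config(d / "flowsheet.yaml", "flowsheet"),
        prices=load_config(d / "prices.yaml", "prices"),
        parameters=load_config(d / "parameters.yaml", "parameters"),
        scenarios=load_config(d / "scenarios.yaml", "scenarios"),
        mc_before=load_config(d / "mc_before.yaml", "mc"),
        mc_after=load_config(d / "mc_after.yaml", "mc"),
        dominant_items=frozenset(params_doc.get("dominant_items", [])),
        labor_share=params_doc.get("labor_share", {"value": 0.13})["value"],
        wage_location=params_doc.get("wage_location", "UK"),
    )
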