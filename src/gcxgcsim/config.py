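"""Configuration files: units, schema validation, YAML round-trip.

A run configuration declares the system graph (vertices, capillary edges
with dimensions/phase/temperature references), named temperature programs,
pressure programs, modulator settings, solver tolerances and reference
conditions. All quantities in the file carry explicit units; internally
everything is SI (m, s, Pa absolute, K). Gauge pressures (the usual GC
convention, e.g. "160.30 kPa(g)") are converted with an ambient pressure of
101.325 kPa; "vacuum" means 0 Pa absolute.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .flownet import (
    P_AMBIENT,
    CapillaryEdge,
    PressureProgram,
    SystemGraph,
    TemperatureProgram,
    Vertex,
)
from .migration import SolverOptions
from .modulator import ModulatorSettings
from .physchem import load_gas

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "config_dict",
    "parse_pressure",
    "parse_temperature",
    "parse_temperature_offset",
    "parse_length",
    "parse_time",
    "config_hash",
]


class ConfigError(ValueError):
    """Schema violation, naming the offending field and expected unit."""


_NUM = r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?"


def _split(value, kinds: str, field_name: str) -> tuple[float, str]:
    if isinstance(value, (int, float)):
        raise ConfigError(
            f"{field_name}: bare number {value!r}; declare a unit ({kinds})"
        )
    m = re.fullmatch(rf"\s*({_NUM})\s*([^\s]+)\s*", str(value))
    if not m:
        raise ConfigError(f"{field_name}: cannot parse {value!r}; expected '<number> <unit>' with unit in ({kinds})")
    return float(m.group(1)), m.group(2)


def parse_pressure(value, field_name: str = "pressure") -> float:
    """Pressure to Pa absolute. Units: Pa, kPa, kPa(g), Pa(g), bar, 'vacuum'."""
    if isinstance(value, str) and value.strip().lower() == "vacuum":
        return 0.0
    num, unit = _split(value, "Pa, kPa, kPa(g), bar, vacuum", field_name)
    scale = {"pa": 1.0, "kpa": 1e3, "bar": 1e5}
    gauge = unit.lower().endswith("(g)")
    base = unit.lower().removesuffix("(g)")
    if base not in scale:
        raise ConfigError(f"{field_name}: unknown pressure unit {unit!r}")
    p = num * scale[base] + (P_AMBIENT if gauge else 0.0)
    if p < 0:
        raise ConfigError(f"{field_name}: absolute pressure must be >= 0")
    return p


def parse_temperature(value, field_name: str = "temperature") -> float:
    """Temperature to K. Units: degC, K."""
    num, unit = _split(value, "degC, K", field_name)
    if unit in ("degC", "C", "°C"):
        return num + 273.15
    if unit == "K":
        return num
    raise ConfigError(f"{field_name}: unknown temperature unit {unit!r}")


def parse_temperature_offset(value, field_name: str = "offset") -> float:
    """Temperature interval to K (degC and K intervals coincide)."""
    num, unit = _split(value, "K, degC", field_name)
    if unit in ("K", "degC", "C", "°C"):
        return num
    raise ConfigError(f"{field_name}: unknown temperature-interval unit {unit!r}")


def parse_length(value, field_name: str = "length") -> float:
    """Length to m. Units: m, cm, mm, um/µm."""
    num, unit = _split(value, "m, cm, mm, um", field_name)
    scale = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6}
    if unit not in scale:
        raise ConfigError(f"{field_name}: unknown length unit {unit!r}")
    return num * scale[unit]


def parse_time(value, field_name: str = "time") -> float:
    """Time to s. Units: s, ms, min, h."""
    num, unit = _split(value, "s, ms, min, h", field_name)
    scale = {"s": 1.0, "ms": 1e-3, "min": 60.0, "h": 3600.0}
    if unit not in scale:
        raise ConfigError(f"{field_name}: unknown time unit {unit!r}")
    return num * scale[unit]


def _parse_ramp_rate(value, field_name: str) -> float:
    num, unit = _split(value, "degC/min, K/min", field_name)
    if unit in ("degC/min", "K/min", "C/min"):
        return num
    raise ConfigError(f"{field_name}: unknown ramp-rate unit {unit!r}")


@dataclass
class RunConfig:
    """Validated run configuration."""

    name: str
    system: SystemGraph
    solver: SolverOptions = field(default_factory=SolverOptions)
    solute_table: str | None = None
    output_dir: str = "."

    def modulator_edges(self) -> list[CapillaryEdge]:
        return [e for e in self.system.edges.values() if e.modulator is not None]

    def modulator_settings(self) -> ModulatorSettings:
        edges = self.modulator_edges()
        if not edges:
            raise ConfigError("system contains no thermal-modulator edge")
        return edges[0].modulator  # type: ignore[return-value]


def _build_temperature_program(name: str, block: dict) -> TemperatureProgram:
    if not isinstance(block, dict) or "initial" not in block:
        raise ConfigError(f"temperature_programs.{name}: need 'initial' and 'steps'")
    initial_K = parse_temperature(block["initial"], f"temperature_programs.{name}.initial")
    steps = []
    for i, step in enumerate(block.get("steps") or []):
        where = f"temperature_programs.{name}.steps[{i}]"
        if "hold" in step:
            steps.append(("hold", parse_time(step["hold"], f"{where}.hold")))
        elif "ramp" in step:
            if "to" not in step:
                raise ConfigError(f"{where}: ramp step needs 'to' target temperature")
            steps.append(
                (
                    "ramp",
                    _parse_ramp_rate(step["ramp"], f"{where}.ramp"),
                    parse_temperature(step["to"], f"{where}.to") - 273.15,
                )
            )
        else:
            raise ConfigError(f"{where}: step must contain 'hold' or 'ramp'")
    return TemperatureProgram.from_steps(initial_K - 273.15, steps)


def _build_pressure_program(value, field_name: str) -> PressureProgram:
    if isinstance(value, str):
        return PressureProgram.constant(parse_pressure(value, field_name))
    if isinstance(value, list):
        times, pressures = [], []
        for i, pair in enumerate(value):
            if not isinstance(pair, list) or len(pair) != 2:
                raise ConfigError(f"{field_name}[{i}]: expected [time, pressure] pair")
            times.append(parse_time(pair[0], f"{field_name}[{i}].time"))
            pressures.append(parse_pressure(pair[1], f"{field_name}[{i}].pressure"))
        return PressureProgram(times, pressures)
    raise ConfigError(f"{field_name}: expected pressure value or [time, pressure] list")


def _build_modulator(block: dict, field_name: str) -> ModulatorSettings:
    for key in ("period", "hot"):
        if key not in block:
            raise ConfigError(f"{field_name}: modulator block needs {key!r}")
    cold_mode = "offset"
    cold_value = -80.0
    if "cold_offset" in block:
        cold_value = parse_temperature_offset(block["cold_offset"], f"{field_name}.cold_offset")
    elif "cold" in block:
        cold_mode = "absolute"
        cold_value = parse_temperature(block["cold"], f"{field_name}.cold")
    return ModulatorSettings(
        period=parse_time(block["period"], f"{field_name}.period"),
        shift=parse_time(block.get("shift", "0 s"), f"{field_name}.shift"),
        hot_duration=parse_time(block["hot"], f"{field_name}.hot"),
        hot_offset=parse_temperature_offset(
            block.get("hot_offset", "25 K"), f"{field_name}.hot_offset"
        ),
        cold_value=cold_value,
        cold_mode=cold_mode,
    )


def config_from_dict(doc: dict, base_dir: Path | None = None) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    system = SystemGraph()
    system.gas = load_gas(doc.get("carrier_gas", "helium"))
    ref = doc.get("reference", {})
    if ref:
        system.T_ref = parse_temperature(ref.get("temperature", "25 degC"), "reference.temperature")
        system.p_ref = parse_pressure(ref.get("pressure", "101.325 kPa"), "reference.pressure")
    programs = doc.get("temperature_programs")
    if not programs:
        raise ConfigError("temperature_programs: at least one program is required")
    for name, block in programs.items():
        system.temperature_programs[name] = _build_temperature_program(name, block)
    for i, vblock in enumerate(doc.get("vertices") or []):
        if "id" not in vblock:
            raise ConfigError(f"vertices[{i}]: missing 'id'")
        pressure = None
        if "pressure" in vblock:
            pressure = _build_pressure_program(
                vblock["pressure"], f"vertices[{i}].pressure"
            )
        system.add_vertex(
            Vertex(id=str(vblock["id"]), pressure=pressure, role=vblock.get("role", "junction"))
        )
    for i, eblock in enumerate(doc.get("edges") or []):
        where = f"edges[{i}]"
        for key in ("id", "from", "to", "length", "diameter"):
            if key not in eblock:
                raise ConfigError(f"{where}: missing {key!r}")
        modulator = None
        if eblock.get("kind") == "thermal_modulator":
            if "modulator" not in eblock:
                raise ConfigError(
                    f"{where}: thermal_modulator edge {eblock['id']!r} needs a 'modulator' block"
                )
            modulator = _build_modulator(eblock["modulator"], f"{where}.modulator")
        system.add_edge(
            CapillaryEdge(
                id=str(eblock["id"]),
                source=str(eblock["from"]),
                target=str(eblock["to"]),
                length=parse_length(eblock["length"], f"{where}.length"),
                diameter=parse_length(eblock["diameter"], f"{where}.diameter"),
                film=parse_length(eblock.get("film", "0 m"), f"{where}.film"),
                phase=eblock.get("phase"),
                temperature=eblock.get("temperature", "oven"),
                modulator=modulator,
            )
        )
    system.validate()
    solver_block = doc.get("solver") or {}
    solver = SolverOptions(
        rtol=float(solver_block.get("rtol", 1e-8)),
        atol_time=float(solver_block.get("atol_time", 1e-10)),
        atol_var=float(solver_block.get("atol_var", 1e-10)),
    )
    solute_table = doc.get("solutes")
    if solute_table and base_dir is not None and not Path(solute_table).is_absolute():
        solute_table = str(base_dir / solute_table)
    return RunConfig(
        name=str(doc.get("name", "unnamed")),
        system=system,
        solver=solver,
        solute_table=solute_table,
        output_dir=str(doc.get("output_dir", ".")),
    )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc, base_dir=path.parent)


def config_dict(config: RunConfig) -> dict:
    """Canonical dict representation (SI units, stable ordering)."""
    system = config.system
    doc: dict = {
        "name": config.name,
        "carrier_gas": system.gas.name,
        "reference": {
            "temperature": f"{system.T_ref:.6g} K",
            "pressure": f"{system.p_ref:.6g} Pa",
        },
        "temperature_programs": {},
        "vertices": [],
        "edges": [],
        "solver": {
            "rtol": config.solver.rtol,
            "atol_time": config.solver.atol_time,
            "atol_var": config.solver.atol_var,
        },
    }
    for name, prog in system.temperature_programs.items():
        steps = []
        for i in range(1, len(prog.times)):
            dt = prog.times[i] - prog.times[i - 1]
            dT = prog.temps[i] - prog.temps[i - 1]
            if dT == 0:
                steps.append({"hold": f"{dt:.9g} s"})
            else:
                steps.append(
                    {
                        "ramp": f"{abs(dT) / dt * 60.0:.9g} degC/min",
                        "to": f"{prog.temps[i] - 273.15:.9g} degC",
                    }
                )
        doc["temperature_programs"][name] = {
            "initial": f"{prog.temps[0] - 273.15:.9g} degC",
            "steps": steps,
        }
    for v in system.vertices.values():
        block: dict = {"id": v.id, "role": v.role}
        if v.pressure is not None:
            block["pressure"] = [
                [f"{t:.9g} s", f"{p:.9g} Pa"]
                for t, p in zip(v.pressure.times, v.pressure.values)
            ]
        doc["vertices"].append(block)
    for e in system.edges.values():
        block = {
            "id": e.id,
            "from": e.source,
            "to": e.target,
            "length": f"{e.length:.9g} m",
            "diameter": f"{e.diameter:.9g} m",
            "film": f"{e.film:.9g} m",
            "temperature": e.temperature,
        }
        if e.phase:
            block["phase"] = e.phase
        if e.modulator is not None:
            m: ModulatorSettings = e.modulator
            block["kind"] = "thermal_modulator"
            mod_block = {
                "period": f"{m.period:.9g} s",
                "shift": f"{m.shift:.9g} s",
                "hot": f"{m.hot_duration:.9g} s",
                "hot_offset": f"{m.hot_offset:.9g} K",
            }
            if m.cold_mode == "offset":
                mod_block["cold_offset"] = f"{m.cold_value:.9g} K"
            else:
                mod_block["cold"] = f"{m.cold_value:.9g} K"
            block["modulator"] = mod_block
        doc["edges"].append(block)
    if config.solute_table:
        doc["solutes"] = config.solute_table
    return doc


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict(config), fh, sort_keys=False)


def apply_modulator_patch(config: RunConfig, patch: dict) -> RunConfig:
    """Apply a correction patch (as emitted by the diagnostics) in place.

    The patch carries a ``modulator`` block with unit-tagged ``period``
    and ``shift``; every thermal-modulator edge of the system is updated.
    """
    block = patch.get("modulator")
    if not isinstance(block, dict):
        raise ConfigError("patch: expected a 'modulator' mapping")
    for edge in config.modulator_edges():
        old: ModulatorSettings = edge.modulator  # type: ignore[assignment]
        edge.modulator = ModulatorSettings(
            period=parse_time(block.get("period", f"{old.period} s"), "patch.modulator.period"),
            shift=parse_time(block.get("shift", f"{old.shift} s"), "patch.modulator.shift"),
            hot_duration=old.hot_duration,
            hot_offset=old.hot_offset,
            cold_value=old.cold_value,
            cold_mode=old.cold_mode,
        )
    return config


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical configuration (for output headers)."""
    blob = yaml.safe_dump(config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
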