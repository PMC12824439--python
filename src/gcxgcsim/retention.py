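"""Thermodynamic retention: the K-centric three-parameter model.

The retention factor of a solute on a stationary phase is parameterized by
the characteristic temperature ``Tchar`` (where k = 1 at the reference phase
ratio), the characteristic slope constant ``thetachar`` (a temperature
interval, so degC and K magnitudes coincide) and the heat-capacity change
``DeltaCp`` of the transfer between phases:

    ln k = ln(phi / phi_ref)
         + (DeltaCp/R + Tchar/thetachar) * (Tchar/T - 1)
         + (DeltaCp/R) * ln(T / Tchar)

``phi = df/d`` is the film-to-diameter ratio of the *local* column and
``phi_ref`` the ratio of the system the parameters were estimated on; k
scales proportionally with phi. Parameters are carried per stationary phase;
a solute without parameters for an (explicitly uncoated) phase migrates with
k = 0.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .physchem import TransportProps

__all__ = [
    "R_GAS",
    "PhaseEntry",
    "SoluteRecord",
    "normalize_phase",
    "retention_factor",
    "retention_factor_modulator",
    "read_solute_table",
    "write_solute_table",
]

R_GAS = 8.31446261815324  # J/(mol K)


def normalize_phase(name: str | None) -> str:
    """Canonical phase key: case and punctuation insensitive ('ZB-1ms' == 'ZB1ms')."""
    if name is None:
        return ""
    return re.sub(r"[^0-9a-z]", "", name.lower())


@dataclass(frozen=True)
class PhaseEntry:
    """K-centric parameters of one solute on one stationary phase."""

    Tchar: float  # K
    thetachar: float  # temperature interval (degC-sized units)
    DeltaCp: float  # J/(mol K)
    phi_ref: float  # df/d ratio of the calibration system

    def __post_init__(self) -> None:
        if self.Tchar <= 0 or self.thetachar <= 0 or self.phi_ref <= 0:
            raise ValueError("Tchar, thetachar and phi_ref must be positive")


@dataclass
class SoluteRecord:
    """Solute identity, per-phase retention parameters, transport properties.

    CAS is an identifier only; no registry lookups happen.
    """

    name: str
    cas: str = ""
    phases: dict[str, PhaseEntry] = field(default_factory=dict)
    transport: TransportProps = field(default_factory=lambda: TransportProps(200.0))

    def phase_entry(self, phase: str | None) -> PhaseEntry | None:
        return self.phases.get(normalize_phase(phase))

    def add_phase(self, phase: str, entry: PhaseEntry) -> None:
        self.phases[normalize_phase(phase)] = entry


def retention_factor(
    solute: SoluteRecord, phase: str | None, T: float, phi: float
) -> float:
    """Retention factor k of the solute at temperature T on this column.

    Parameters
    ----------
    phase:
        Stationary-phase name of the local column. ``None`` or '' means an
        explicitly uncoated segment (k = 0). A coated phase for which the
        solute carries no parameters yields k = 0 with a warning.
    T:
        Absolute temperature, K.
    phi:
        Film-to-diameter ratio df/d of the local column.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    key = normalize_phase(phase)
    if key == "":
        return 0.0
    if phi <= 0:
        raise ValueError("phase ratio phi must be positive on a coated column")
    entry = solute.phases.get(key)
    if entry is None:
        warnings.warn(
            f"solute {solute.name!r} has no retention parameters for phase "
            f"{phase!r}; assuming k = 0",
            stacklevel=2,
        )
        return 0.0
    lnk = (
        math.log(phi / entry.phi_ref)
        + (entry.DeltaCp / R_GAS + entry.Tchar / entry.thetachar)
        * (entry.Tchar / T - 1.0)
        + (entry.DeltaCp / R_GAS) * math.log(T / entry.Tchar)
    )
    return math.exp(lnk)


def retention_factor_modulator(
    solute: SoluteRecord,
    phase: str | None,
    T_oven: float,
    Thot_offset: float,
    phi: float,
) -> float:
    """k at the modulator hot-jet temperature: oven temperature + offset."""
    return retention_factor(solute, phase, T_oven + Thot_offset, phi)


_COLUMNS = [
    "Name",
    "CAS",
    "Phase",
    "Tchar",
    "thetachar",
    "DeltaCp",
    "phi_ref",
    "MolarMass",
    "DiffusionVolume",
]


def read_solute_table(path: str | Path | io.TextIOBase) -> list[SoluteRecord]:
    """Read a delimited solute table (one row per solute-phase pair).

    Columns: Name, CAS, Phase, Tchar [K], thetachar, DeltaCp [J/(mol K)],
    phi_ref, and optionally MolarMass [g/mol], DiffusionVolume. Comma and
    semicolon dialects are both accepted; '#' lines are comments.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in _COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"solute table missing required columns: {missing}")
    records: dict[str, SoluteRecord] = {}
    for _, row in df.iterrows():
        name = str(row["Name"]).strip()
        if name not in records:
            molar_mass = float(row["MolarMass"]) if "MolarMass" in df.columns and pd.notna(row.get("MolarMass")) else 200.0
            dvol = (
                float(row["DiffusionVolume"])
                if "DiffusionVolume" in df.columns and pd.notna(row.get("DiffusionVolume"))
                else None
            )
            records[name] = SoluteRecord(
                name=name,
                cas=str(row["CAS"]).strip() if pd.notna(row.get("CAS")) else "",
                transport=TransportProps(molar_mass, dvol),
            )
        records[name].add_phase(
            str(row["Phase"]),
            PhaseEntry(
                Tchar=float(row["Tchar"]),
                thetachar=float(row["thetachar"]),
                DeltaCp=float(row["DeltaCp"]),
                phi_ref=float(row["phi_ref"]),
            ),
        )
    return list(records.values())


def write_solute_table(solutes: list[SoluteRecord], path: str | Path) -> None:
    rows = []
    for s in solutes:
        for phase, entry in s.phases.items():
            rows.append(
                {
                    "Name": s.name,
                    "CAS": s.cas,
                    "Phase": phase,
                    "Tchar": entry.Tchar,
                    "thetachar": entry.thetachar,
                    "DeltaCp": entry.DeltaCp,
                    "phi_ref": entry.phi_ref,
                    "MolarMass": s.transport.molar_mass,
                    "DiffusionVolume": s.transport.diffusion_volume,
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
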