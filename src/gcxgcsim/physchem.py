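"""Carrier-gas transport properties.

Temperature-dependent viscosity of the mobile phase and binary diffusion
coefficients of solutes in the carrier gas. Both feed the flow-network and
band-broadening calculations: viscosity sets the pneumatic restriction of
every capillary, the diffusion coefficient sets the longitudinal and
resistance-to-mass-transfer terms of the Golay plate-height equation.

Viscosity follows the power law

    eta(T) = eta_ref * (T / T_ref) ** (xi0 + xi1 * (T - T_ref) / T_ref)

with gas-specific coefficients stored in a small delimited table
(``data/carrier_gases.csv``) so they can be recalibrated without touching
code. Diffusion coefficients use the Fuller-Schettler-Giddings (FSG)
correlation with atomic diffusion-volume increments.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "CarrierGas",
    "TransportProps",
    "load_gas",
    "viscosity",
    "diffusion_coefficient",
    "diffusion_volume_from_molar_mass",
]

#: Valid temperature envelope for the viscosity power law, K.
T_MIN = 200.0
T_MAX = 700.0

# FSG atomic increments (dimensionless diffusion volumes).
FSG_CARBON = 15.9
FSG_HYDROGEN = 2.31
FSG_OXYGEN = 6.11


@dataclass(frozen=True)
class CarrierGas:
    """Mobile-phase gas with its viscosity power-law coefficients.

    ``viscosity_ref`` is eta at ``T_ref`` in Pa*s; ``xi0``/``xi1`` are the
    exponent parameters (``xi1 = 0`` gives a plain power law).
    """

    name: str
    viscosity_ref: float
    T_ref: float
    xi0: float
    xi1: float = 0.0
    molar_mass: float = 4.0026
    diffusion_volume: float = 2.67

    def __post_init__(self) -> None:
        if self.viscosity_ref <= 0:
            raise ValueError("viscosity_ref must be positive")
        if self.T_ref <= 0:
            raise ValueError("T_ref must be positive")


@dataclass(frozen=True)
class TransportProps:
    """Solute-side inputs of the FSG diffusion estimate.

    diffusion_volume defaults to a generic saturated-hydrocarbon estimate
    derived from the molar mass (see diffusion_volume_from_molar_mass).
    """

    molar_mass: float
    diffusion_volume: float | None = None

    def __post_init__(self) -> None:
        if not self.molar_mass or self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")


def _gas_table(path: str | Path | None = None) -> dict[str, CarrierGas]:
    if path is None:
        source = resources.files("gcxgcsim.data").joinpath("carrier_gases.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, CarrierGas] = {}
    for row in csv.DictReader(text.splitlines()):
        table[row["name"].strip().lower()] = CarrierGas(
            name=row["name"].strip().lower(),
            viscosity_ref=float(row["viscosity_ref_Pas"]),
            T_ref=float(row["T_ref_K"]),
            xi0=float(row["xi0"]),
            xi1=float(row["xi1"]),
            molar_mass=float(row["molar_mass_gmol"]),
            diffusion_volume=float(row["diffusion_volume"]),
        )
    return table


def load_gas(name: str, table_path: str | Path | None = None) -> CarrierGas:
    """Look up a carrier gas in the bundled (or overridden) property table."""
    table = _gas_table(table_path)
    key = name.strip().lower()
    if key not in table:
        raise KeyError(
            f"unknown carrier gas {name!r}; known: {sorted(table)}"
        )
    return table[key]


def viscosity(gas: CarrierGas, T: float) -> float:
    """Dynamic viscosity eta(T) in Pa*s.

    Parameters
    ----------
    gas:
        Carrier gas with power-law coefficients.
    T:
        Temperature in K; must lie in the calibrated 200-700 K envelope.
    """
    if not T_MIN <= T <= T_MAX:
        raise ValueError(
            f"temperature {T} K outside viscosity model range "
            f"[{T_MIN}, {T_MAX}] K"
        )
    tr = T / gas.T_ref
    return gas.viscosity_ref * tr ** (gas.xi0 + gas.xi1 * (tr - 1.0))


def diffusion_volume_from_molar_mass(molar_mass: float) -> float:
    """Generic hydrocarbon FSG diffusion volume for a solute of given mass.

    Treats the solute as the n-alkane C_n H_{2n+2} with the same molar mass
    (n from M = 14.027 n + 2.016, clipped at n >= 1) and sums the FSG atomic
    increments. Adequate when no structure-specific value is supplied.
    """
    n = max((molar_mass - 2.016) / 14.027, 1.0)
    return n * FSG_CARBON + (2.0 * n + 2.0) * FSG_HYDROGEN


def diffusion_coefficient(
    solute: TransportProps, gas: CarrierGas, T: float, p: float
) -> float:
    """Binary diffusion coefficient of the solute in the carrier gas, m^2/s.

    Fuller-Schettler-Giddings correlation::

        D = 1e-3 * T^1.75 * sqrt(1/M_A + 1/M_B)
            / (p_atm * (V_A^(1/3) + V_B^(1/3))^2)   [cm^2/s]

    with molar masses in g/mol, pressure in atm and atomic diffusion
    volumes V. Scales as T^1.75 / p.
    """
    if T <= 0 or p <= 0:
        raise ValueError("temperature and pressure must be positive")
    v_solute = solute.diffusion_volume
    if v_solute is None:
        v_solute = diffusion_volume_from_molar_mass(solute.molar_mass)
    p_atm = p / 101325.0
    d_cm2 = (
        1.0e-3
        * T**1.75
        * math.sqrt(1.0 / solute.molar_mass + 1.0 / gas.molar_mass)
        / (p_atm * (v_solute ** (1.0 / 3.0) + gas.diffusion_volume ** (1.0 / 3.0)) ** 2)
    )
    return d_cm2 * 1.0e-4
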