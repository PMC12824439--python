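"""Band migration and broadening through capillary modules.

A solute band is tracked module by module as a Gaussian in time with center
``t`` and temporal variance ``tau^2``. Within one module the band obeys, with
position x as the independent variable,

    dt/dx     = r(x, t)                      residency, r = (1 + k) / u_M
    dtau^2/dx = H(x, t) r^2 + 2 tau^2 dr/dt

where k is the local retention factor, u_M the local mobile-phase velocity
from the flow network, and H the Golay plate height for open tubular
columns. The second variance term captures peak compression/stretching when
the residency changes while the band passes (temperature programming); dr/dt
is evaluated by central finite difference. The exit state of one module is
the entry state of the next; thermal modulators instead fan a band out into
slices (see `gcxgcsim.modulator`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .flownet import CapillaryEdge, FlowField, SystemGraph
from .physchem import diffusion_coefficient, diffusion_volume_from_molar_mass, TransportProps
from .retention import SoluteRecord, normalize_phase

__all__ = [
    "PeakState",
    "ModuleResult",
    "SolverOptions",
    "golay_plate_height",
    "plate_height",
    "migrate",
    "simulate_path",
    "PathResult",
]


@dataclass
class PeakState:
    """A solute band at a module boundary: center time, variance, area."""

    t: float
    tau2: float = 0.0
    area: float = 1.0

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.area < 0 or not math.isfinite(self.t):
            raise ValueError("invalid peak state")

    @property
    def tau(self) -> float:
        return math.sqrt(self.tau2)


@dataclass
class ModuleResult:
    """Outcome of migrating one band through one module."""

    exit_state: PeakState
    eluted: bool
    elution_temperature: float
    trajectory_x: np.ndarray = dataclass_field(default_factory=lambda: np.empty(0))
    trajectory_t: np.ndarray = dataclass_field(default_factory=lambda: np.empty(0))
    trajectory_tau2: np.ndarray = dataclass_field(default_factory=lambda: np.empty(0))


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive Runge-Kutta settings for the migration ODEs.

    x is the independent variable. ``dt_fd`` is the central-difference step
    for dr/dt in seconds; ``ds_ratio`` sets the stationary-phase diffusion
    coefficient as D_S = D_M / ds_ratio (negligible film term for thin
    films).
    """

    rtol: float = 1e-8
    atol_time: float = 1e-10
    atol_var: float = 1e-10
    dt_fd: float = 1e-3
    ds_ratio: float = 5e4
    max_step_fraction: float = 0.1


DEFAULT_SOLVER = SolverOptions()


def golay_plate_height(
    k: float, u: float, d: float, df: float, DM: float, DS: float
) -> float:
    """Golay plate height for an open tubular column, m.

    H = 2 DM/u + (1 + 6k + 11k^2)/(96 (1+k)^2) d^2 u / DM
        + (2/3) k/(1+k)^2 df^2 u / DS
    """
    one_k = 1.0 + k
    h = 2.0 * DM / u
    h += (1.0 + 6.0 * k + 11.0 * k * k) / (96.0 * one_k * one_k) * d * d * u / DM
    if df > 0.0 and k > 0.0:
        h += (2.0 / 3.0) * k / (one_k * one_k) * df * df * u / DS
    return h


def _retention_closure(
    edge: CapillaryEdge, solute: SoluteRecord
) -> Callable[[float], float]:
    """Fast per-edge ln-k evaluator (resolves the phase entry once)."""
    entry = solute.phase_entry(edge.phase) if edge.phase else None
    if entry is None or edge.film <= 0:
        return lambda T: 0.0
    from .retention import R_GAS

    a = math.log(edge.phi / entry.phi_ref)
    b = entry.DeltaCp / R_GAS + entry.Tchar / entry.thetachar
    c = entry.DeltaCp / R_GAS
    Tchar = entry.Tchar
    exp, log = math.exp, math.log

    def k_of_T(T: float) -> float:
        return exp(a + b * (Tchar / T - 1.0) + c * log(T / Tchar))

    return k_of_T


def plate_height(
    graph: SystemGraph,
    field: FlowField,
    edge: CapillaryEdge,
    solute: SoluteRecord,
    x: float,
    t: float,
    options: SolverOptions = DEFAULT_SOLVER,
) -> float:
    """Local Golay plate height of a solute inside an edge at (x, t)."""
    program = graph.edge_temperature(edge)
    pin2, pout2, F = field.edge_state(edge.id, t)
    frac = x / edge.length if edge.length else 0.0
    p = math.sqrt(max(pin2 - (pin2 - pout2) * frac, pin2 * 1e-12))
    T = program(t, x)
    area = math.pi * edge.diameter**2 / 4.0
    u = F * (graph.p_ref / p) * (T / graph.T_ref) / area
    k = _retention_closure(edge, solute)(T)
    DM = diffusion_coefficient(solute.transport, graph.gas, T, p)
    return golay_plate_height(k, u, edge.diameter, edge.film, DM, DM / options.ds_ratio)


def migrate(
    graph: SystemGraph,
    field: FlowField,
    edge: CapillaryEdge,
    entry: PeakState,
    solute: SoluteRecord,
    options: SolverOptions = DEFAULT_SOLVER,
    horizon: float | None = None,
    temperature_override: Callable[[float, float], float] | None = None,
    store_trajectory: bool = False,
) -> ModuleResult:
    """Propagate one band through one column module.

    ``temperature_override(t, x)`` replaces the edge's registered program
    (used e.g. to drive the rectangular modulator temperature in brute-force
    checks). A band still on the column at ``horizon`` is returned flagged
    as not eluted (censored), with the state frozen where integration
    stopped.
    """
    if edge.length == 0.0:
        return ModuleResult(
            exit_state=PeakState(entry.t, entry.tau2, entry.area),
            eluted=True,
            elution_temperature=graph.edge_temperature(edge)(entry.t),
        )
    program = graph.edge_temperature(edge)
    if temperature_override is None:
        T_of = program
    else:
        T_of = lambda t, x=0.0: temperature_override(t, x)  # noqa: E731
    if horizon is None:
        horizon = max(program.duration, entry.t) + 3600.0
    if entry.t >= horizon:
        return ModuleResult(
            exit_state=PeakState(entry.t, entry.tau2, entry.area),
            eluted=False,
            elution_temperature=T_of(entry.t, 0.0),
        )

    L = edge.length
    d = edge.diameter
    df = edge.film
    area_cs = math.pi * d * d / 4.0
    p_ref, T_ref = graph.p_ref, graph.T_ref
    k_of_T = _retention_closure(edge, solute)
    transport = solute.transport
    gas = graph.gas
    edge_id = edge.id
    edge_state = field.edge_state
    sqrt = math.sqrt
    ds_ratio = options.ds_ratio
    dt_fd = options.dt_fd

    # FSG constant parts: D = fsg_c * T^1.75 / p
    v_solute = transport.diffusion_volume
    if v_solute is None:
        v_solute = diffusion_volume_from_molar_mass(transport.molar_mass)
    fsg_c = (
        1.0e-3
        * sqrt(1.0 / transport.molar_mass + 1.0 / gas.molar_mass)
        / ((v_solute ** (1 / 3) + gas.diffusion_volume ** (1 / 3)) ** 2)
        * 101325.0
        * 1.0e-4
    )

    def residency(x: float, t: float) -> tuple[float, float, float, float]:
        """(r, k, u, p) at position x, time t."""
        pin2, pout2, F = edge_state(edge_id, t)
        p2 = pin2 - (pin2 - pout2) * (x / L)
        if p2 <= 0.0:
            # only reachable at the outlet boundary of a vacuum-terminated
            # edge, where u diverges and the residency vanishes; clamp
            if pout2 <= pin2 * 1e-12:
                p2 = pin2 * 1e-12
            else:
                raise FloatingPointError(
                    f"zero pressure inside edge {edge_id} at x={x:.4f} m"
                )
        p = sqrt(p2)
        if F <= 0.0:
            raise FloatingPointError(
                f"no forward flow in edge {edge_id} at t={t:.3f}s"
            )
        T = T_of(t, x)
        u = F * (p_ref / p) * (T / T_ref) / area_cs
        k = k_of_T(T)
        return (1.0 + k) / u, k, u, p

    def rhs(x: float, y: Sequence[float]) -> list[float]:
        t, tau2 = y[0], y[1]
        r, k, u, p = residency(x, t)
        T = T_of(t, x)
        DM = fsg_c * T**1.75 / p
        H = golay_plate_height(k, u, d, df, DM, DM / ds_ratio)
        r_plus, _, _, _ = residency(x, t + dt_fd)
        r_minus, _, _, _ = residency(x, t - dt_fd)
        drdt = (r_plus - r_minus) / (2.0 * dt_fd)
        return [r, H * r * r + 2.0 * max(tau2, 0.0) * drdt]

    def horizon_event(x: float, y: Sequence[float]) -> float:
        return y[0] - horizon

    horizon_event.terminal = True  # type: ignore[attr-defined]
    horizon_event.direction = 1.0  # type: ignore[attr-defined]

    sol = solve_ivp(
        rhs,
        (0.0, L),
        [entry.t, entry.tau2],
        method="RK45",
        rtol=options.rtol,
        atol=[options.atol_time, options.atol_var],
        events=horizon_event,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"migration solver failed in edge {edge_id}: {sol.message}")
    eluted = sol.t[-1] >= L and not (sol.t_events and len(sol.t_events[0]) > 0)
    t_exit = float(sol.y[0, -1])
    tau2_exit = float(max(sol.y[1, -1], 0.0))
    result = ModuleResult(
        exit_state=PeakState(t=t_exit, tau2=tau2_exit, area=entry.area),
        eluted=bool(eluted),
        elution_temperature=T_of(t_exit, L),
    )
    if store_trajectory:
        result.trajectory_x = sol.t.copy()
        result.trajectory_t = sol.y[0].copy()
        result.trajectory_tau2 = sol.y[1].copy()
    return result


@dataclass
class PathResult:
    """Per-solute outcome of a full path simulation."""

    solute: str
    slices: list  # list[modulator.Slice] with final detector states
    censored: bool
    first_dimension_result: ModuleResult | None = None


def simulate_path(
    graph: SystemGraph,
    path: Sequence[CapillaryEdge],
    solutes: Sequence[SoluteRecord],
    injection: PeakState | None = None,
    field: FlowField | None = None,
    horizon: float | None = None,
    options: SolverOptions = DEFAULT_SOLVER,
    slice_eps: float = 1e-4,
) -> list[PathResult]:
    """Chain migrate/modulator steps module by module along a path.

    Thermal-modulator edges fan each arriving band into slices, which are
    propagated independently downstream (no recombination; the projection
    step folds them back into 2D peaks). Bands/slices that do not elute
    within the horizon (oven program duration incl. final hold by default)
    are reported as censored/dropped.
    """
    from . import modulator as tm  # local import: modulator uses PeakState

    if injection is None:
        injection = PeakState(t=0.0, tau2=0.0, area=1.0)
    oven = graph.temperature_programs.get("oven")
    if horizon is None:
        if oven is None:
            raise ValueError("horizon required when no 'oven' program is registered")
        horizon = oven.duration
    if field is None:
        field = FlowField(graph, t_end=horizon * 1.05 + 60.0)

    results: list[PathResult] = []
    for solute in solutes:
        bands: list[tuple[PeakState, tm.Slice | None]] = [
            (PeakState(injection.t, injection.tau2, injection.area), None)
        ]
        censored = False
        first_dim: ModuleResult | None = None
        for edge in path:
            if not bands:
                break
            if edge.modulator is not None:
                settings: tm.ModulatorSettings = edge.modulator
                new_bands: list[tuple[PeakState, tm.Slice | None]] = []
                for state, _prov in bands:
                    for sl in tm.slice_band(
                        settings, state, solute_name=solute.name, eps=slice_eps
                    ):
                        released = tm.release(
                            settings, sl, graph, field, edge, solute
                        )
                        new_bands.append((released, sl))
                bands = new_bands
            else:
                new_bands = []
                for state, prov in bands:
                    res = migrate(
                        graph, field, edge, state, solute,
                        options=options, horizon=horizon,
                    )
                    if first_dim is None and edge is path[0]:
                        first_dim = res
                    if res.eluted:
                        new_bands.append((res.exit_state, prov))
                    else:
                        censored = True
                bands = new_bands
        slices = []
        for state, prov in bands:
            if prov is not None:
                prov.state = state
                slices.append(prov)
            else:
                # no modulator on the path: synthesize a single pseudo-slice
                slices.append(
                    tm.Slice(
                        solute=solute.name,
                        cycle=0,
                        window=(0.0, math.inf),
                        fraction=1.0,
                        release_time=injection.t,
                        state=state,
                    )
                )
        results.append(
            PathResult(
                solute=solute.name,
                slices=slices,
                censored=censored or not slices,
                first_dimension_result=first_dim,
            )
        )
    return results
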