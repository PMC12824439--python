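"""Capillary flow network: graph abstraction and pressure/flow solution.

A GC system is a directed graph whose vertices are pressure points
(injector, junctions between capillary segments, detector) and whose edges
are capillary modules. For ideal-gas laminar (Hagen-Poiseuille) flow the
molar balance at every junction is linear in the *squared* absolute
pressures, so the whole network is solved with one linear system per time
point, however the segments are arranged.

Per edge, the normalized volumetric flow (reported at reference conditions
``T_n``, ``p_n``, by default 25 degC and 101.325 kPa) is

    F = (pi / 256) * (T_n / p_n) * (p_in^2 - p_out^2) / kappa

with the pneumatic restriction ``kappa = integral eta(T(x,t)) T(x,t) / d^4 dx``
(= ``eta * T * L / d^4`` for a spatially uniform temperature). Pressures are
handled as absolute Pa; a vacuum outlet (mass-spectrometer interface) is
0 Pa absolute. Time dependence is quasi-steady: the static network is solved
at each requested time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.integrate import quad

from .physchem import CarrierGas, load_gas, viscosity

__all__ = [
    "TemperatureProgram",
    "PressureProgram",
    "Vertex",
    "CapillaryEdge",
    "SystemGraph",
    "FlowSolution",
    "StructuralError",
    "flow_restriction",
    "solve_pressures",
    "pressure_profile",
    "local_velocity",
    "holdup_time",
    "path_holdup_time",
    "FlowField",
]

P_AMBIENT = 101325.0  # Pa, used to convert gauge pressures


class StructuralError(ValueError):
    """The system graph cannot be solved as specified."""


class TemperatureProgram:
    """Piecewise-linear oven (or zone) temperature program T(t).

    Built either directly from breakpoints or from the usual
    plateau/ramp description (initial temperature, holds, ramp rates).
    Temperatures are stored in K; evaluation is constant outside the
    programmed span. An optional ``spatial`` hook ``f(x, t, T)`` may
    superimpose a position-dependent offset (no gradient models ship).
    """

    def __init__(
        self,
        times: Sequence[float],
        temps_K: Sequence[float],
        spatial: Callable[[float, float, float], float] | None = None,
    ) -> None:
        self.times = np.asarray(times, dtype=float)
        self.temps = np.asarray(temps_K, dtype=float)
        if self.times.size != self.temps.size or self.times.size == 0:
            raise ValueError("times and temperatures must have equal nonzero length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("breakpoint times must be non-decreasing")
        self.spatial = spatial

    @classmethod
    def isothermal(cls, T_K: float) -> "TemperatureProgram":
        return cls([0.0], [T_K])

    @classmethod
    def from_steps(
        cls, initial_C: float, steps: Iterable[tuple] = ()
    ) -> "TemperatureProgram":
        """Build from ('hold', duration_s) / ('ramp', rate_C_per_min, target_C)."""
        t, T = 0.0, initial_C + 273.15
        times, temps = [t], [T]
        for step in steps:
            kind = step[0]
            if kind == "hold":
                t += float(step[1])
            elif kind == "ramp":
                rate, target = float(step[1]) / 60.0, float(step[2]) + 273.15
                if rate <= 0:
                    raise ValueError("ramp rate must be positive")
                t += abs(target - T) / rate
                T = target
            else:
                raise ValueError(f"unknown program step {kind!r}")
            times.append(t)
            temps.append(T)
        return cls(times, temps)

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def __call__(self, t: float, x: float = 0.0) -> float:
        T = float(np.interp(t, self.times, self.temps))
        if self.spatial is not None:
            T = self.spatial(x, t, T)
        return T


class PressureProgram:
    """Piecewise-linear absolute pressure p(t) in Pa (vacuum = 0)."""

    def __init__(self, times: Sequence[float], values_Pa: Sequence[float]) -> None:
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values_Pa, dtype=float)
        if self.times.size != self.values.size or self.times.size == 0:
            raise ValueError("times and values must have equal nonzero length")
        if np.any(self.values < 0):
            raise ValueError("absolute pressures must be non-negative")

    @classmethod
    def constant(cls, p_Pa: float) -> "PressureProgram":
        return cls([0.0], [p_Pa])

    @classmethod
    def vacuum(cls) -> "PressureProgram":
        return cls.constant(0.0)

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))


@dataclass
class Vertex:
    """Pressure point of the network.

    ``pressure`` is a fixed program for inlets/outlets and ``None`` for
    junctions whose pressure the solver determines.
    """

    id: str
    pressure: PressureProgram | None = None
    role: str = "junction"  # inlet | outlet | junction


@dataclass
class CapillaryEdge:
    """Capillary module: a column segment or a thermal-modulator segment.

    Dimensions in m. ``temperature`` names a program registered on the
    SystemGraph. ``modulator`` carries ModulatorSettings for thermal
    modulator segments (the flow solver uses the base temperature program
    for those; the sub-millisecond hot jet perturbs the total restriction
    negligibly).
    """

    id: str
    source: str
    target: str
    length: float
    diameter: float
    film: float = 0.0
    phase: str | None = None
    temperature: str = "oven"
    modulator: object | None = None
    nominal_flow: float | None = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"edge {self.id}: length must be >= 0")
        if self.diameter <= 0:
            raise ValueError(f"edge {self.id}: diameter must be positive")
        if not 0 <= self.film < self.diameter / 2:
            raise ValueError(f"edge {self.id}: film thickness must satisfy 0 <= df << d")

    @property
    def phi(self) -> float:
        """Film-to-diameter ratio df/d of this column (phase-ratio proxy)."""
        return self.film / self.diameter


@dataclass
class SystemGraph:
    """The simulated instrument: vertices, capillary edges, programs, gas."""

    vertices: dict[str, Vertex] = field(default_factory=dict)
    edges: dict[str, CapillaryEdge] = field(default_factory=dict)
    temperature_programs: dict[str, TemperatureProgram] = field(default_factory=dict)
    gas: CarrierGas = field(default_factory=lambda: load_gas("helium"))
    T_ref: float = 298.15  # reference conditions for reported flows
    p_ref: float = 101325.0

    def add_vertex(self, vertex: Vertex) -> None:
        self.vertices[vertex.id] = vertex

    def add_edge(self, edge: CapillaryEdge) -> None:
        for v in (edge.source, edge.target):
            if v not in self.vertices:
                raise StructuralError(f"edge {edge.id} references unknown vertex {v!r}")
        self.edges[edge.id] = edge

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in self.vertices.values():
            g.add_node(v.id, vertex=v)
        for e in self.edges.values():
            g.add_edge(e.source, e.target, edge=e)
        return g

    def edge_temperature(self, edge: CapillaryEdge) -> TemperatureProgram:
        try:
            return self.temperature_programs[edge.temperature]
        except KeyError:
            raise StructuralError(
                f"edge {edge.id} references unknown temperature program "
                f"{edge.temperature!r}"
            ) from None

    def inlets(self) -> list[str]:
        g = self.to_networkx()
        return [v for v in g.nodes if g.in_degree(v) == 0]

    def outlets(self) -> list[str]:
        g = self.to_networkx()
        return [v for v in g.nodes if g.out_degree(v) == 0]

    def validate(self) -> None:
        g = self.to_networkx()
        if not self.edges:
            raise StructuralError("system has no capillary edges")
        if not nx.is_weakly_connected(g):
            raise StructuralError("system graph is not connected")
        inlets, outlets = self.inlets(), self.outlets()
        if not inlets or not outlets:
            raise StructuralError("system needs at least one inlet and one outlet")
        for v in inlets + outlets:
            if self.vertices[v].pressure is None:
                raise StructuralError(
                    f"boundary vertex {v!r} needs a fixed pressure program"
                )
        reach_from_in = set()
        for v in inlets:
            reach_from_in |= {v} | nx.descendants(g, v)
        reach_to_out = set()
        for v in outlets:
            reach_to_out |= {v} | nx.ancestors(g, v)
        for e in self.edges.values():
            if e.length == 0:
                raise StructuralError(f"edge {e.id}: zero-length edges cannot carry the flow solution")
            if e.source not in reach_from_in or e.target not in reach_to_out:
                raise StructuralError(
                    f"edge {e.id} does not lie on an inlet-to-outlet path"
                )
        for e in self.edges.values():
            self.edge_temperature(e)

    def default_path(self) -> list[CapillaryEdge]:
        """The unique inlet-to-outlet module sequence of a series system."""
        g = self.to_networkx()
        paths = []
        for s in self.inlets():
            for t in self.outlets():
                paths.extend(nx.all_simple_paths(g, s, t))
        if len(paths) != 1:
            raise StructuralError(
                f"expected exactly one inlet-to-outlet path, found {len(paths)}"
            )
        nodes = paths[0]
        return [g.edges[u, v]["edge"] for u, v in zip(nodes, nodes[1:])]


@dataclass
class FlowSolution:
    """Network solution at one time point (absolute Pa, normalized m^3/s)."""

    time: float
    pressures: dict[str, float]
    flows: dict[str, float]
    restrictions: dict[str, float]

    def edge_endpoint_pressures(self, edge: CapillaryEdge) -> tuple[float, float]:
        return self.pressures[edge.source], self.pressures[edge.target]


def flow_restriction(graph: SystemGraph, edge: CapillaryEdge, t: float) -> float:
    """Pneumatic restriction kappa of one edge at time t (Pa s K / m^3).

    kappa = integral_0^L eta(T(x,t)) * T(x,t) / d^4 dx; collapses to the
    closed form eta*T*L/d^4 when the temperature is spatially uniform.
    """
    program = graph.edge_temperature(edge)
    d4 = edge.diameter**4
    if program.spatial is None:
        T = program(t)
        return viscosity(graph.gas, T) * T * edge.length / d4
    val, _ = quad(
        lambda x: viscosity(graph.gas, program(t, x)) * program(t, x) / d4,
        0.0,
        edge.length,
        limit=200,
    )
    return val


def solve_pressures(graph: SystemGraph, t: float) -> FlowSolution:
    """Solve the squared-pressure linear system of the network at time t.

    Unknown junction pressures are obtained from molar balance
    (equivalently, conservation of normalized volumetric flow) at every
    junction; fixed vertices contribute boundary values. Raises
    StructuralError naming the vertex if an unknown is isolated.
    """
    graph.validate()
    kappas = {e.id: flow_restriction(graph, e, t) for e in graph.edges.values()}
    known: dict[str, float] = {}
    unknown: list[str] = []
    for v in graph.vertices.values():
        if v.pressure is not None:
            known[v.id] = v.pressure(t) ** 2
        else:
            unknown.append(v.id)
    index = {vid: i for i, vid in enumerate(unknown)}
    n = len(unknown)
    A = np.zeros((n, n))
    b = np.zeros(n)
    # balance at vertex j: sum_in (P_u - P_j)/kappa - sum_out (P_j - P_v)/kappa = 0
    for e in graph.edges.values():
        c = 1.0 / kappas[e.id]
        for vid, other, sign in ((e.target, e.source, 1.0), (e.source, e.target, 1.0)):
            if vid in index:
                i = index[vid]
                A[i, i] -= c
                if other in index:
                    A[i, index[other]] += c
                else:
                    b[i] -= c * known[other]
    for vid, i in index.items():
        if A[i, i] == 0.0:
            raise StructuralError(f"vertex {vid!r} has no connected edges to solve")
    try:
        P_unknown = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise StructuralError(f"singular flow system: {exc}") from exc
    P = dict(known)
    for vid, i in index.items():
        P[vid] = float(P_unknown[i])
    pressures = {vid: math.sqrt(max(val, 0.0)) for vid, val in P.items()}
    coeff = (math.pi / 256.0) * graph.T_ref / graph.p_ref
    flows = {
        e.id: coeff * (P[e.source] - P[e.target]) / kappas[e.id]
        for e in graph.edges.values()
    }
    return FlowSolution(time=t, pressures=pressures, flows=flows, restrictions=kappas)


def pressure_profile(
    graph: SystemGraph, solution: FlowSolution, edge_id: str, x: float
) -> float:
    """Absolute pressure p(x) inside an edge, Pa; exact at the endpoints.

    p(x) = sqrt(p_in^2 - (p_in^2 - p_out^2) * kappa(0->x)/kappa(0->L));
    for spatially uniform temperature the restriction fraction is x/L.
    """
    edge = graph.edges[edge_id]
    if not 0.0 <= x <= edge.length:
        raise ValueError(f"x={x} outside [0, {edge.length}] on edge {edge_id}")
    p_in, p_out = solution.edge_endpoint_pressures(edge)
    program = graph.edge_temperature(edge)
    if program.spatial is None or edge.length == 0:
        frac = x / edge.length if edge.length else 0.0
    else:
        t = solution.time
        d4 = edge.diameter**4
        part, _ = quad(
            lambda xi: viscosity(graph.gas, program(t, xi)) * program(t, xi) / d4,
            0.0,
            x,
            limit=200,
        )
        frac = part / solution.restrictions[edge_id]
    val = p_in**2 - (p_in**2 - p_out**2) * frac
    return math.sqrt(max(val, 0.0))


def local_velocity(
    graph: SystemGraph, solution: FlowSolution, edge_id: str, x: float
) -> float:
    """Local mobile-phase velocity u_M(x) in m/s.

    u_M = F * (p_ref / p(x)) * (T / T_ref) / (pi d^2 / 4): the normalized
    flow re-expanded to local conditions over the open cross-section.
    """
    edge = graph.edges[edge_id]
    p = pressure_profile(graph, solution, edge_id, x)
    if p <= 0.0:
        if x >= edge.length:
            return math.inf  # vacuum-terminated outlet boundary
        raise FloatingPointError(
            f"zero pressure inside edge {edge_id} at x={x}"
        )
    T = graph.edge_temperature(edge)(solution.time, x)
    area = math.pi * edge.diameter**2 / 4.0
    return solution.flows[edge_id] * (graph.p_ref / p) * (T / graph.T_ref) / area


def holdup_time(graph: SystemGraph, solution: FlowSolution, edge_id: str) -> float:
    """Hold-up time of one edge, s (closed form for uniform temperature).

    t_M = (128/3) * eta * L^2 / d^2 * (p_in^3 - p_out^3) / (p_in^2 - p_out^2)^2.
    """
    edge = graph.edges[edge_id]
    if solution.flows[edge_id] <= 0.0:
        raise ValueError(f"edge {edge_id} carries no forward flow; hold-up undefined")
    p_in, p_out = solution.edge_endpoint_pressures(edge)
    program = graph.edge_temperature(edge)
    if program.spatial is None:
        T = program(solution.time)
        eta = viscosity(graph.gas, T)
        return (
            (128.0 / 3.0)
            * eta
            * edge.length**2
            / edge.diameter**2
            * (p_in**3 - p_out**3)
            / (p_in**2 - p_out**2) ** 2
        )
    val, _ = quad(
        lambda x: 1.0 / local_velocity(graph, solution, edge_id, x),
        0.0,
        edge.length,
        limit=200,
    )
    return val


def path_holdup_time(
    graph: SystemGraph, solution: FlowSolution, edge_ids: Iterable[str]
) -> float:
    """Hold-up time of a path = sum of its edges' hold-up times."""
    return sum(holdup_time(graph, solution, eid) for eid in edge_ids)


class FlowField:
    """Quasi-steady flow solution sampled on a time grid, for fast lookup.

    The migration ODEs query endpoint squared pressures and normalized flow
    of an edge at arbitrary times; this caches the per-time-point network
    solves and interpolates linearly (the underlying quantities are smooth
    between program breakpoints, which are included in the grid).
    """

    def __init__(self, graph: SystemGraph, t_end: float, dt: float = 0.5) -> None:
        breakpoints: set[float] = {0.0, float(t_end)}
        for prog in graph.temperature_programs.values():
            breakpoints.update(float(x) for x in prog.times if 0 <= x <= t_end)
        for v in graph.vertices.values():
            if v.pressure is not None:
                breakpoints.update(float(x) for x in v.pressure.times if 0 <= x <= t_end)
        grid = np.union1d(
            np.arange(0.0, t_end + dt, dt), np.array(sorted(breakpoints))
        )
        self.graph = graph
        self.times = grid
        self._pin2: dict[str, np.ndarray] = {}
        self._pout2: dict[str, np.ndarray] = {}
        self._flow: dict[str, np.ndarray] = {}
        sols = [solve_pressures(graph, float(t)) for t in grid]
        for e in graph.edges.values():
            self._pin2[e.id] = np.array([s.pressures[e.source] ** 2 for s in sols])
            self._pout2[e.id] = np.array([s.pressures[e.target] ** 2 for s in sols])
            self._flow[e.id] = np.array([s.flows[e.id] for s in sols])

    def edge_state(self, edge_id: str, t: float) -> tuple[float, float, float]:
        """(p_in^2, p_out^2, F) of an edge at time t."""
        return (
            float(np.interp(t, self.times, self._pin2[edge_id])),
            float(np.interp(t, self.times, self._pout2[edge_id])),
            float(np.interp(t, self.times, self._flow[edge_id])),
        )

    def solution_at(self, t: float) -> FlowSolution:
        return solve_pressures(self.graph, t)
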