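import math

import numpy as np
import pytest
from scipy.integrate import quad

from gcxgcsim.flownet import (
    CapillaryEdge,
    PressureProgram,
    StructuralError,
    SystemGraph,
    TemperatureProgram,
    Vertex,
    flow_restriction,
    holdup_time,
    local_velocity,
    path_holdup_time,
    pressure_profile,
    solve_pressures,
)
from gcxgcsim.physchem import load_gas, viscosity
from conftest import build_single_column
from oracles import holdup_oracle, nonlinear_flow_oracle, series_junction_oracle


class TestTemperatureProgram:
    def test_plateau_ramp_breakpoints(self):
        prog = TemperatureProgram.from_steps(
            50.0, [("hold", 120.0), ("ramp", 10.0, 225.0), ("hold", 900.0)]
        )
        assert prog.duration == pytest.approx(120.0 + 175.0 * 6.0 + 900.0)
        assert prog(0.0) == pytest.approx(323.15)
        assert prog(120.0) == pytest.approx(323.15)
        assert prog(120.0 + 60.0) == pytest.approx(333.15)  # 10 C/min
        assert prog(1e9) == pytest.approx(498.15)  # constant extrapolation

    def test_continuity(self):
        prog = TemperatureProgram.from_steps(50.0, [("hold", 60.0), ("ramp", 5.0, 100.0)])
        ts = np.linspace(0, prog.duration, 500)
        Ts = np.array([prog(t) for t in ts])
        assert np.max(np.abs(np.diff(Ts))) < 0.5  # no jumps on a fine grid


class TestFlowRestriction:
    def test_uniform_closed_form(self, single_column):
        g = single_column(L=10.0, T_C=150.0)
        e = g.edges["col0"]
        T = 150.0 + 273.15
        expected = viscosity(g.gas, T) * T * e.length / e.diameter**4
        assert flow_restriction(g, e, 0.0) == pytest.approx(expected, rel=1e-14)

    def test_diameter_fourth_power(self, single_column):
        g1 = single_column(d=0.25e-3)
        g2 = single_column(d=0.125e-3)
        k1 = flow_restriction(g1, g1.edges["col0"], 0.0)
        k2 = flow_restriction(g2, g2.edges["col0"], 0.0)
        assert k2 == pytest.approx(16.0 * k1, rel=1e-12)

    def test_two_zone_spatial_profile_matches_quadrature(self, single_column):
        g = single_column(L=2.0, T_C=100.0)
        T1, T2 = 373.15, 473.15
        g.temperature_programs["oven"] = TemperatureProgram(
            [0.0], [T1], spatial=lambda x, t, T: T1 if x < 1.0 else T2
        )
        e = g.edges["col0"]
        got = flow_restriction(g, e, 0.0)
        per_zone = sum(
            viscosity(g.gas, T) * T * 1.0 / e.diameter**4 for T in (T1, T2)
        )
        assert got == pytest.approx(per_zone, rel=1e-10)


class TestSolvePressures:
    def test_no_driving_pressure_no_flow(self, single_column):
        g = single_column(p_in=1.5e5, p_out=1.5e5)
        sol = solve_pressures(g, 0.0)
        assert sol.flows["col0"] == pytest.approx(0.0, abs=1e-20)

    def test_series_junction_closed_form(self, single_column):
        g = build_single_column(L=10.0, n_segments=2, p_in=2.6e5, p_out=0.0)
        # make the two restrictions different
        g.edges["col1"].diameter = 0.1e-3
        sol = solve_pressures(g, 0.0)
        k1 = flow_restriction(g, g.edges["col0"], 0.0)
        k2 = flow_restriction(g, g.edges["col1"], 0.0)
        expected = series_junction_oracle(2.6e5, 0.0, k1, k2)
        assert sol.pressures["j1"] == pytest.approx(expected, rel=1e-12)

    def test_junction_conservation_branched(self):
        # one inlet feeding two different outlets through a junction
        g = SystemGraph(gas=load_gas("helium"))
        g.temperature_programs["oven"] = TemperatureProgram.isothermal(423.15)
        g.add_vertex(Vertex("in", pressure=PressureProgram.constant(3e5), role="inlet"))
        g.add_vertex(Vertex("j"))
        g.add_vertex(Vertex("out1", pressure=PressureProgram.constant(1e5), role="outlet"))
        g.add_vertex(Vertex("out2", pressure=PressureProgram.vacuum(), role="outlet"))
        g.add_edge(CapillaryEdge("a", "in", "j", 10.0, 0.25e-3))
        g.add_edge(CapillaryEdge("b", "j", "out1", 2.0, 0.1e-3))
        g.add_edge(CapillaryEdge("c", "j", "out2", 1.0, 0.05e-3))
        sol = solve_pressures(g, 0.0)
        net = sol.flows["a"] - sol.flows["b"] - sol.flows["c"]
        assert abs(net) <= 1e-9 * max(abs(f) for f in sol.flows.values())

    def test_random_networks_match_nonlinear_rootfinder(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n_junction = rng.integers(1, 4)
            g = SystemGraph(gas=load_gas("helium"))
            g.temperature_programs["oven"] = TemperatureProgram.isothermal(
                float(rng.uniform(320, 500))
            )
            p_in = float(rng.uniform(1.5e5, 4e5))
            g.add_vertex(Vertex("in", pressure=PressureProgram.constant(p_in), role="inlet"))
            names = []
            for i in range(n_junction):
                g.add_vertex(Vertex(f"j{i}"))
                names.append(f"j{i}")
            g.add_vertex(Vertex("out", pressure=PressureProgram.vacuum(), role="outlet"))
            chain = ["in"] + names + ["out"]
            oracle_edges = []
            known = {0: p_in, len(chain) - 1: 0.0}
            for i in range(len(chain) - 1):
                d = float(rng.uniform(0.05e-3, 0.3e-3))
                L = float(rng.uniform(0.5, 20.0))
                g.add_edge(CapillaryEdge(f"e{i}", chain[i], chain[i + 1], L, d))
            if n_junction >= 2:  # add a parallel shortcut to create a loop
                d = float(rng.uniform(0.05e-3, 0.2e-3))
                g.add_edge(CapillaryEdge("loop", names[0], names[-1], 3.0, d))
            sol = solve_pressures(g, 0.0)
            kappas = {e.id: flow_restriction(g, e, 0.0) for e in g.edges.values()}
            idx = {v: i for i, v in enumerate(chain)}
            oracle_edges = [
                (idx[e.source] - 1, idx[e.target] - 1, kappas[e.id])
                for e in g.edges.values()
            ]
            # oracle indexing: unknowns are junctions 0..n-1; boundaries by value
            known_p = {-1: p_in, len(chain) - 2: 0.0}
            p_oracle = nonlinear_flow_oracle(
                n_junction, oracle_edges, known_p, x0=np.full(n_junction, p_in / 2)
            )
            for i, name in enumerate(names):
                assert sol.pressures[name] == pytest.approx(
                    float(p_oracle[i]), rel=1e-8
                ), f"trial {trial}"

    def test_subdivision_invariance(self):
        whole = build_single_column(L=10.0, p_in=2.6e5)
        split = build_single_column(L=10.0, p_in=2.6e5, n_segments=2)
        f1 = solve_pressures(whole, 0.0).flows["col0"]
        f2 = solve_pressures(split, 0.0).flows["col0"]
        assert f2 == pytest.approx(f1, rel=1e-12)

    def test_isolated_unknown_vertex_named(self):
        g = build_single_column()
        g.add_vertex(Vertex("orphan"))
        g.add_edge(CapillaryEdge("dangling", "orphan", "outlet", 1.0, 0.1e-3))
        with pytest.raises(StructuralError):
            solve_pressures(g, 0.0)

    def test_boundary_without_pressure_rejected(self):
        g = SystemGraph(gas=load_gas("helium"))
        g.temperature_programs["oven"] = TemperatureProgram.isothermal(373.15)
        g.add_vertex(Vertex("in", role="inlet"))
        g.add_vertex(Vertex("out", pressure=PressureProgram.vacuum(), role="outlet"))
        g.add_edge(CapillaryEdge("e", "in", "out", 1.0, 0.1e-3))
        with pytest.raises(StructuralError, match="in"):
            g.validate()


class TestPressureProfile:
    def test_endpoint_identity(self, single_column):
        g = single_column(p_in=2.5e5, p_out=0.8e5)
        sol = solve_pressures(g, 0.0)
        L = g.edges["col0"].length
        assert pressure_profile(g, sol, "col0", 0.0) == pytest.approx(2.5e5)
        assert pressure_profile(g, sol, "col0", L) == pytest.approx(0.8e5)

    def test_vacuum_outlet_closed_form(self, single_column):
        g = single_column(p_in=2.0e5, p_out=0.0, L=10.0)
        sol = solve_pressures(g, 0.0)
        for frac in (0.1, 0.5, 0.9):
            assert pressure_profile(g, sol, "col0", frac * 10.0) == pytest.approx(
                2.0e5 * math.sqrt(1.0 - frac), rel=1e-12
            )

    def test_midpoint_with_double_inlet_pressure(self, single_column):
        p_out = 1.0e5
        g = single_column(p_in=2.0 * p_out, p_out=p_out, L=10.0)
        sol = solve_pressures(g, 0.0)
        expected = math.sqrt((4.0 * p_out**2 + p_out**2) / 2.0)
        assert pressure_profile(g, sol, "col0", 5.0) == pytest.approx(expected, rel=1e-12)

    def test_outside_edge_rejected(self, single_column):
        g = single_column()
        sol = solve_pressures(g, 0.0)
        with pytest.raises(ValueError):
            pressure_profile(g, sol, "col0", -0.1)


class TestVelocityAndHoldup:
    def test_velocity_increases_toward_vacuum(self, single_column):
        g = single_column(p_in=2.0e5, p_out=0.0, L=10.0)
        sol = solve_pressures(g, 0.0)
        xs = np.linspace(0.0, 9.99, 50)
        us = [local_velocity(g, sol, "col0", x) for x in xs]
        assert np.all(np.diff(us) > 0)

    def test_outlet_velocity_definition(self, single_column):
        g = single_column(p_in=2.0e5, p_out=1.0e5, L=10.0)
        sol = solve_pressures(g, 0.0)
        e = g.edges["col0"]
        T = g.temperature_programs["oven"](0.0)
        u_exp = (
            sol.flows["col0"]
            * (g.p_ref / 1.0e5)
            * (T / g.T_ref)
            / (math.pi * e.diameter**2 / 4.0)
        )
        assert local_velocity(g, sol, "col0", 10.0) == pytest.approx(u_exp, rel=1e-12)

    def test_holdup_closed_form_vs_quadrature(self, single_column):
        g = single_column(p_in=2.4e5, p_out=0.4e5, L=15.0)
        sol = solve_pressures(g, 0.0)
        closed = holdup_time(g, sol, "col0")
        numeric, _ = quad(
            lambda x: 1.0 / local_velocity(g, sol, "col0", x), 0.0, 15.0, limit=200
        )
        assert closed == pytest.approx(numeric, rel=1e-8)
        T = g.temperature_programs["oven"](0.0)
        eta = viscosity(g.gas, T)
        assert closed == pytest.approx(
            holdup_oracle(eta, 15.0, 0.25e-3, 2.4e5, 0.4e5), rel=1e-12
        )

    def test_path_holdup_additive(self):
        g = build_single_column(L=10.0, n_segments=3, p_in=2.2e5)
        sol = solve_pressures(g, 0.0)
        total = path_holdup_time(g, sol, ["col0", "col1", "col2"])
        parts = sum(holdup_time(g, sol, f"col{i}") for i in range(3))
        assert total == pytest.approx(parts, rel=1e-14)

    def test_holdup_scales_with_length_squared(self, single_column):
        g1 = single_column(L=10.0, p_in=2.0e5, p_out=0.5e5)
        g2 = single_column(L=20.0, p_in=2.0e5, p_out=0.5e5)
        t1 = holdup_time(g1, solve_pressures(g1, 0.0), "col0")
        t2 = holdup_time(g2, solve_pressures(g2, 0.0), "col0")
        assert t2 == pytest.approx(4.0 * t1, rel=1e-12)

    def test_zero_flow_holdup_rejected(self, single_column):
        g = single_column(p_in=1.0e5, p_out=1.0e5)
        sol = solve_pressures(g, 0.0)
        with pytest.raises(ValueError, match="hold-up"):
            holdup_time(g, sol, "col0")
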