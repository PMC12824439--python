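import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gcxgcsim.fixtures import make_reference_instrument, make_solutes
from gcxgcsim.flownet import (
    CapillaryEdge,
    FlowField,
    PressureProgram,
    SystemGraph,
    TemperatureProgram,
    Vertex,
)
from gcxgcsim.physchem import TransportProps, load_gas
from gcxgcsim.retention import PhaseEntry, SoluteRecord


def build_single_column(
    L=10.0,
    d=0.25e-3,
    df=0.25e-6,
    phase="ZB-1ms",
    T_C=150.0,
    p_in=2.0e5,
    p_out=0.0,
    n_segments=1,
):
    """One capillary (optionally split into segments) from inlet to outlet."""
    g = SystemGraph(gas=load_gas("helium"))
    g.temperature_programs["oven"] = TemperatureProgram.isothermal(T_C + 273.15)
    g.add_vertex(Vertex("inlet", pressure=PressureProgram.constant(p_in), role="inlet"))
    nodes = ["inlet"]
    for i in range(1, n_segments):
        g.add_vertex(Vertex(f"j{i}"))
        nodes.append(f"j{i}")
    g.add_vertex(Vertex("outlet", pressure=PressureProgram.constant(p_out), role="outlet"))
    nodes.append("outlet")
    for i in range(n_segments):
        g.add_edge(
            CapillaryEdge(
                id=f"col{i}",
                source=nodes[i],
                target=nodes[i + 1],
                length=L / n_segments,
                diameter=d,
                film=df,
                phase=phase,
            )
        )
    g.validate()
    return g


def make_test_solute(
    name="probe", Tchar=420.0, theta=30.0, dcp=120.0, phi_ref=1e-3, molar_mass=242.4
):
    rec = SoluteRecord(name=name, cas="75-09-2", transport=TransportProps(molar_mass))
    rec.add_phase("ZB-1ms", PhaseEntry(Tchar, theta, dcp, phi_ref))
    rec.add_phase("Stabilwax", PhaseEntry(Tchar + 20.0, theta, dcp, phi_ref))
    return rec


@pytest.fixture
def single_column():
    return build_single_column


@pytest.fixture
def test_solute():
    return make_test_solute()


@pytest.fixture(scope="session")
def instrument_config():
    return make_reference_instrument("III-10-3")


@pytest.fixture(scope="session")
def instrument_field(instrument_config):
    horizon = instrument_config.system.temperature_programs["oven"].duration
    return FlowField(instrument_config.system, t_end=horizon * 1.05 + 60.0)


@pytest.fixture(scope="session")
def small_solutes():
    return make_solutes(5, seed=1)


@pytest.fixture(scope="session")
def forty_solutes():
    return make_solutes(40, seed=7)
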