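"""Deterministic fixture generators: instrument configs, solutes, drift data.

Everything a test or demo needs is generated here, seeded and
reproducible: the looped-modulator GCxGC instrument with its eight
heating-rate x modulation-period program variants, plausible K-centric
solute sets filtered to elute within the fastest program, and synthetic
"measured" peak tables with an injected modulation-period error, modulator
shift and reporting noise for exercising the diagnostics. The distortion
model perturbs only the reported times (grid drift accumulates per
modulation cycle), never the underlying physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .diagnostics import CorrectionSet, DriftSeries, apply_corrections
from .flownet import (
    P_AMBIENT,
    CapillaryEdge,
    FlowField,
    PressureProgram,
    SystemGraph,
    TemperatureProgram,
    Vertex,
)
from .migration import PeakState, SolverOptions, migrate, simulate_path
from .modulator import ModulatorSettings
from .physchem import TransportProps, load_gas
from .projection import PeakTable2D, SliceRecord, build_peak_table, records_from_results
from .retention import PhaseEntry, SoluteRecord

__all__ = [
    "PROGRAMS",
    "FIRST_PHASE",
    "SECOND_PHASE",
    "FixtureSpec",
    "make_reference_instrument",
    "make_solutes",
    "DriftedMeasurement",
    "make_drifted_measurement",
]

# Program variants: name -> (heating rate degC/min, modulation period s,
# final hold min). All start at 50 degC (2 min hold) and ramp to 225 degC.
PROGRAMS: dict[str, tuple[float, float, float]] = {
    "I-3-3": (3.0, 3.0, 10.0),
    "II-5-3": (5.0, 3.0, 15.0),
    "III-10-3": (10.0, 3.0, 15.0),
    "IV-3-6": (3.0, 6.0, 25.0),
    "V-3-4": (3.0, 4.0, 25.0),
    "VI-5-4": (5.0, 4.0, 5.0),
    "VII-3-3": (3.0, 3.0, 25.0),
    "VIII-5-3": (5.0, 3.0, 25.0),
}

FIRST_PHASE = "ZB-1ms"  # nonpolar first-dimension column
SECOND_PHASE = "Stabilwax"  # polar second-dimension column

# Instrument geometry (m): estimated first-dimension length, segmented
# second-dimension column with two 5 mm modulation points, transfer line.
L_FIRST = 29.74
D_FIRST, DF_FIRST = 0.25e-3, 0.25e-6
D_SECOND, DF_SECOND = 0.10e-3, 0.10e-6
L_MOD_IN, L_TM, L_LOOP, L_OUT, L_TRANSFER = 0.30, 0.005, 0.90, 0.53, 0.24
TRANSFER_LINE_C = 250.0  # fixed transfer-line temperature, degC
P_IN_50C_KPAG = 160.30
P_IN_225C_KPAG = 274.96
HOT_DURATION = 0.350
HOT_OFFSET = 25.0


def make_reference_instrument(
    program: str = "V-3-4",
    shift: float = 0.0,
    period: float | None = None,
) -> RunConfig:
    """The looped thermal-modulator GCxGC instrument as a run configuration.

    ``program`` selects one of the eight heating-rate/modulation-period
    variants (see PROGRAMS). The inlet pressure ramps linearly in time with
    the oven program between its calibrated values at the 50 and 225 degC
    plateaus; the outlet (ToF-MS interface) is vacuum; the transfer line is
    held at a fixed 250 degC.
    """
    if program not in PROGRAMS:
        raise KeyError(f"unknown program {program!r}; choose from {sorted(PROGRAMS)}")
    rate, tMP, end_hold_min = PROGRAMS[program]
    if period is not None:
        tMP = period
    system = SystemGraph(gas=load_gas("helium"))
    system.temperature_programs["oven"] = TemperatureProgram.from_steps(
        50.0,
        [("hold", 120.0), ("ramp", rate, 225.0), ("hold", end_hold_min * 60.0)],
    )
    system.temperature_programs["transfer_line"] = TemperatureProgram.isothermal(
        TRANSFER_LINE_C + 273.15
    )
    ramp_start = 120.0
    ramp_end = ramp_start + (225.0 - 50.0) / rate * 60.0
    inlet_pressure = PressureProgram(
        [0.0, ramp_start, ramp_end],
        [
            P_IN_50C_KPAG * 1e3 + P_AMBIENT,
            P_IN_50C_KPAG * 1e3 + P_AMBIENT,
            P_IN_225C_KPAG * 1e3 + P_AMBIENT,
        ],
    )
    system.add_vertex(Vertex("injector", pressure=inlet_pressure, role="inlet"))
    for vid in ("j1", "j2", "j3", "j4", "j5", "j6"):
        system.add_vertex(Vertex(vid))
    system.add_vertex(Vertex("detector", pressure=PressureProgram.vacuum(), role="outlet"))

    settings = ModulatorSettings(
        period=tMP, shift=shift, hot_duration=HOT_DURATION, hot_offset=HOT_OFFSET
    )

    def col(id, src, dst, L, d, df, phase, temp="oven", modulator=None):
        system.add_edge(
            CapillaryEdge(
                id=id, source=src, target=dst, length=L, diameter=d, film=df,
                phase=phase, temperature=temp, modulator=modulator,
            )
        )

    col("column1", "injector", "j1", L_FIRST, D_FIRST, DF_FIRST, FIRST_PHASE)
    col("mod_in", "j1", "j2", L_MOD_IN, D_SECOND, DF_SECOND, SECOND_PHASE)
    col("TM1", "j2", "j3", L_TM, D_SECOND, DF_SECOND, SECOND_PHASE, modulator=settings)
    col("loop", "j3", "j4", L_LOOP, D_SECOND, DF_SECOND, SECOND_PHASE)
    col("TM2", "j4", "j5", L_TM, D_SECOND, DF_SECOND, SECOND_PHASE, modulator=settings)
    col("mod_out", "j5", "j6", L_OUT, D_SECOND, DF_SECOND, SECOND_PHASE)
    col("transfer", "j6", "detector", L_TRANSFER, D_SECOND, DF_SECOND, SECOND_PHASE,
        temp="transfer_line")
    system.validate()
    return RunConfig(name=f"gcxgc-{program}", system=system)


def make_control_software_system(T_oven_C: float = 50.0) -> RunConfig:
    """The control software's simplified model: two capillaries in series.

    30 m x 0.25 mm + 2 m x 0.1 mm, everything at one oven temperature,
    vacuum outlet — the representation the instrument software was limited
    to, yielding its nominal 0.8 mL/min.
    """
    system = SystemGraph(gas=load_gas("helium"))
    system.temperature_programs["oven"] = TemperatureProgram.isothermal(
        T_oven_C + 273.15
    )
    system.add_vertex(
        Vertex(
            "injector",
            pressure=PressureProgram.constant(P_IN_50C_KPAG * 1e3 + P_AMBIENT),
            role="inlet",
        )
    )
    system.add_vertex(Vertex("j1"))
    system.add_vertex(Vertex("detector", pressure=PressureProgram.vacuum(), role="outlet"))
    system.add_edge(
        CapillaryEdge("column1", "injector", "j1", 30.0, D_FIRST, DF_FIRST,
                      phase=FIRST_PHASE)
    )
    system.add_edge(
        CapillaryEdge("column2", "j1", "detector", 2.0, D_SECOND, DF_SECOND,
                      phase=SECOND_PHASE)
    )
    system.validate()
    return RunConfig(name="control-software", system=system)


_PHI_REF = DF_FIRST / D_FIRST  # df/d of the calibration system (both columns)


def _candidate_solute(rng: np.random.Generator, idx: int) -> SoluteRecord:
    Tchar1 = float(rng.uniform(330.0, 560.0))
    theta1 = float(rng.uniform(22.0, 45.0))
    dcp1 = float(rng.uniform(50.0, 250.0))
    # polar second phase: moderately higher characteristic temperature so
    # second-dimension retention lands in the sub-period range
    Tchar2 = Tchar1 + float(rng.uniform(5.0, 35.0))
    theta2 = float(rng.uniform(20.0, 40.0))
    dcp2 = float(rng.uniform(50.0, 250.0))
    molar_mass = max(60.0, 80.0 + (Tchar1 - 330.0) * 0.9 + float(rng.normal(0, 15)))
    rec = SoluteRecord(
        name=f"solute-{idx:03d}",
        cas=f"9999-{idx:03d}-0",
        transport=TransportProps(molar_mass),
    )
    rec.add_phase(FIRST_PHASE, PhaseEntry(Tchar1, theta1, dcp1, _PHI_REF))
    rec.add_phase(SECOND_PHASE, PhaseEntry(Tchar2, theta2, dcp2, _PHI_REF))
    return rec


def make_solutes(
    n: int,
    seed: int = 0,
    filter_program: str = "VI-5-4",
) -> list[SoluteRecord]:
    """Seeded plausible solute set (K-centric parameters on both phases).

    Candidates are drawn from realistic parameter ranges and kept only if a
    forward simulation (modulation disabled) elutes them from the full path
    within the horizon of ``filter_program``. The default VI-5-4 is the
    most restrictive program variant (its final hold is only 5 min), so
    the generated set elutes under every program. Same seed, same table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = make_reference_instrument(filter_program)
    graph = cfg.system
    horizon = graph.temperature_programs["oven"].duration
    field_ = FlowField(graph, t_end=horizon * 1.05 + 60.0, dt=2.0)
    path = graph.default_path()
    coarse = SolverOptions(rtol=1e-6, atol_time=1e-8, atol_var=1e-8)
    out: list[SoluteRecord] = []
    idx = 0
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n:
            raise RuntimeError("solute generation failed to converge")
        cand = _candidate_solute(rng, idx)
        state = PeakState(t=0.0, tau2=0.0, area=1.0)
        ok = True
        for edge in path:  # modulation disabled: plain migration throughout
            res = migrate(graph, field_, edge, state, cand,
                          options=coarse, horizon=horizon)
            if not res.eluted:
                ok = False
                break
            state = res.exit_state
        if ok:
            cand.name = f"solute-{len(out):03d}"
            cand.cas = f"9999-{len(out):03d}-0"
            out.append(cand)
        idx += 1
    return out


@dataclass
class FixtureSpec:
    """Scenario description for a synthetic drifted measurement."""

    scenario: str = "drift"
    seed: int = 0
    n_solutes: int = 10
    n_cycles: int = 1000
    delta_period: float = 0.0  # actual minus set modulation period, s
    shift: float = 0.0  # modulator shift, s
    noise_sigma: float = 0.0  # reporting noise, s
    program: str = "V-3-4"


@dataclass
class DriftedMeasurement:
    """Synthetic measurement with known injected distortions."""

    measured: PeakTable2D
    predicted: PeakTable2D
    measured_records: list[SliceRecord]
    predicted_records: list[SliceRecord]
    drift_series: DriftSeries
    settings: ModulatorSettings
    truth: dict = field(default_factory=dict)


def make_drifted_measurement(
    config: RunConfig,
    solutes: list[SoluteRecord],
    delta_period: float = 0.0,
    shift: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_cycles: int = 1000,
    bleed_t2: float = 1.5,
    results=None,
) -> DriftedMeasurement:
    """Simulate once, then distort the reported times.

    The instrument's actual modulation grid has period tMP + delta_period
    and lags the injection clock by ``shift``, so a slice released in cycle
    n is reported n*delta_period + shift later than predicted on the
    nominal grid; Gaussian noise of ``noise_sigma`` is added to reported
    times only. Also emits the bleed-marker drift series (one fixed
    second-dimension marker observed over ``n_cycles`` cycles) used for
    period estimation.
    """
    if abs(delta_period) >= 0.01:
        raise ValueError("delta_period must be below 10 ms")
    graph = config.system
    settings = config.modulator_settings()
    rng = np.random.default_rng(seed)
    if results is None:
        path = graph.default_path()
        results = simulate_path(graph, path, solutes, options=config.solver)
    predicted_records = records_from_results(results, settings)
    cas = {s.name: s.cas for s in solutes}
    predicted = build_peak_table(predicted_records, settings, cas_by_solute=cas)

    distortion = CorrectionSet(
        tMP_set=settings.period,
        tMP_corr=settings.period + delta_period,
        tshift=shift,
    )
    measured_records = apply_corrections(predicted_records, distortion)
    if noise_sigma > 0.0:
        for r in measured_records:
            eps = float(rng.normal(0.0, noise_sigma))
            r.time += eps
            r.twod_time += eps
            r.twod_folded = r.twod_time % settings.period
            r.n_elute = settings.hot_cycle_of(r.time)
    measured = build_peak_table(measured_records, settings, cas_by_solute=cas)

    cycles = np.arange(n_cycles)
    times = bleed_t2 + cycles * delta_period + shift
    if noise_sigma > 0.0:
        times = times + rng.normal(0.0, noise_sigma, size=n_cycles)
    series = DriftSeries(marker="column bleed", cycles=cycles, times=times)
    return DriftedMeasurement(
        measured=measured,
        predicted=predicted,
        measured_records=measured_records,
        predicted_records=predicted_records,
        drift_series=series,
        settings=settings,
        truth={
            "delta_period": delta_period,
            "period": settings.period + delta_period,
            "shift": shift,
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
    )
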