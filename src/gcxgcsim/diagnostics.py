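"""System diagnostics: modulation-period drift, modulator shift, column length.

Small systematic errors of the instrument show up as structured deviations
between measured and predicted 2D retention times:

* an actual modulation period slightly longer than the set value makes the
  apparent second-dimension time of a fixed marker (e.g. column bleed)
  drift linearly with the cycle index — an ordinary least-squares slope on
  (cycle, observed 2t) recovers the true period;
* a constant latency between injection clock and modulation grid shifts all
  second-dimension times by the same amount — recovered as the mean
  measured-minus-predicted deviation pooled over analytes and runs;
* the effective first-dimension column length is recovered from hold-up
  time measurements of an unretained marker at several inlet pressures and
  oven temperatures by least squares against the flow-network model.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .flownet import (
    FlowField,
    PressureProgram,
    SystemGraph,
    TemperatureProgram,
    solve_pressures,
    path_holdup_time,
)
from .projection import PeakTable2D, SliceRecord

__all__ = [
    "DriftSeries",
    "CorrectionSet",
    "estimate_period",
    "accumulated_deviation",
    "estimate_shift",
    "estimate_shift_tables",
    "estimate_column_length",
    "apply_corrections",
]


@dataclass
class DriftSeries:
    """Observed second-dimension times of a fixed marker per modulation cycle."""

    marker: str
    cycles: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.cycles.size < 3:
            raise ValueError("drift series needs at least 3 points")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycle indices must be strictly increasing")
        if self.cycles.size != self.times.size:
            raise ValueError("cycles and times must have equal length")

    @classmethod
    def from_csv(cls, path, marker: str = "bleed") -> "DriftSeries":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        return cls(
            marker=marker,
            cycles=df["cycle"].to_numpy(),
            times=df["twod_time_s"].to_numpy(),
        )

    def to_csv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("cycle,twod_time_s\n")
            for c, t in zip(self.cycles, self.times):
                fh.write(f"{c:.0f},{t:.9f}\n")


@dataclass
class CorrectionSet:
    """Estimated actual modulation period and modulator shift."""

    tMP_set: float
    tMP_corr: float
    tMP_err: float = 0.0
    tshift: float = 0.0
    tshift_err: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.tMP_corr - self.tMP_set) >= 0.01 * self.tMP_set:
            warnings.warn(
                "estimated period differs from the set value by more than 1%;"
                " drift data may be invalid",
                stacklevel=2,
            )

    def to_patch(self) -> dict:
        """Config patch ingestible by the simulator (modulator block)."""
        return {
            "modulator": {
                "period": f"{self.tMP_corr:.9f} s",
                "shift": f"{self.tshift:.9f} s",
            }
        }


def estimate_period(series: DriftSeries, tMP_set: float) -> CorrectionSet:
    """Actual modulation period from the per-cycle drift of a fixed marker.

    The observed second-dimension time of the marker grows by
    (tMP_actual - tMP_set) per cycle on the analyst's nominal grid; the OLS
    slope of observed time vs cycle index therefore corrects the period.
    The standard error of the slope is reported as the period uncertainty.
    """
    res = stats.linregress(series.cycles, series.times)
    return CorrectionSet(
        tMP_set=tMP_set,
        tMP_corr=tMP_set + float(res.slope),
        tMP_err=float(res.stderr),
    )


def accumulated_deviation(tMP_set: float, tMP_corr: float, n_cycles: int) -> float:
    """Accumulated second-dimension drift after n modulation cycles, s."""
    if n_cycles < 0:
        raise ValueError("cycle count must be non-negative")
    return n_cycles * (tMP_corr - tMP_set)


def estimate_shift(
    measured: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float]:
    """Constant modulator shift as the mean measured-predicted 2tR deviation.

    Pools all analytes and runs unweighted; returns (mean, standard
    deviation of the individual deviations).
    """
    meas = np.asarray(measured, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if meas.size == 0 or meas.size != pred.size:
        raise ValueError("need equally sized, non-empty measured/predicted arrays")
    dev = meas - pred
    return float(dev.mean()), float(dev.std(ddof=1)) if dev.size > 1 else 0.0


def estimate_shift_tables(
    measured: PeakTable2D | Sequence[PeakTable2D],
    predicted: PeakTable2D | Sequence[PeakTable2D],
) -> tuple[float, float]:
    """Shift estimate from matched peak tables (possibly several runs)."""
    if isinstance(measured, PeakTable2D):
        measured = [measured]
    if isinstance(predicted, PeakTable2D):
        predicted = [predicted]
    meas_all, pred_all = [], []
    for m_tab, p_tab in zip(measured, predicted, strict=True):
        m = m_tab.table.set_index("solute")["tR2"]
        p = p_tab.table.set_index("solute")["tR2"]
        common = m.index.intersection(p.index)
        meas_all.extend(m.loc[common].tolist())
        pred_all.extend(p.loc[common].tolist())
    return estimate_shift(meas_all, pred_all)


def estimate_column_length(
    graph: SystemGraph,
    edge_id: str,
    observations: Sequence[tuple[float, float, float]],
    oven_program: str = "oven",
    inlet: str | None = None,
    x0: float | None = None,
) -> tuple[float, np.ndarray]:
    """Effective length of one column from hold-up time measurements.

    Parameters
    ----------
    observations:
        (inlet pressure Pa absolute, oven temperature K, observed hold-up
        time s) per measurement; hold-up is over the full inlet-to-outlet
        path with modulation disabled.
    edge_id:
        Edge whose length is fitted; nominal diameters stay fixed, so
        diameter deviations are absorbed into the estimated length.

    Returns (length, residuals).
    """
    if not observations:
        raise ValueError("need at least one hold-up observation")
    if inlet is None:
        inlets = graph.inlets()
        if len(inlets) != 1:
            raise ValueError("specify the inlet vertex explicitly")
        inlet = inlets[0]
    work = copy.deepcopy(graph)
    edge = work.edges[edge_id]
    path_ids = [e.id for e in work.default_path()]

    def model(L: float) -> np.ndarray:
        edge.length = float(L)
        t_model = []
        for p_in, T, _ in observations:
            work.temperature_programs[oven_program] = TemperatureProgram.isothermal(T)
            work.vertices[inlet].pressure = PressureProgram.constant(p_in)
            sol = solve_pressures(work, 0.0)
            t_model.append(path_holdup_time(work, sol, path_ids))
        return np.asarray(t_model)

    t_obs = np.array([obs[2] for obs in observations])

    def residual(params: np.ndarray) -> np.ndarray:
        return model(params[0]) - t_obs

    start = x0 if x0 is not None else graph.edges[edge_id].length
    fit = least_squares(
        residual, x0=[start], bounds=([1e-3], [1e4]), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if not fit.success:
        raise RuntimeError(
            f"column-length fit did not converge; residuals {fit.fun}"
        )
    return float(fit.x[0]), fit.fun


def apply_corrections(
    records: Sequence[SliceRecord], correction: CorrectionSet
) -> list[SliceRecord]:
    """Move predicted slice times onto the corrected modulation grid.

    A slice released in cycle n is released n*(tMP_corr - tMP_set) + tshift
    later on the actual grid than on the nominal one; the raw detector time
    and the second-dimension time shift by the same amount.
    """
    d_period = correction.tMP_corr - correction.tMP_set
    out = []
    for r in records:
        delta = r.release_cycle * d_period + correction.tshift
        out.append(
            SliceRecord(
                solute=r.solute,
                time=r.time + delta,
                tau=r.tau,
                area=r.area,
                n_elute=r.n_elute,
                release_cycle=r.release_cycle,
                twod_time=r.twod_time + delta,
                twod_folded=(r.twod_time + delta) % max(correction.tMP_set, 1e-12),
                wraparound=r.wraparound,
                cas=r.cas,
            )
        )
    return out
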