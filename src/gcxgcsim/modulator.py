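"""Thermal modulator: rectangular temperature cycle, slicing, release.

The modulator is a short (few mm) section of the second-dimension column
swept periodically by a cold jet (trapping) and a hot jet (release). Its
temperature is approximated by a periodic rectangular function riding on
the oven program: within each modulation cycle of period ``tMP`` (grid
translated by ``tshift``) the cold phase of duration ``tcold`` comes first
and the hot phase of duration ``thot = tMP - tcold`` ends the cycle. A
band arriving from upstream is cut into per-cycle slices by Gaussian area;
each slice is released as a sharp pulse at the start of the hot phase that
terminates its collection window, and crosses the modulation point in

    t_migration = L (1 + k) / u_M        (k at oven T + hot-jet offset)

leaving with retention time ``t_nexthot + t_migration`` and peak width
``tau = t_migration``. This replaces a full thermal/ODE treatment of the
modulator, which reproduces comparable retention times and widths at
orders of magnitude higher cost (kept only as a test oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from statistics import NormalDist

from .flownet import CapillaryEdge, FlowField, SystemGraph, TemperatureProgram
from .migration import PeakState
from .retention import SoluteRecord, retention_factor_modulator

__all__ = [
    "ModulatorSettings",
    "Slice",
    "modulator_temperature",
    "slice_band",
    "release",
]

_NORMAL = NormalDist()


@dataclass(frozen=True)
class ModulatorSettings:
    """Thermal-modulator parameters.

    period:       modulation period tMP, s
    shift:        translation of the whole modulation grid, s (signed)
    hot_duration: active hot-jet duration thot, s
    hot_offset:   temperature increase of the hot jet above the oven, K
    cold_value:   cold-jet temperature, K: an offset relative to the oven
                  program (cold_mode='offset', default) or absolute
                  (cold_mode='absolute'). Has little influence: the
                  simplified model assumes complete trapping.
    """

    period: float
    shift: float = 0.0
    hot_duration: float = 0.35
    hot_offset: float = 25.0
    cold_value: float = -80.0
    cold_mode: str = "offset"

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("modulation period must be positive")
        if not 0 < self.hot_duration < self.period:
            raise ValueError("hot duration must lie in (0, period)")
        if self.cold_mode not in ("offset", "absolute"):
            raise ValueError("cold_mode must be 'offset' or 'absolute'")

    @property
    def cold_duration(self) -> float:
        return self.period - self.hot_duration

    def cycle_of(self, t: float) -> int:
        """Index of the modulation cycle containing time t."""
        return math.floor((t - self.shift) / self.period)

    def window(self, n: int) -> tuple[float, float]:
        """Half-open collection window [a_n, b_n) of cycle n."""
        a = self.shift + n * self.period
        return a, a + self.period

    def next_hot(self, n: int) -> float:
        """Start of the hot phase terminating the window of cycle n."""
        return self.shift + n * self.period + self.cold_duration

    def hot_cycle_of(self, t: float) -> int:
        """Index of the last hot jet fired at or before t (hot-jet grid).

        Second-dimension elution is counted on this grid: a slice released
        by hot jet n and detected before hot jet n+1 has elution cycle n.
        """
        return math.floor((t - self.shift - self.cold_duration) / self.period)


@dataclass
class Slice:
    """One modulation-cycle portion of a band."""

    solute: str
    cycle: int
    window: tuple[float, float]
    fraction: float
    release_time: float
    state: PeakState


def modulator_temperature(
    settings: ModulatorSettings, oven: TemperatureProgram, t: float
) -> float:
    """Modulator temperature at time t, K (rectangular function on the oven).

    The hot window of cycle n is [n tMP + tshift + tcold, (n+1) tMP + tshift),
    half-open, so a time exactly on the cold/hot boundary is hot.
    """
    n = settings.cycle_of(t)
    local = t - settings.shift - n * settings.period
    if local >= settings.cold_duration:
        return oven(t) + settings.hot_offset
    if settings.cold_mode == "absolute":
        return settings.cold_value
    return oven(t) + settings.cold_value


def slice_band(
    settings: ModulatorSettings,
    band: PeakState,
    solute_name: str = "",
    eps: float = 1e-4,
) -> list[Slice]:
    """Cut an arriving Gaussian band into per-cycle slices.

    The slice of cycle n receives the Gaussian area fraction
    Phi((b_n - tR)/tau) - Phi((a_n - tR)/tau) of the band. Tails beyond a
    total truncated mass of ``eps`` (symmetric) are discarded, so the
    retained fractions sum to at least 1 - eps. A degenerate band
    (tau = 0) gives a single slice of full area.
    """
    tR, tau = band.t, band.tau
    if tau == 0.0:
        n = settings.cycle_of(tR)
        return [
            Slice(
                solute=solute_name,
                cycle=n,
                window=settings.window(n),
                fraction=1.0,
                release_time=settings.next_hot(n),
                state=band,
            )
        ]
    z = _NORMAL.inv_cdf(1.0 - eps / 2.0)
    n_lo = settings.cycle_of(tR - z * tau)
    n_hi = settings.cycle_of(tR + z * tau)
    slices: list[Slice] = []
    for n in range(n_lo, n_hi + 1):
        a, b = settings.window(n)
        frac = _NORMAL.cdf((b - tR) / tau) - _NORMAL.cdf((a - tR) / tau)
        if frac <= 0.0:
            continue
        slices.append(
            Slice(
                solute=solute_name,
                cycle=n,
                window=(a, b),
                fraction=frac,
                release_time=settings.next_hot(n),
                state=band,
            )
        )
    return slices


def release(
    settings: ModulatorSettings,
    sl: Slice,
    graph: SystemGraph,
    field: FlowField,
    edge: CapillaryEdge,
    solute: SoluteRecord,
) -> PeakState:
    """Release a trapped slice at the next hot jet; return its exit state.

    The retention factor is evaluated at the oven temperature plus the
    hot-jet offset; the mobile-phase velocity is taken at the midpoint of
    the modulation segment at the release instant (release is treated as
    quasi-instantaneous, so no window averaging).
    """
    t_hot = settings.next_hot(sl.cycle)
    program = graph.edge_temperature(edge)
    T_oven = program(t_hot)
    k = retention_factor_modulator(
        solute, edge.phase, T_oven, settings.hot_offset, edge.phi
    ) if edge.film > 0 and edge.phase else 0.0
    pin2, pout2, F = field.edge_state(edge.id, t_hot)
    p_mid2 = 0.5 * (pin2 + pout2)
    p_mid = math.sqrt(p_mid2) if p_mid2 > 0 else 0.0
    if p_mid <= 0.0 or F <= 0.0:
        raise FloatingPointError(
            f"no forward flow at modulation point {edge.id} at t={t_hot:.3f}s"
        )
    T_hot = T_oven + settings.hot_offset
    area_cs = math.pi * edge.diameter**2 / 4.0
    u = F * (graph.p_ref / p_mid) * (T_hot / graph.T_ref) / area_cs
    t_migration = edge.length * (1.0 + k) / u
    sl.release_time = t_hot
    return PeakState(
        t=t_hot + t_migration,
        tau2=t_migration**2,
        area=sl.fraction * sl.state.area,
    )
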