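"""Folding slice records into 2D peaks and comparison metrics.

The raw result of a GCxGC simulation is a peak list: one Gaussian per
released slice at the detector. Folding the raw times on the modulation
grid yields, per solute, first-dimension retention time/width (projection
of slice heights onto the modulation-cycle axis) and second-dimension
retention time/width (height-weighted means across slices). The second
dimension width is deliberately the weighted mean of the slice widths, not
the width of the projected distribution, which would be artificially
narrow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .modulator import ModulatorSettings, Slice

__all__ = [
    "SliceRecord",
    "FoldResult",
    "PeakTable2D",
    "fold",
    "records_from_results",
    "project_first_dimension",
    "project_second_dimension",
    "build_peak_table",
    "render_chromatogram",
    "fwhm_halfheight",
    "fwhm_largest",
    "ComparisonMetrics",
    "compare",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class SliceRecord:
    """One slice at the detector: raw time, width, height, provenance."""

    solute: str
    time: float  # raw elution time at the detector, s
    tau: float  # temporal standard deviation, s
    area: float
    n_elute: int  # modulation cycle at detector elution
    release_cycle: int  # cycle in which the slice was (re)injected
    twod_time: float  # raw second-dimension time (wraparound preserved), s
    twod_folded: float  # display value folded into [0, tMP)
    wraparound: bool
    cas: str = ""

    @property
    def height(self) -> float:
        if self.tau > 0.0:
            return self.area / (self.tau * SQRT_2PI)
        return self.area


@dataclass(frozen=True)
class FoldResult:
    n_elute: int
    twod_time: float
    twod_folded: float
    wraparound: bool


def fold(
    t: float, settings: ModulatorSettings, release_cycle: int | None = None
) -> FoldResult:
    """Fold a raw detector time onto the modulation grid.

    ``n_elute`` counts full modulation cycles at elution on the hot-jet
    grid (the grid of reinjection events, translated by tshift + tcold).
    The raw second-dimension time is measured from the hot-jet release of
    the cycle the slice was injected in (wraparound preserved, NOT modulo);
    when the injection cycle is unknown (measured data) the elution cycle
    is assumed. The folded display value wraps into [0, tMP). A slice
    released in cycle n that elutes in cycle n has twod_time < tMP and no
    wraparound; elution in a later cycle sets the wraparound flag.
    """
    if t < 0:
        raise ValueError("raw time must be non-negative")
    n_elute = settings.hot_cycle_of(t)
    if release_cycle is None:
        release_cycle = n_elute
    twod = t - settings.next_hot(release_cycle)
    folded = twod % settings.period
    return FoldResult(
        n_elute=n_elute,
        twod_time=twod,
        twod_folded=folded,
        wraparound=n_elute > release_cycle,
    )


def records_from_results(results, settings: ModulatorSettings) -> list[SliceRecord]:
    """Flatten per-solute PathResults into detector slice records."""
    records: list[SliceRecord] = []
    for res in results:
        if res.censored and not res.slices:
            continue
        for sl in res.slices:
            assert isinstance(sl, Slice)
            f = fold(sl.state.t, settings, release_cycle=sl.cycle)
            records.append(
                SliceRecord(
                    solute=res.solute,
                    time=sl.state.t,
                    tau=sl.state.tau,
                    area=sl.state.area,
                    n_elute=f.n_elute,
                    release_cycle=sl.cycle,
                    twod_time=f.twod_time,
                    twod_folded=f.twod_folded,
                    wraparound=f.wraparound,
                )
            )
    return records


def project_first_dimension(
    records: list[SliceRecord], settings: ModulatorSettings
) -> tuple[float, float]:
    """Height-weighted first-dimension retention time and width of one solute.

    The first-dimension time of a slice is the number of modulations at
    elution times tMP; the peak profile is the height-weighted distribution
    over those times. Returns (1tR, 1tauR).
    """
    if not records:
        raise ValueError("no slices to project")
    h = np.array([r.height for r in records])
    total = h.sum()
    if total <= 0:
        raise ValueError("zero total height in first-dimension projection")
    t1 = np.array([r.n_elute * settings.period for r in records])
    mean = float((h * t1).sum() / total)
    var = float((h * (t1 - mean) ** 2).sum() / total)
    return mean, math.sqrt(max(var, 0.0))


def project_second_dimension(records: list[SliceRecord]) -> tuple[float, float]:
    """Height-weighted second-dimension retention time and width.

    2tR is the weighted mean of the raw per-slice second-dimension times;
    2tauR is the weighted mean of the slice widths (the projected
    distribution itself is degenerately narrow).
    """
    if not records:
        raise ValueError("no slices to project")
    h = np.array([r.height for r in records])
    total = h.sum()
    if total <= 0:
        raise ValueError("zero total height in second-dimension projection")
    t2 = float((h * np.array([r.twod_time for r in records])).sum() / total)
    tau2 = float((h * np.array([r.tau for r in records])).sum() / total)
    return t2, tau2


@dataclass
class PeakTable2D:
    """Per-solute 2D retention times/widths plus the raw slice records."""

    table: pd.DataFrame
    records: list[SliceRecord] = dataclass_field(default_factory=list)
    period: float = float("nan")

    COLUMNS = (
        "solute",
        "cas",
        "tR1",
        "tauR1",
        "tR2",
        "tauR2",
        "n_slices",
        "wraparound",
        "area",
    )

    def to_csv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, index=False, float_format="%.9f")

    @classmethod
    def from_csv(
        cls, path, column_map: dict[str, str] | None = None
    ) -> "PeakTable2D":
        df = pd.read_csv(path, comment="#")
        if column_map:
            df = df.rename(columns=column_map)
        missing = [c for c in ("solute", "tR1", "tR2") if c not in df.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        for col in cls.COLUMNS:
            if col not in df.columns:
                df[col] = "" if col in ("cas",) else np.nan
        df["cas"] = df["cas"].fillna("").astype(str)
        return cls(table=df[list(cls.COLUMNS)])


def build_peak_table(
    records: list[SliceRecord],
    settings: ModulatorSettings,
    cas_by_solute: dict[str, str] | None = None,
) -> PeakTable2D:
    """Fold a slice list into the per-solute 2D peak table."""
    rows = []
    by_solute: dict[str, list[SliceRecord]] = {}
    for r in records:
        by_solute.setdefault(r.solute, []).append(r)
    for solute, recs in by_solute.items():
        t1, tau1 = project_first_dimension(recs, settings)
        t2, tau2 = project_second_dimension(recs)
        rows.append(
            {
                "solute": solute,
                "cas": (cas_by_solute or {}).get(solute, ""),
                "tR1": t1,
                "tauR1": tau1,
                "tR2": t2,
                "tauR2": tau2,
                "n_slices": len(recs),
                "wraparound": any(r.wraparound for r in recs),
                "area": sum(r.area for r in recs),
            }
        )
    table = pd.DataFrame(rows, columns=list(PeakTable2D.COLUMNS))
    return PeakTable2D(table=table, records=records, period=settings.period)


def render_chromatogram(
    records: list[SliceRecord],
    rate: float,
    period: float,
    t_end: float | None = None,
):
    """Render the raw detector signal and its folded 2D matrix.

    Returns (t, signal, matrix): the raw signal is the sum of the slice
    Gaussians sampled at ``rate`` Hz; the matrix is the signal reshaped into
    rows of one modulation period (row length = round(tMP * rate)), the
    conventional GCxGC presentation.
    """
    if not records:
        raise ValueError("no slices to render")
    row_len = round(period * rate)
    if t_end is None:
        t_end = max(r.time + 6.0 * max(r.tau, 1.0 / rate) for r in records)
    n_rows = math.ceil(t_end / period)
    n = n_rows * row_len
    t = np.arange(n) / rate
    signal = np.zeros(n)
    for r in records:
        tau = max(r.tau, 1e-12)
        lo = np.searchsorted(t, r.time - 8.0 * tau)
        hi = np.searchsorted(t, r.time + 8.0 * tau)
        signal[lo:hi] += r.height * np.exp(
            -0.5 * ((t[lo:hi] - r.time) / tau) ** 2
        )
    matrix = signal.reshape(n_rows, row_len)
    return t, signal, matrix


def plot_chromatogram(
    records: list[SliceRecord],
    rate: float,
    period: float,
    path,
    t_end: float | None = None,
) -> None:
    """Minimal 2D contour rendering of the folded chromatogram to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _, _, matrix = render_chromatogram(records, rate, period, t_end=t_end)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(
        matrix.T,
        origin="lower",
        aspect="auto",
        extent=(0.0, matrix.shape[0] * period, 0.0, period),
        cmap="viridis",
    )
    ax.set_xlabel("first-dimension time / s")
    ax.set_ylabel("second-dimension time / s")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fwhm_halfheight(t: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation at half height."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    i_max = int(np.argmax(y))
    peak = y[i_max]
    if peak <= 0:
        raise ValueError("trace has no maximum above baseline")
    half = peak / 2.0
    left = None
    for i in range(i_max, 0, -1):
        if y[i - 1] <= half <= y[i]:
            left = t[i - 1] + (half - y[i - 1]) / (y[i] - y[i - 1]) * (t[i] - t[i - 1])
            break
    right = None
    for i in range(i_max, len(y) - 1):
        if y[i] >= half >= y[i + 1]:
            right = t[i] + (y[i] - half) / (y[i] - y[i + 1]) * (t[i + 1] - t[i])
            break
    if left is None or right is None:
        raise ValueError("no half-height crossing found on one side of the peak")
    return float(right - left)


def fwhm_largest(traces: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Largest per-slice FWHM (the measured 2FWHM convention)."""
    if not traces:
        raise ValueError("no traces")
    return max(fwhm_halfheight(t, y) for t, y in traces)


@dataclass
class ComparisonMetrics:
    """rmse / rmsre of retention times and widths, per dimension."""

    n_matched: int
    unmatched: list[str]
    rmse_tR1: float
    rmsre_tR1: float
    rmse_tR2: float
    rmsre_tR2: float
    rmse_tauR1: float = float("nan")
    rmsre_tauR1: float = float("nan")
    rmse_tauR2: float = float("nan")
    rmsre_tauR2: float = float("nan")


def _rmse_rmsre(meas: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    diff = meas - pred
    rmse = float(np.sqrt(np.mean(diff**2)))
    nz = meas != 0
    if not np.all(nz):
        warnings.warn("pairs with measured value 0 excluded from rmsre", stacklevel=3)
    if np.any(nz):
        rmsre = float(np.sqrt(np.mean((diff[nz] / meas[nz]) ** 2)))
    else:
        rmsre = float("nan")
    return rmse, rmsre


def compare(predicted: PeakTable2D, measured: PeakTable2D) -> ComparisonMetrics:
    """rmse and rmsre between predicted and measured 2D peak tables.

    Solutes are matched by CAS number when both sides carry one, else by
    exact name; unmatched solutes are reported and excluded.
    """
    pred = predicted.table.copy()
    meas = measured.table.copy()

    def cas_col(df):
        cas = df["cas"].astype(str).str.strip()
        return cas.where((cas != "") & (cas != "nan"), other="")

    pred = pred.assign(_cas=cas_col(pred))
    meas = meas.assign(_cas=cas_col(meas))
    by_cas = pred[pred._cas != ""].merge(
        meas[meas._cas != ""], on="_cas", suffixes=("_p", "_m")
    )
    rest_p = pred[~pred._cas.isin(set(by_cas._cas))]
    rest_m = meas[~meas._cas.isin(set(by_cas._cas))]
    by_name = rest_p.merge(rest_m, on="solute", suffixes=("_p", "_m"))
    merged = pd.concat([by_cas, by_name], ignore_index=True)
    if merged.empty:
        raise ValueError("no common solutes between predicted and measured tables")
    matched_p = set(by_cas.get("solute_p", pd.Series(dtype=str))) | set(
        by_name["solute"]
    )
    matched_m = set(by_cas.get("solute_m", pd.Series(dtype=str))) | set(
        by_name["solute"]
    )
    unmatched = sorted(
        (set(pred["solute"]) - matched_p) | (set(meas["solute"]) - matched_m)
    )
    out = {}
    for col in ("tR1", "tR2", "tauR1", "tauR2"):
        m = merged[f"{col}_m"].to_numpy(dtype=float)
        p = merged[f"{col}_p"].to_numpy(dtype=float)
        ok = np.isfinite(m) & np.isfinite(p)
        if ok.any():
            out[f"rmse_{col}"], out[f"rmsre_{col}"] = _rmse_rmsre(m[ok], p[ok])
    return ComparisonMetrics(
        n_matched=len(merged), unmatched=list(unmatched), **out
    )
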