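import math

import numpy as np
import pandas as pd
import pytest

from gcxgcsim.migration import PeakState
from gcxgcsim.modulator import ModulatorSettings, slice_band
from gcxgcsim.projection import (
    PeakTable2D,
    SliceRecord,
    build_peak_table,
    compare,
    fold,
    fwhm_halfheight,
    fwhm_largest,
    project_first_dimension,
    project_second_dimension,
    render_chromatogram,
)


@pytest.fixture
def settings():
    return ModulatorSettings(period=4.0, shift=0.0, hot_duration=0.35, hot_offset=25.0)


def record(solute="s", time=10.0, tau=0.01, area=1.0, n_elute=2, release_cycle=2,
           twod=0.8, wraparound=False):
    return SliceRecord(
        solute=solute, time=time, tau=tau, area=area, n_elute=n_elute,
        release_cycle=release_cycle, twod_time=twod, twod_folded=twod % 4.0,
        wraparound=wraparound,
    )


class TestFold:
    def test_elution_cycle_counting(self, settings):
        # 2.5 periods past the hot-jet grid anchor -> cycle 2
        t = settings.shift + settings.cold_duration + 2.5 * settings.period
        assert fold(t, settings).n_elute == 2

    def test_same_cycle_elution_no_wraparound(self, settings):
        n = 7
        t = settings.next_hot(n) + 0.9 * settings.period
        f = fold(t, settings, release_cycle=n)
        assert f.twod_time < settings.period
        assert not f.wraparound
        assert f.twod_time == pytest.approx(0.9 * settings.period)

    def test_wraparound_preserved_not_modulo(self, settings):
        n = 7
        t = settings.next_hot(n) + 1.3 * settings.period
        f = fold(t, settings, release_cycle=n)
        assert f.wraparound
        assert f.twod_time == pytest.approx(1.3 * settings.period)
        assert f.twod_folded == pytest.approx(f.twod_time - settings.period)

    def test_negative_time_rejected(self, settings):
        with pytest.raises(ValueError):
            fold(-1.0, settings)


class TestFirstDimensionProjection:
    def test_single_slice(self, settings):
        t1, tau1 = project_first_dimension([record(n_elute=5)], settings)
        assert t1 == 5 * settings.period
        assert tau1 == 0.0

    def test_two_equal_slices(self, settings):
        recs = [record(n_elute=5), record(n_elute=6)]
        t1, tau1 = project_first_dimension(recs, settings)
        assert t1 == pytest.approx(5.5 * settings.period)
        assert tau1 == pytest.approx(settings.period / 2.0)

    def test_weights_are_heights(self, settings):
        # same area, different widths -> the narrow slice dominates
        recs = [
            record(n_elute=5, tau=0.01, area=1.0),
            record(n_elute=6, tau=0.03, area=1.0),
        ]
        t1, _ = project_first_dimension(recs, settings)
        w = np.array([1.0 / 0.01, 1.0 / 0.03])
        expected = (w * np.array([20.0, 24.0])).sum() / w.sum()
        assert t1 == pytest.approx(expected)

    def test_order_invariance(self, settings):
        recs = [record(n_elute=n, area=a) for n, a in ((3, 0.2), (4, 0.5), (5, 0.3))]
        fwd = project_first_dimension(recs, settings)
        rev = project_first_dimension(recs[::-1], settings)
        assert fwd[0] == pytest.approx(rev[0], rel=1e-12)
        assert fwd[1] == pytest.approx(rev[1], rel=1e-12)

    def test_gaussian_band_recovery_within_half_period(self, settings):
        """End-to-end slicing of a Gaussian band recovers its center to
        within tMP/2 after projection."""
        center = 37.3 + settings.next_hot(0)
        tau = settings.period  # tMP = tau
        band = PeakState(t=center, tau2=tau**2)
        recs = []
        for sl in slice_band(settings, band, solute_name="s"):
            recs.append(
                record(n_elute=sl.cycle, area=sl.fraction, tau=0.01,
                       time=sl.release_time)
            )
        t1, _ = project_first_dimension(recs, settings)
        # the records place each slice in its collection-window cycle, so
        # the continuous reference is the window-quantized band center
        center_cycle_time = settings.cycle_of(center) * settings.period
        assert abs(t1 - center_cycle_time) <= settings.period / 2.0

    def test_fine_modulation_converges_to_band_center(self):
        """As tMP shrinks well below the band width, the projected 1tR
        approaches the unmodulated elution time."""
        tau = 5.0
        center = 103.7
        s = ModulatorSettings(period=tau / 10.0, hot_duration=0.05)
        band = PeakState(t=center, tau2=tau**2)
        recs = [
            record(n_elute=sl.cycle, area=sl.fraction, tau=0.01)
            for sl in slice_band(s, band, solute_name="s")
        ]
        t1, _ = project_first_dimension(recs, s)
        assert abs(t1 - center) < s.period

    def test_zero_height_rejected(self, settings):
        with pytest.raises(ValueError):
            project_first_dimension([record(area=0.0)], settings)


class TestSecondDimensionProjection:
    def test_identical_slices(self):
        recs = [record(twod=1.2, tau=0.02)] * 3
        t2, tau2 = project_second_dimension(recs)
        assert t2 == pytest.approx(1.2)
        assert tau2 == pytest.approx(0.02)

    def test_width_is_weighted_mean_of_widths(self):
        # widths 10/30 ms with heights 3:1 -> mean width 15 ms
        recs = [
            record(twod=1.0, tau=0.010, area=0.010 * 3.0),  # height 3
            record(twod=1.0, tau=0.030, area=0.030 * 1.0),  # height 1
        ]
        _, tau2 = project_second_dimension(recs)
        assert tau2 == pytest.approx(0.015, rel=1e-12)

    def test_spreadsheet_style_weighted_means(self, settings):
        rng = np.random.default_rng(2)
        recs = [
            record(n_elute=int(n), twod=float(t2), tau=float(tau), area=float(a))
            for n, t2, tau, a in zip(
                range(5, 10),
                rng.uniform(0.5, 1.5, 5),
                rng.uniform(0.005, 0.05, 5),
                rng.uniform(0.1, 1.0, 5),
            )
        ]
        heights = np.array([r.area / (r.tau * math.sqrt(2 * math.pi)) for r in recs])
        t2_hand = (heights * np.array([r.twod_time for r in recs])).sum() / heights.sum()
        tau2_hand = (heights * np.array([r.tau for r in recs])).sum() / heights.sum()
        t2, tau2 = project_second_dimension(recs)
        assert t2 == pytest.approx(t2_hand, rel=1e-12)
        assert tau2 == pytest.approx(tau2_hand, rel=1e-12)


class TestRenderChromatogram:
    def test_signal_integral_matches_total_area(self, settings):
        recs = [
            record(time=10.0, tau=0.05, area=0.7),
            record(time=14.5, tau=0.08, area=0.3),
        ]
        t, signal, _ = render_chromatogram(recs, rate=200.0, period=4.0)
        integral = np.trapezoid(signal, t)
        assert integral == pytest.approx(1.0, rel=1e-3)

    def test_matrix_reshape_is_exact_inverse(self, settings):
        recs = [record(time=9.0, tau=0.05)]
        t, signal, matrix = render_chromatogram(recs, rate=100.0, period=4.0)
        assert matrix.shape[1] == 400
        np.testing.assert_array_equal(matrix.ravel(), signal)

    def test_single_slice_peak_position(self):
        recs = [record(time=10.0, tau=0.05)]
        t, signal, _ = render_chromatogram(recs, rate=500.0, period=4.0)
        assert abs(t[int(np.argmax(signal))] - 10.0) <= 1.0 / 500.0


def test_plot_chromatogram_writes_figure(tmp_path):
    from gcxgcsim.projection import plot_chromatogram

    recs = [record(time=9.0, tau=0.05), record(time=13.2, tau=0.03, twod=1.1)]
    out = tmp_path / "chrom.png"
    plot_chromatogram(recs, rate=100.0, period=4.0, path=out)
    assert out.exists() and out.stat().st_size > 0


class TestFWHM:
    def test_gaussian_identity(self):
        t = np.arange(0.0, 20.0, 0.01)
        y = np.exp(-0.5 * (t - 10.0) ** 2)
        assert fwhm_halfheight(t, y) == pytest.approx(
            2.0 * math.sqrt(2.0 * math.log(2.0)), abs=0.01
        )

    def test_largest_slice_rule(self):
        t = np.arange(0.0, 2.0, 1e-4)
        make = lambda tau: np.exp(-0.5 * ((t - 1.0) / tau) ** 2)
        widths = [fwhm_halfheight(t, make(0.040)), fwhm_halfheight(t, make(0.080))]
        assert fwhm_largest([(t, make(0.040)), (t, make(0.080))]) == max(widths)
        assert max(widths) == pytest.approx(0.080 * 2.3548, rel=1e-3)

    def test_sparse_sampling_tolerance(self):
        """Five points across a peak still give the FWHM within 20%: the
        documented uncertainty of half-height estimates on sparse data."""
        tau = 1.0
        true = 2.3548 * tau
        t = np.linspace(-3.0, 3.0, 5)  # ~5 samples across the peak
        y = np.exp(-0.5 * (t / tau) ** 2)
        got = fwhm_halfheight(t, y)
        assert got == pytest.approx(true, rel=0.20)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            fwhm_halfheight(np.arange(5.0), np.zeros(5))


class TestCompare:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=list(PeakTable2D.COLUMNS))
        return PeakTable2D(table=df)

    def _row(self, name, t1, t2, cas="", tau1=1.0, tau2=0.02):
        return {
            "solute": name, "cas": cas, "tR1": t1, "tauR1": tau1, "tR2": t2,
            "tauR2": tau2, "n_slices": 3, "wraparound": False, "area": 1.0,
        }

    def test_identical_tables_zero_error(self):
        tab = self._table([self._row("a", 100.0, 1.0), self._row("b", 200.0, 2.0)])
        m = compare(tab, tab)
        assert m.rmse_tR1 == 0.0 and m.rmse_tR2 == 0.0
        assert m.rmsre_tR1 == 0.0 and m.rmsre_tR2 == 0.0

    def test_single_pair_offset(self):
        pred = self._table([self._row("a", 100.0, 1.0)])
        meas = self._table([self._row("a", 100.0, 1.1)])
        assert compare(pred, meas).rmse_tR2 == pytest.approx(0.1)

    def test_three_pairs_hand_computed(self):
        pred = self._table(
            [self._row("a", 100.0, 1.0), self._row("b", 200.0, 2.0),
             self._row("c", 300.0, 3.0)]
        )
        meas = self._table(
            [self._row("a", 101.0, 1.2), self._row("b", 198.0, 1.9),
             self._row("c", 303.0, 3.3)]
        )
        rmse_hand = math.sqrt((1.0**2 + 2.0**2 + 3.0**2) / 3.0)
        m = compare(pred, meas)
        assert m.rmse_tR1 == pytest.approx(rmse_hand, rel=1e-12)
        rmsre_hand = math.sqrt(
            ((1 / 101) ** 2 + (2 / 198) ** 2 + (3 / 303) ** 2) / 3.0
        )
        assert m.rmsre_tR1 == pytest.approx(rmsre_hand, rel=1e-12)

    def test_matching_prefers_cas_then_name(self):
        pred = self._table([self._row("methyl myristate", 100.0, 1.0, cas="124-10-7")])
        meas = self._table([self._row("Methyl tetradecanoate", 101.0, 1.1, cas="124-10-7")])
        m = compare(pred, meas)
        assert m.n_matched == 1

    def test_unmatched_reported_and_excluded(self):
        pred = self._table([self._row("a", 100.0, 1.0), self._row("x", 50.0, 0.5)])
        meas = self._table([self._row("a", 100.0, 1.0), self._row("y", 60.0, 0.6)])
        m = compare(pred, meas)
        assert m.n_matched == 1
        assert set(m.unmatched) == {"x", "y"}

    def test_empty_intersection_rejected(self):
        pred = self._table([self._row("a", 100.0, 1.0)])
        meas = self._table([self._row("b", 100.0, 1.0)])
        with pytest.raises(ValueError):
            compare(pred, meas)


class TestPeakTableIO:
    def test_csv_round_trip(self, tmp_path, settings):
        recs = [record(n_elute=4), record(n_elute=5, solute="t", twod=1.6)]
        tab = build_peak_table(recs, settings)
        path = tmp_path / "peaks.csv"
        tab.to_csv(path, header_lines=["demo"])
        back = PeakTable2D.from_csv(path)
        pd.testing.assert_frame_equal(
            back.table.astype({"wraparound": bool}),
            tab.table,
            check_dtype=False,
            check_exact=False,
            atol=1e-9,
        )
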