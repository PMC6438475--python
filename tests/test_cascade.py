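import numpy as np
import pytest
from hypothesis import given, strategies as st

from cytocascade import (AnalysisConfig, Cohort, NoElevationError, align_set,
                         analyze_series, compute_auc, detect_onset, detect_peak,
                         fit_curve, onset_table)
from cytocascade.cascade import AlignedCurve, corrected_values

from conftest import piecewise_linear_series


class TestDetectPeak:
    def test_triangle_peak(self, triangle_series, config):
        curve = fit_curve(triangle_series, config)
        peak = detect_peak(curve, config)
        assert peak.t_peak == 200
        assert peak.peak_amp == pytest.approx(100, abs=1e-9)
        assert not peak.effective_peak_is_last
        assert peak.baseline == pytest.approx(0, abs=1e-12)

    def test_monotone_rise_uses_last_value_as_effective_peak(self, config):
        s = piecewise_linear_series([(150, 0), (300, 60)])
        peak = detect_peak(fit_curve(s, config), config)
        assert peak.effective_peak_is_last
        assert peak.t_peak == 300
        assert peak.peak_amp == pytest.approx(60, abs=1e-9)

    def test_flat_series_is_no_elevation(self, config):
        t = np.arange(-30, 301, 30, dtype=float)
        s = piecewise_linear_series([(0, 2), (300, 2)])
        s.conc[:] = 2.0
        with pytest.raises(NoElevationError):
            detect_peak(fit_curve(s, config), config)

    def test_first_of_two_peaks_wins(self, config):
        s = piecewise_linear_series(
            [(100, 0), (120, 80), (180, 20), (250, 100), (300, 0)])
        peak = detect_peak(fit_curve(s, config), config)
        assert peak.t_peak == 120
        assert peak.peak_amp == pytest.approx(80, abs=1e-9)

    def test_low_prominence_jitter_not_a_peak(self, config):
        # small 5% bump at t=50 must not preempt the main peak at 200
        s = piecewise_linear_series(
            [(30, 0), (50, 5), (70, 0), (100, 0), (200, 100), (300, 0)])
        peak = detect_peak(fit_curve(s, config), config)
        assert peak.t_peak == 200


class TestDetectOnset:
    def test_triangle_5pct_crossing(self, triangle_series, config):
        curve = fit_curve(triangle_series, config)
        res = detect_onset(curve, detect_peak(curve, config), config)
        assert res.threshold_value == pytest.approx(5.0, abs=1e-9)
        assert res.t_onset == 105  # 1 pg/mL/min rise from t=100
        assert res.t_onset <= res.t_peak

    def test_monotone_rise_crossing_rounds_up(self, config):
        # rate 0.4 pg/mL/min from t=150, effective peak 60 at t=300:
        # threshold 3 crossed at 157.5 -> first grid minute at or above is 158
        s = piecewise_linear_series([(150, 0), (300, 60)])
        curve = fit_curve(s, config)
        res = detect_onset(curve, detect_peak(curve, config), config)
        assert res.t_onset == 158

    def test_two_peak_shape_uses_first_peak_threshold(self, config):
        # first peak amp 80 -> threshold 4; rise 4 pg/mL/min from t=100
        s = piecewise_linear_series(
            [(100, 0), (120, 80), (180, 20), (250, 100), (300, 0)])
        curve = fit_curve(s, config)
        res = detect_onset(curve, detect_peak(curve, config), config)
        assert res.threshold_value == pytest.approx(4.0, abs=1e-9)
        assert res.t_onset == 101

    def test_left_censored_when_already_elevated(self, config):
        s = piecewise_linear_series([(-30, 50), (100, 100), (300, 0)])
        curve = fit_curve(s, AnalysisConfig(baseline_mode="raw"))
        peak = detect_peak(curve, AnalysisConfig(baseline_mode="raw"))
        with pytest.warns(UserWarning, match="left-censored"):
            res = detect_onset(curve, peak, AnalysisConfig(baseline_mode="raw"))
        assert res.left_censored
        assert res.t_onset == -30


class TestAlignAndAuc:
    def test_shifted_identical_pulses_align_pointwise(self, config):
        a = piecewise_linear_series([(60, 0), (120, 90), (200, 0)])
        b = piecewise_linear_series([(97, 0), (157, 90), (237, 0)])  # +37 min
        fa, fb = analyze_series(a, config), analyze_series(b, config)
        aset = align_set([fa, fb], config)
        na = len(aset.curves[0].times)
        assert np.allclose(aset.curves[0].values[:na], aset.curves[1].values[:na],
                           atol=1e-6)
        assert aset.aucs[0] == pytest.approx(aset.aucs[1], rel=1e-6)

    def test_common_duration_is_minimum_span(self, config):
        a = piecewise_linear_series([(120, 0), (200, 100), (300, 0)])  # onset ~120
        b = piecewise_linear_series([(160, 0), (240, 100), (300, 20)])  # onset ~160
        fa, fb = analyze_series(a, config), analyze_series(b, config)
        aset = align_set([fa, fb], config)
        expected = min(300 - fa[1].t_onset, 300 - fb[1].t_onset)
        assert aset.common_duration == expected
        for c in aset.curves:
            assert c.times[0] == 0 and c.times[-1] == aset.common_duration

    def test_single_member_spans_own_duration(self, config):
        a = piecewise_linear_series([(100, 0), (200, 100), (300, 0)])
        fa = analyze_series(a, config)
        aset = align_set([fa], config)
        assert aset.common_duration == 300 - fa[1].t_onset

    def test_empty_set_rejected(self, config):
        with pytest.raises(ValueError):
            align_set([], config)

    def test_auc_constant_and_triangle(self):
        t = np.arange(0, 101, 1.0)
        const = AlignedCurve(times=t, values=np.full(101, 10.0), source=None, onset=None)
        assert compute_auc(const, 100) == pytest.approx(1000)
        tri = AlignedCurve(times=t, values=t.copy(), source=None, onset=None)
        assert compute_auc(tri, 100) == pytest.approx(5000)

    def test_auc_sine_matches_analytic_within_0p1pct(self):
        t = np.arange(0, 241, 1.0)
        y = 100 * np.sin(np.pi * t / 240)
        curve = AlignedCurve(times=t, values=y, source=None, onset=None)
        exact = 100 * 2 * 240 / np.pi
        assert compute_auc(curve, 240) == pytest.approx(exact, rel=1e-3)

    def test_non_positive_duration_rejected(self):
        c = AlignedCurve(times=np.arange(5.0), values=np.ones(5), source=None, onset=None)
        with pytest.raises(ValueError):
            compute_auc(c, 0)


class TestOnsetTable:
    def test_two_animal_summary(self, config):
        series = [
            piecewise_linear_series([(40, 0), (140, 100), (240, 0)],
                                    animal="r1", cytokine="IL-10"),
            piecewise_linear_series([(60, 0), (160, 100), (260, 0)],
                                    animal="r2", cytokine="IL-10"),
        ]
        tab = onset_table(Cohort(series), config)
        row = tab.iloc[0]
        onsets = row["mean_onset_min"]
        assert row["n"] == 2
        assert row["sd_onset_min"] == pytest.approx(
            np.std([42, 62], ddof=1), abs=0.5)  # ~14.14 for a 20-min shift
        assert row["sem_onset_min"] == pytest.approx(row["sd_onset_min"] / np.sqrt(2))

    def test_no_elevation_reduces_n(self, config):
        flat = piecewise_linear_series([(0, 2), (300, 2)], animal="r3",
                                       cytokine="IL-10")
        flat.conc[:] = 2.0
        series = [
            piecewise_linear_series([(40, 0), (140, 100), (240, 0)],
                                    animal="r1", cytokine="IL-10"),
            piecewise_linear_series([(60, 0), (160, 100), (260, 0)],
                                    animal="r2", cytokine="IL-10"),
            flat,
        ]
        tab = onset_table(Cohort(series), config)
        assert tab.iloc[0]["n"] == 2
        assert tab.iloc[0]["n_excluded"] == 1


def _pulse_series(t0, amp, animal="r1"):
    return piecewise_linear_series(
        [(t0, 0), (t0 + 80, amp), (t0 + 160, 0)], animal=animal)


class TestChainProperties:
    @given(st.integers(-60, 60), st.integers(20, 120))
    def test_time_shift_invariance(self, delta, t0):
        cfg = AnalysisConfig(baseline_mode="raw")
        a = piecewise_linear_series([(t0, 0), (t0 + 80, 100), (t0 + 160, 0)])
        b = piecewise_linear_series(
            [(t0 + delta, 0), (t0 + delta + 80, 100), (t0 + delta + 160, 0)],
            t_first=-30 + delta, t_last=300 + delta)
        (ca, oa), (cb, ob) = analyze_series(a, cfg), analyze_series(b, cfg)
        assert ob.t_onset == oa.t_onset + delta
        assert ob.t_peak == oa.t_peak + delta
        assert ob.peak_amp == pytest.approx(oa.peak_amp, rel=1e-9)
        sa = align_set([(ca, oa)], cfg)
        sb = align_set([(cb, ob)], cfg)
        assert sb.common_duration == sa.common_duration
        assert sb.aucs[0] == pytest.approx(sa.aucs[0], rel=1e-9)

    @given(c=st.floats(0.05, 50))
    def test_concentration_scale_equivariance(self, c):
        config = AnalysisConfig()
        a = _pulse_series(90, 100)
        b = _pulse_series(90, 100)
        b.conc = b.conc * c
        (ca, oa), (cb, ob) = analyze_series(a, config), analyze_series(b, config)
        assert ob.t_onset == oa.t_onset  # 5% rule is relative
        assert ob.peak_amp == pytest.approx(oa.peak_amp * c, rel=1e-9)
        assert ob.threshold_value == pytest.approx(oa.threshold_value * c, rel=1e-9)
        sa, sb = align_set([(ca, oa)], config), align_set([(cb, ob)], config)
        assert sb.aucs[0] == pytest.approx(sa.aucs[0] * c, rel=1e-9)

    @given(st.sampled_from([0.05, 0.1, 0.2, 0.4]), st.sampled_from([0.05, 0.1, 0.2, 0.4]))
    def test_onset_monotone_in_fraction(self, f1, f2):
        lo, hi = min(f1, f2), max(f1, f2)
        s = _pulse_series(70, 100)
        curve = fit_curve(s, AnalysisConfig())
        t_lo = detect_onset(curve, detect_peak(curve), AnalysisConfig(onset_fraction=lo)).t_onset
        t_hi = detect_onset(curve, detect_peak(curve), AnalysisConfig(onset_fraction=hi)).t_onset
        assert t_lo <= t_hi

    def test_sustained_equals_first_touch_on_noise_free(self, config):
        # on a monotone rise the sustained rule coincides with first touch
        s = _pulse_series(100, 100)
        curve = fit_curve(s, config)
        res = detect_onset(curve, detect_peak(curve, config), config)
        y, _ = corrected_values(curve, config)
        first_touch = curve.grid[np.argmax(y >= res.threshold_value)]
        assert res.t_onset == first_touch
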