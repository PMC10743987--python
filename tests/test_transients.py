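"""Per-beat metric extraction: baselines, peaks, rises, taus, contraction,
coupling and the whole-run driver."""

import math

import numpy as np
import pytest

from ecckymo import (AnalysisConfig, Kymograph, RunRejected, SimCellParams,
                     analyze_run, analyze_trace, contraction_metrics,
                     coupling_metrics, detect_first_peak, detect_rise_start,
                     estimate_baseline, simulate_cell, transient_metrics,
                     ContractionContext, TransientMetrics)
from ecckymo.errors import BaselineError
from ecckymo.segment import WidthTrace

H = 1.0  # convenient line period for synthetic traces


def cfg(**kw):
    kw.setdefault("pacing_hz", 1.0)
    return AnalysisConfig(**kw)


def tm(t_rise, t_peak):
    return TransientMetrics(f0=1, noise_sd=0, dff_max=1, rise_time_ms=0,
                            tau50_ms=0, tau90_ms=0, t_rise_ms=t_rise,
                            t_peak_ms=t_peak, f_peak=2)


class TestBaseline:
    def test_constant_trace(self):
        f0, sd = estimate_baseline(np.full(300, 5.0), cfg(), line_period_ms=H)
        assert (f0, sd) == (5.0, 0.0)

    def test_median_is_outlier_robust(self):
        trace = np.full(300, 5.0)
        trace[50] = 500.0
        f0, _ = estimate_baseline(trace, cfg(), line_period_ms=H, end_line=120)
        assert f0 == 5.0

    def test_noise_sd_recovered_from_gaussian(self, rng):
        trace = 1.0 + 0.1 * rng.standard_normal(400)
        _, sd = estimate_baseline(trace, cfg(baseline_window_ms=400),
                                  line_period_ms=H)
        assert sd == pytest.approx(0.1, abs=0.02)

    def test_short_window_raises(self):
        with pytest.raises(BaselineError, match="search_start"):
            estimate_baseline(np.ones(300), cfg(), line_period_ms=H,
                              end_line=10)


class TestPeakDetection:
    def test_triangular_pulse_apex(self):
        trace = np.ones(1000)
        trace[100:120] += np.linspace(0, 1, 20)
        trace[120:140] += np.linspace(1, 0, 20)
        t, v = detect_first_peak(trace, cfg(), line_period_ms=H)
        assert t == 119.0 and v == pytest.approx(2.0)

    def test_tie_breaks_to_earliest_line(self):
        trace = np.ones(1000)
        trace[[200, 400]] = 3.0
        t, _ = detect_first_peak(trace, cfg(), line_period_ms=H)
        assert t == 200.0

    def test_matches_windowed_argmax_oracle(self, rng):
        """1000 random traces: detection equals brute-force argmax."""
        config = cfg(search_start_ms=25, pacing_hz=1000.0 / 50.0)
        for _ in range(1000):
            trace = rng.random(120)
            t, v = detect_first_peak(trace, config, line_period_ms=H)
            window = trace[25:75]
            assert t == 25 + int(np.argmax(window))
            assert v == window.max()

    def test_flat_trace_rejected_as_no_transient(self):
        with pytest.raises(RunRejected) as err:
            detect_first_peak(np.ones(1000), cfg(), line_period_ms=H,
                              f0=1.0, noise_sd=0.0)
        assert err.value.reason_code == "no_transient"


class TestRiseDetection:
    def test_step_function_onset(self):
        trace = np.ones(400)
        trace[100:] = 2.0
        t, fallback = detect_rise_start(trace, 1.0, 0.0, cfg(),
                                        line_period_ms=H, peak_line=200)
        assert t == 100.0 and not fallback

    def test_linear_ramp_onset_within_one_line(self):
        trace = np.ones(400)
        trace[150:250] = 1 + np.linspace(0, 1, 100)
        t, _ = detect_rise_start(trace, 1.0, 0.0, cfg(), line_period_ms=H,
                                 peak_line=249)
        assert abs(t - 150.0) <= 1.0 + 1e-9

    def test_manual_shift_applied(self):
        trace = np.ones(400)
        trace[100:] = 2.0
        t, _ = detect_rise_start(trace, 1.0, 0.0, cfg(rise_shift_lines=-3),
                                 line_period_ms=H, peak_line=200)
        assert t == 97.0

    def test_no_sustained_crossing_falls_back_flagged(self):
        # never exceeds baseline + k*sigma: the last sub-threshold line
        # before the peak is used and the beat is flagged
        trace = np.linspace(1.0, 1.1, 200)
        t, fallback = detect_rise_start(trace, 2.5, 1.0, cfg(),
                                        line_period_ms=H, peak_line=199)
        assert fallback
        assert t == 198.0


class TestTransientMetrics:
    def decay_trace(self, tau=100.0, f0=1.0, amp=1.08, rise=20, n=2000):
        t = np.arange(n) * H
        trace = np.full(n, f0)
        trace[100:100 + rise] = f0 + amp * f0 * np.arange(rise) / rise
        dt = t[100 + rise:] - t[100 + rise]
        trace[100 + rise:] = f0 + amp * f0 * np.exp(-dt / tau)
        return trace

    def test_dff_max_ratio(self):
        """F0 = 1 peaking at 2.08 gives dF/F0 = 1.08."""
        trace = self.decay_trace()
        m = transient_metrics(trace, cfg(), line_period_ms=H, f0=1.0,
                              noise_sd=0.0, peak_line=120, rise_line=100)
        assert m.dff_max == pytest.approx(1.08, rel=5e-3)
        assert m.rise_time_ms == pytest.approx(20.0, abs=1.0)

    def test_tau_closed_form_for_exponential(self):
        """Pure exponential, tau = 100 ms: tau50 = 69.3, tau90 = 230.3."""
        trace = self.decay_trace(tau=100.0)
        m = transient_metrics(trace, cfg(), line_period_ms=H, f0=1.0,
                              noise_sd=0.0, peak_line=120, rise_line=100)
        assert m.tau50_ms == pytest.approx(100 * math.log(2), abs=1.0)
        assert m.tau90_ms == pytest.approx(100 * math.log(10), abs=1.0)

    def test_truncated_decay_flags_and_nans(self):
        trace = self.decay_trace(tau=100.0, n=260)  # ends before 90% recovery
        m = transient_metrics(trace, cfg(), line_period_ms=H, f0=1.0,
                              noise_sd=0.0, peak_line=120, rise_line=100)
        assert math.isnan(m.tau90_ms)
        assert "truncated" in m.flags

    def test_gain_rescaling_invariance(self):
        """Multiplying the trace by a constant gain changes no ratio metric."""
        trace = self.decay_trace()
        a = analyze_trace(trace, cfg(), line_period_ms=H)
        b = analyze_trace(trace * 2.7, cfg(), line_period_ms=H)
        ma, mb = a.beats[0], b.beats[0]
        assert mb.dff_max == pytest.approx(ma.dff_max, rel=1e-9)
        assert mb.rise_time_ms == ma.rise_time_ms
        assert mb.tau50_ms == pytest.approx(ma.tau50_ms, rel=1e-6)
        assert mb.tau90_ms == pytest.approx(ma.tau90_ms, rel=1e-6)


class TestContraction:
    def width_trace(self, w):
        w = np.asarray(w, dtype=float)
        return WidthTrace(width_um=w, times_ms=np.arange(w.size) * H,
                          interpolated=np.zeros(w.size, dtype=bool))

    def test_constant_width_is_no_contraction(self):
        wt = self.width_trace(np.full(600, 20.0))
        ctx = ContractionContext(baseline_end_line=200, window_start_line=200,
                                 window_stop_line=600)
        with pytest.raises(RunRejected) as err:
            contraction_metrics(wt, ctx, cfg())
        assert err.value.reason_code == "no_contraction"

    def test_triangular_dip_slope_recovered_exactly(self):
        """Unquantized triangular dip with fall slope 0.05 um/ms."""
        n = 800
        w = np.full(n, 20.0)
        fall = np.arange(50) * 0.05
        w[300:350] -= fall
        w[350:450] -= (fall[-1] - np.arange(100) * 0.025)
        wt = self.width_trace(w)
        ctx = ContractionContext(baseline_end_line=250, window_start_line=250,
                                 window_stop_line=700)
        m = contraction_metrics(wt, ctx, cfg(width_smooth_lines=0))
        assert m.contraction_velocity_um_per_ms == pytest.approx(0.05, rel=1e-6)
        assert m.relaxation_velocity_um_per_ms == pytest.approx(0.025, rel=1e-6)
        assert m.t_contraction_peak_ms == pytest.approx(349.0, abs=1.5)
        assert m.percent_shortening == pytest.approx(100 * fall[-1] / 20.0,
                                                     rel=1e-6)


class TestCoupling:
    def test_all_events_simultaneous_gives_zero_offsets(self):
        class Ctr:  # minimal stand-in with the one consumed attribute
            t_contraction_peak_ms = 100.0
            flags = []
        c = coupling_metrics(tm(100, 100), tm(100, 100), Ctr())
        assert (c.v_rise_to_ca_rise_ms, c.v_peak_to_ca_peak_ms,
                c.ca_peak_to_contraction_peak_ms,
                c.v_peak_to_contraction_peak_ms) == (0, 0, 0, 0)

    def test_representative_offsets_add_up(self):
        """Peaks at 100/162/235.16 ms give offsets 62, 73.16, 135.16 ms."""
        class Ctr:
            t_contraction_peak_ms = 235.16
            flags = []
        c = coupling_metrics(tm(96, 100), tm(110, 162), Ctr())
        assert c.v_peak_to_ca_peak_ms == pytest.approx(62.0)
        assert c.ca_peak_to_contraction_peak_ms == pytest.approx(73.16)
        assert c.v_peak_to_contraction_peak_ms == pytest.approx(135.16)

    def test_additivity_on_random_event_triples(self, rng):
        """Direct-subtraction oracle over 1000 random triples."""
        for _ in range(1000):
            t_vp, t_cp, t_ctr = np.sort(rng.uniform(0, 500, 3))
            class Ctr:
                t_contraction_peak_ms = t_ctr
                flags = []
            c = coupling_metrics(tm(t_vp - 5, t_vp), tm(t_cp - 5, t_cp), Ctr())
            assert c.v_peak_to_ca_peak_ms == t_cp - t_vp
            assert c.ca_peak_to_contraction_peak_ms == t_ctr - t_cp
            assert c.v_peak_to_contraction_peak_ms == pytest.approx(
                c.v_peak_to_ca_peak_ms + c.ca_peak_to_contraction_peak_ms)

    def test_missing_contraction_gives_nan_offsets(self):
        c = coupling_metrics(tm(96, 100), tm(110, 162), None)
        assert math.isnan(c.v_peak_to_contraction_peak_ms)
        assert c.v_peak_to_ca_peak_ms == pytest.approx(62.0)


class TestAnalyzeRun:
    def test_noiseless_single_beat_gives_one_clean_row(self, representative_cell):
        _, _, _, result = representative_cell
        rows = result.to_rows()
        assert len(rows) == 1
        assert rows[0]["qc_flags"] == ""

    def test_full_run_detects_six_beats(self):
        """5000 lines at 1 Hz with the first stimulus at 200 ms: 6 beats."""
        p = SimCellParams(noise_sd=0.0, first_stim_ms=200.0, seed=0)
        kymo, truth = simulate_cell(p)
        result = analyze_run(kymo, cfg(search_start_ms=150.0))
        assert result.status == "ok"
        assert len(result.beats) == 6
        assert len(truth.beats) == 6

    def test_all_background_image_rejected_as_no_cell(self, rng):
        for noise in (0.0, 5.0):
            img = np.full((800, 64), 20.0)
            if noise:
                img = img + rng.normal(0, noise, img.shape)
            kymo = Kymograph(voltage=img, calcium=img, transmitted=img,
                             line_period_ms=1.24, pixel_size_um=0.25)
            result = analyze_run(kymo, cfg())
            assert result.status == "rejected"
            assert result.reason_code == "no_cell"

    def test_channel_gain_changes_no_metric(self, representative_cell):
        """Scaling both fluorescence channels leaves every reported
        parameter unchanged (threshold and ratios scale together)."""
        params, kymo, _, result = representative_cell
        import dataclasses
        scaled = dataclasses.replace(
            kymo, voltage=kymo.voltage * 2.7, calcium=kymo.calcium * 2.7)
        config = cfg(beats_to_analyze=1,
                     search_start_ms=max(params.first_stim_ms - 50, 0))
        r2 = analyze_run(scaled, config)
        a, b = result.to_rows()[0], r2.to_rows()[0]
        for key, val in a.items():
            if key in ("v_f0", "ca_f0", "condition", "animal_id", "run_id",
                       "qc_flags"):
                continue
            if isinstance(val, float) and math.isnan(val):
                assert math.isnan(b[key])
            else:
                assert b[key] == pytest.approx(val, rel=1e-6, abs=1e-9), key
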