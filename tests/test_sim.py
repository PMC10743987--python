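"""Simulator: waveforms, decay solver, rendering, cohorts, ground truth."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

from ecckymo import (CohortGroupSpec, SimCellParams, SingleExpDecay,
                     decay_from_half_times, default_group_specs,
                     generate_cohort, in_cell_pixel_count, render_kymograph,
                     simulate_cell, simulate_transient, simulate_width)

LN10 = math.log(10.0)


@pytest.fixture()
def timebase():
    return np.arange(2000) * 1.24


class TestDecay:
    def test_single_exponential_closed_form(self):
        """Time to 90% decay of a single exponential is tau * ln(10)."""
        d = SingleExpDecay(62.47)
        assert d.tau90_ms == pytest.approx(62.47 * LN10)
        # representative AP fixture: Tau90 143.84 ms
        assert d.tau90_ms == pytest.approx(143.84, abs=5e-3)
        assert d.tau50_ms == pytest.approx(62.47 * math.log(2))

    def test_two_exponential_root_solved_against_bisection(self):
        """Solver reproduces the representative Ca2+ half-times; the check
        is an independent bisection on the analytic decay curve."""
        d = decay_from_half_times(90.5, 235.6)
        t50 = brentq(lambda t: d.curve(np.array([t]))[0] - 0.5, 1e-9, 5000)
        t90 = brentq(lambda t: d.curve(np.array([t]))[0] - 0.1, 1e-9, 5000)
        assert t50 == pytest.approx(90.5, rel=1e-3)
        assert t90 == pytest.approx(235.6, rel=1e-3)
        ts = np.linspace(0, 2000, 20001)
        vals = d.curve(ts)
        assert vals[0] == pytest.approx(1.0)
        assert np.all(np.diff(vals) <= 1e-12), "decay must be monotone"

    def test_single_exponential_ratio_returns_single(self):
        d = decay_from_half_times(100 * math.log(2), 100 * LN10)
        assert isinstance(d, SingleExpDecay)
        assert d.tau_ms == pytest.approx(100.0)

    def test_invalid_half_times_rejected(self):
        with pytest.raises(ValueError):
            decay_from_half_times(200.0, 100.0)


class TestTransientWaveform:
    def test_zero_amplitude_is_identity(self, timebase):
        sim = simulate_transient(0.0, 5.0, SingleExpDecay(50.0), [100.0],
                                 timebase)
        np.testing.assert_array_equal(sim.trace, np.ones_like(timebase))

    def test_empty_stimulus_list_gives_flat_trace(self, timebase):
        sim = simulate_transient(1.0, 5.0, SingleExpDecay(50.0), [], timebase)
        np.testing.assert_array_equal(sim.trace, np.ones_like(timebase))

    def test_peak_value_and_event_times(self, timebase):
        sim = simulate_transient(0.5, 24.8, SingleExpDecay(50.0), [124.0],
                                 timebase)
        assert sim.t_rise_ms[0] == 124.0
        assert sim.t_peak_ms[0] == 124.0 + 24.8
        peak_idx = int(round((124.0 + 24.8) / 1.24))
        assert sim.trace[peak_idx] == pytest.approx(1.5)
        assert not sim.overlap

    def test_overlapping_beats_flagged_not_fatal(self, timebase):
        with pytest.warns(UserWarning, match="overlap"):
            sim = simulate_transient(1.0, 5.0, SingleExpDecay(400.0),
                                     [100.0, 300.0], timebase)
        assert sim.overlap

    def test_stimulus_outside_timebase_rejected(self, timebase):
        with pytest.raises(ValueError, match="timebase"):
            simulate_transient(1.0, 5.0, SingleExpDecay(50.0), [1e6], timebase)


class TestWidthWaveform:
    def test_zero_shortening_is_constant(self, timebase):
        sim = simulate_width(20.0, 0.0, 60.0, 100.0, [500.0], timebase)
        np.testing.assert_array_equal(sim.width_um, np.full_like(timebase, 20.0))

    def test_minimum_width_arithmetic(self, timebase):
        """20 um baseline at 3.4% shortening dips to 19.32 um."""
        peak = 496.0  # on the line grid
        sim = simulate_width(20.0, 3.4, 60.0, 100.0, [peak], timebase)
        assert sim.width_um.min() == pytest.approx(19.32)
        assert sim.t_min_ms[0] == peak

    def test_piecewise_linear_fall_slope_is_the_velocity(self, timebase):
        """True contraction velocity equals the constructed ramp slope."""
        sim = simulate_width(20.0, 5.0, 50.0, 80.0, [500.0], timebase)
        depth = 20.0 * 0.05
        assert sim.contraction_velocity_um_per_ms == pytest.approx(depth / 100.0)
        # numeric slope of the rendered ramp agrees
        i0, i1 = int(420 / 1.24), int(480 / 1.24)
        slope = np.diff(sim.width_um[i0:i1]) / 1.24
        assert np.allclose(slope, -depth / 100.0)

    def test_half_times_are_exact_by_construction(self, timebase):
        sim = simulate_width(20.0, 5.0, 50.0, 80.0, [500.0], timebase)
        w = sim.width_um
        half = 20.0 - 0.5 * (20.0 * 0.05)
        t = timebase
        below = t[w < half]
        assert below.min() == pytest.approx(500.0 - 50.0, abs=1.3)
        assert below.max() == pytest.approx(500.0 + 80.0, abs=1.3)

    def test_peak_beyond_timebase_rejected(self, timebase):
        with pytest.raises(ValueError, match="beyond"):
            simulate_width(20.0, 3.4, 60.0, 100.0, [1e7], timebase)


class TestRendering:
    def base_params(self, **kw):
        kw.setdefault("noise_sd", 0.0)
        kw.setdefault("n_lines", 64)
        return SimCellParams(**kw)

    def test_constant_traces_render_identical_lines(self):
        p = self.base_params()
        ones = np.ones(p.n_lines)
        kymo = render_kymograph(ones, ones, np.full(p.n_lines, 40.0), p)
        for ch in (kymo.voltage, kymo.calcium, kymo.transmitted):
            assert np.all(ch == ch[0])

    def test_halved_width_halves_pixel_count(self):
        p = self.base_params()
        ones = np.ones(p.n_lines)
        width = np.full(p.n_lines, 40.0)
        width[10] = 20.0
        kymo = render_kymograph(ones, ones, width, p)
        thresh = (p.cell_intensity + p.background_intensity) / 2
        counts = (kymo.transmitted > thresh).sum(axis=1)
        assert counts[10] * 2 == counts[0]

    def test_pixel_count_conservation_against_geometric_oracle(self, rng):
        """In-cell pixel count per line equals round(width / pixel_size)."""
        p = self.base_params(n_lines=200)
        widths = rng.uniform(5.0, 120.0, p.n_lines)
        kymo = render_kymograph(np.ones(p.n_lines), np.ones(p.n_lines),
                                widths, p)
        thresh = (p.cell_intensity + p.background_intensity) / 2
        counts = (kymo.transmitted > thresh).sum(axis=1)
        np.testing.assert_array_equal(
            counts, np.maximum(np.rint(widths / p.pixel_size_um), 1))
        np.testing.assert_array_equal(
            counts, in_cell_pixel_count(widths, p.pixel_size_um))

    def test_membrane_rim_pixels_are_brighter(self):
        p = self.base_params()
        kymo = render_kymograph(np.ones(p.n_lines), np.ones(p.n_lines),
                                np.full(p.n_lines, 40.0), p)
        row = kymo.voltage[0]
        in_cell = np.flatnonzero(row > p.background_intensity)
        assert row[in_cell[0]] == pytest.approx(p.membrane_gain * p.cell_intensity)
        assert row[in_cell[-1]] == pytest.approx(p.membrane_gain * p.cell_intensity)
        assert row[in_cell[1]] == pytest.approx(p.cell_intensity)

    def test_cell_beyond_image_rejected(self):
        p = self.base_params(cell_center_px=5)
        with pytest.raises(ValueError, match="beyond"):
            render_kymograph(np.ones(p.n_lines), np.ones(p.n_lines),
                             np.full(p.n_lines, 90.0), p)

    def test_render_is_deterministic_given_seed(self):
        p = self.base_params(noise_sd=10.0, seed=5)
        args = (np.ones(p.n_lines), np.ones(p.n_lines),
                np.full(p.n_lines, 40.0))
        a, b = render_kymograph(*args, p), render_kymograph(*args, p)
        assert np.array_equal(a.voltage, b.voltage)
        assert np.array_equal(a.calcium, b.calcium)
        c = render_kymograph(*args, replace(p, seed=6))
        assert not np.array_equal(a.voltage, c.voltage)

    def test_poisson_noise_model(self):
        p = self.base_params(noise_model="poisson", seed=2)
        kymo = render_kymograph(np.ones(p.n_lines), np.ones(p.n_lines),
                                np.full(p.n_lines, 40.0), p)
        assert np.all(kymo.voltage == np.rint(kymo.voltage))


class TestGroundTruth:
    def test_coupling_offsets_additive_exactly(self, representative_cell):
        """v-peak-to-contraction equals the sum of its two legs, exactly."""
        _, _, truth, _ = representative_cell
        b = truth.beats
        np.testing.assert_array_equal(
            b["v_peak_to_contraction_peak_ms"],
            b["v_peak_to_ca_peak_ms"] + b["ca_peak_to_contraction_peak_ms"])

    def test_event_ordering_invariant(self, representative_cell):
        _, _, truth, _ = representative_cell
        b = truth.beats
        assert (b["t_v_rise_ms"] <= b["t_ca_rise_ms"]).all()
        assert (b["t_ca_rise_ms"] <= b["t_ca_peak_ms"]).all()
        assert (b["t_ca_peak_ms"] <= b["t_contraction_peak_ms"]).all()

    def test_simulate_cell_is_bit_deterministic(self):
        p = SimCellParams(n_lines=300, noise_sd=10.0, seed=9)
        k1, _ = simulate_cell(p)
        k2, _ = simulate_cell(p)
        assert np.array_equal(k1.voltage, k2.voltage)
        assert np.array_equal(k1.calcium, k2.calcium)
        assert np.array_equal(k1.transmitted, k2.transmitted)


class TestCohort:
    def test_zero_cv_yields_group_means(self):
        specs = {"g": CohortGroupSpec(means={"v_tau90_ms": 120.0,
                                             "ca_rise_ms": 20.0}, cv=0.0)}
        base = SimCellParams(n_lines=300, noise_sd=0.0)
        cell = next(generate_cohort(specs, n_cells_per_group=1, seed=0,
                                    base_params=base))
        assert cell.params.v_tau90_ms == 120.0
        assert cell.params.ca_rise_ms == 20.0

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError, match="variation"):
            CohortGroupSpec(means={"v_tau90_ms": 100.0}, cv=-0.1)

    def test_identical_group_specs_give_null_contrast(self):
        """Two groups drawn from the same spec have ~equal medians."""
        spec = CohortGroupSpec(means=default_group_specs()["female"].means,
                               cv=0.15)
        base = SimCellParams(n_lines=300, noise_sd=0.0)
        cells = list(generate_cohort({"a": spec, "b": spec},
                                     n_cells_per_group=25, seed=3,
                                     base_params=base))
        med = {g: np.median([c.params.v_tau90_ms for c in cells
                             if c.group == g]) for g in ("a", "b")}
        assert med["a"] == pytest.approx(med["b"], rel=0.15)

    def test_cohort_deterministic_given_seed(self):
        specs = default_group_specs()
        base = SimCellParams(n_lines=300)
        a = [c.params for c in generate_cohort(specs, 2, seed=7,
                                               base_params=base)]
        b = [c.params for c in generate_cohort(specs, 2, seed=7,
                                               base_params=base)]
        assert a == b

    def test_draws_are_mean_preserving(self):
        """Log-normal draws have expectation equal to the group mean."""
        spec = {"g": CohortGroupSpec(means={"v_tau90_ms": 143.84}, cv=0.15)}
        base = SimCellParams(n_lines=300, noise_sd=0.0)
        vals = [c.params.v_tau90_ms for c in
                generate_cohort(spec, 400, seed=5, base_params=base)]
        assert np.mean(vals) == pytest.approx(143.84, rel=0.03)
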