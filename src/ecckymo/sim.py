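"""Synthetic kymograph generator with per-beat ground truth.

Generates the three traces of excitation-contraction coupling — an optical
action potential, a cytosolic Ca2+ transient and cell shortening — and
renders them into a noisy 3-channel line-scan kymograph (~806 Hz line rate,
512-pixel lines, 1 Hz pacing by default) so that every downstream stage can
be tested against known truth without microscope data.

Waveform model
--------------
Fluorescence traces are normalized to a baseline of 1.  Each stimulus adds
a pulse that rises (linearly by default) from 0 to ``amp_dff`` over
``rise_ms`` and then decays back per a single-exponential or
two-exponential decay law.  The Ca2+ decay is two-exponential by default
because a measured tau50/tau90 ratio above ln2/ln10 (~0.301) cannot be
produced by any single exponential; :func:`decay_from_half_times` solves
for a monotone two-exponential curve with the requested half-recovery
times.  Cell shortening is a piecewise-linear dip (fall over twice the
contraction half-time, recovery over twice the relaxation half-time), so
the true contraction and relaxation velocities are the constant segment
slopes ``depth / (2 * half_time)``.

Rendering model
---------------
For each line the cell occupies ``round(width / pixel_size)`` contiguous
pixels centred on ``cell_center_px``.  The voltage channel is
``cell_intensity * v(t)`` inside the cell with the outermost in-cell pixel
on each side multiplied by ``membrane_gain`` (the voltage dye concentrates
on the membrane); the Ca2+ channel is ``cell_intensity * ca(t)``; the
transmitted channel is a constant plateau over the cell.  Background
pixels sit at ``background_intensity``; additive Gaussian noise (or
optionally Poisson noise) is applied and intensities are clipped at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .io import Kymograph

LN2 = math.log(2.0)
LN10 = math.log(10.0)


# --------------------------------------------------------------------------
# decay laws
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleExpDecay:
    """Single-exponential recovery, ``D(t) = exp(-t / tau_ms)``."""

    tau_ms: float

    def __post_init__(self):
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be positive")

    def curve(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-np.asarray(t, dtype=float) / self.tau_ms)

    def time_to_fraction(self, remaining: float) -> float:
        """Time at which the decay has fallen to ``remaining`` of its start."""
        return -self.tau_ms * math.log(remaining)

    @property
    def tau50_ms(self) -> float:
        return self.tau_ms * LN2

    @property
    def tau90_ms(self) -> float:
        return self.tau_ms * LN10


@dataclass(frozen=True)
class BiexpDecay:
    """Two-exponential recovery ``D(t) = w e^{-t/tau1} + (1-w) e^{-t/tau2}``.

    ``weight`` may exceed 1 (with a compensating negative fast component);
    this produces an initial shoulder, which is what makes tau50/tau90
    ratios above ln2/ln10 reachable.  Construction enforces D(0) = 1 by
    form; monotonicity is the caller's concern (checked by the solver).
    """

    weight: float
    tau1_ms: float
    tau2_ms: float

    def __post_init__(self):
        if self.tau1_ms <= 0 or self.tau2_ms <= 0:
            raise ValueError("time constants must be positive")

    def curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.weight * np.exp(-t / self.tau1_ms)
                + (1.0 - self.weight) * np.exp(-t / self.tau2_ms))

    def time_to_fraction(self, remaining: float) -> float:
        hi = 50.0 * max(self.tau1_ms, self.tau2_ms)
        return brentq(lambda t: self.curve(t) - remaining, 0.0, hi)

    @property
    def tau50_ms(self) -> float:
        return self.time_to_fraction(0.5)

    @property
    def tau90_ms(self) -> float:
        return self.time_to_fraction(0.1)


DecaySpec = SingleExpDecay | BiexpDecay


def decay_from_half_times(tau50_ms: float, tau90_ms: float,
                          rtol: float = 1e-3) -> DecaySpec:
    """Build a monotone decay law with the given 50% and 90% recovery times.

    If the pair is consistent with one exponential (tau50/tau90 close to
    ln2/ln10) a :class:`SingleExpDecay` is returned.  Otherwise the tail
    time constant is scanned over a grid and ``(weight, tau2)`` are
    root-solved for each candidate until a monotone curve reproduces both
    half-times; the result is verified by bisection on the analytic curve.
    """
    if not (tau90_ms > tau50_ms > 0):
        raise ValueError("need tau90 > tau50 > 0")
    ratio = tau50_ms / tau90_ms
    if abs(ratio - LN2 / LN10) < rtol:
        return SingleExpDecay(tau90_ms / LN10)

    t_grid = np.linspace(0.0, 60.0 * tau90_ms, 4096)
    tail_guess = (tau90_ms - tau50_ms) / math.log(5.0)
    for f1 in (0.8, 0.85, 0.9, 0.95, 1.0, 1.05, 1.1, 1.2, 0.7, 1.4, 0.6, 1.8):
        tau1 = f1 * tail_guess
        for w0, t20 in ((1.9, 0.5 * tau1), (1.3, 0.3 * tau1),
                        (2.5, 0.7 * tau1), (0.5, 2.0 * tau1)):
            sol = root(
                lambda x: [
                    x[0] * math.exp(-tau50_ms / tau1)
                    + (1 - x[0]) * math.exp(-tau50_ms / x[1]) - 0.5,
                    x[0] * math.exp(-tau90_ms / tau1)
                    + (1 - x[0]) * math.exp(-tau90_ms / x[1]) - 0.1,
                ],
                x0=[w0, t20],
            )
            if not sol.success or sol.x[1] <= 0:
                continue
            cand = BiexpDecay(float(sol.x[0]), tau1, float(sol.x[1]))
            vals = cand.curve(t_grid)
            if np.any(np.diff(vals) > 1e-12) or abs(vals[0] - 1) > 1e-9:
                continue
            if (abs(cand.tau50_ms - tau50_ms) < rtol * tau50_ms
                    and abs(cand.tau90_ms - tau90_ms) < rtol * tau90_ms):
                return cand
    raise ValueError(
        f"no monotone two-exponential decay found for tau50={tau50_ms}, "
        f"tau90={tau90_ms}")


# --------------------------------------------------------------------------
# parameter set and ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimCellParams:
    """Ground-truth parameters of one simulated cell.

    Acquisition defaults follow the study conditions the package targets:
    512-pixel lines at a 1.24 ms three-channel line period (~806 Hz), 5000
    lines (6.2 s), 1 Hz field pacing.  Waveform defaults are the
    representative single-cell parameter set (a female left-ventricular
    myocyte): optical AP with dF/F0 0.22, 3.72 ms rise and 143.84 ms
    Tau90; Ca2+ transient with dF/F0 1.08, 27.3 ms rise, Tau1/2 90.5 ms
    and Tau90 235.6 ms; 3.4% shortening with 66.96 / 110.36 ms contraction
    and relaxation half-times.  The diastolic cell length along the scan
    line (``baseline_width_um``) is not reported with that parameter set;
    92.8 um is adopted so that the piecewise-linear shortening pulse has a
    peak contraction velocity of 0.037 um/ms, consistent with the same
    representative cell (see the methods note).
    """

    line_period_ms: float = 1.24
    n_lines: int = 5000
    n_pixels: int = 512
    pixel_size_um: float = 0.25
    pacing_hz: float = 1.0
    first_stim_ms: float = 250.0
    cell_center_px: int = 256
    baseline_width_um: float = 92.8
    v_amp_dff: float = 0.22
    v_rise_ms: float = 3.72
    v_tau90_ms: float = 143.84
    ca_amp_dff: float = 1.08
    ca_rise_ms: float = 27.3
    ca_tau50_ms: float = 90.5
    ca_tau90_ms: float = 235.6
    ap_to_ca_rise_delay_ms: float = 13.54
    shortening_pct: float = 3.4
    contraction_half_ms: float = 66.96
    relaxation_half_ms: float = 110.36
    ca_peak_to_contraction_peak_ms: float = 73.16
    cell_intensity: float = 200.0
    background_intensity: float = 20.0
    membrane_gain: float = 2.0
    noise_sd: float = 10.0
    seed: int = 0
    rise_shape: str = "linear"      # "linear" | "cosine"
    width_shape: str = "linear"     # "linear" | "cosine"
    noise_model: str = "gaussian"   # "gaussian" | "poisson"

    def __post_init__(self):
        if not (self.ca_tau90_ms > self.ca_tau50_ms > 0):
            raise ValueError("need ca_tau90_ms > ca_tau50_ms > 0")
        if not self.background_intensity < self.cell_intensity:
            raise ValueError("background_intensity must be below cell_intensity")
        if not self.baseline_width_um < self.n_pixels * self.pixel_size_um:
            raise ValueError("cell wider than the scan line")
        if not 1000.0 / self.pacing_hz > self.v_tau90_ms:
            raise ValueError("pacing period must exceed the AP Tau90")
        if not 0 <= self.shortening_pct < 100:
            raise ValueError("shortening_pct must be in [0, 100)")
        for name in ("line_period_ms", "pixel_size_um", "pacing_hz",
                     "cell_intensity", "baseline_width_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.first_stim_ms < 0 or self.background_intensity < 0 \
                or self.noise_sd < 0:
            raise ValueError("first_stim_ms, background and noise must be >= 0")
        if self.membrane_gain < 1:
            raise ValueError("membrane_gain must be >= 1")

    @property
    def pacing_period_ms(self) -> float:
        return 1000.0 / self.pacing_hz

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_lines) * self.line_period_ms

    def stim_times_ms(self) -> np.ndarray:
        last_line = (self.n_lines - 1) * self.line_period_ms
        return np.arange(self.first_stim_ms, last_line, self.pacing_period_ms)

    def v_decay(self) -> SingleExpDecay:
        return SingleExpDecay(self.v_tau90_ms / LN10)

    def ca_decay(self) -> DecaySpec:
        return decay_from_half_times(self.ca_tau50_ms, self.ca_tau90_ms)


#: Column order of the ground-truth table (one row per beat).
TRUTH_COLUMNS = [
    "beat", "t_v_rise_ms", "t_v_peak_ms", "t_ca_rise_ms", "t_ca_peak_ms",
    "t_contraction_peak_ms",
    "v_dff_max", "v_rise_time_ms", "v_tau90_ms",
    "ca_dff_max", "ca_rise_time_ms", "ca_tau50_ms", "ca_tau90_ms",
    "v_baseline_shift", "ca_baseline_shift",
    "percent_shortening", "contraction_half_ms", "relaxation_half_ms",
    "contraction_velocity_um_per_ms", "relaxation_velocity_um_per_ms",
    "v_rise_to_ca_rise_ms", "v_peak_to_ca_peak_ms",
    "ca_peak_to_contraction_peak_ms", "v_peak_to_contraction_peak_ms",
]


@dataclass
class GroundTruthRecord:
    """True per-beat event times and metric values for one simulated cell."""

    cell_id: str
    params: SimCellParams
    beats: pd.DataFrame  # columns TRUTH_COLUMNS

    def __post_init__(self):
        b = self.beats
        ok = ((b["t_v_rise_ms"] <= b["t_ca_rise_ms"])
              & (b["t_ca_rise_ms"] <= b["t_ca_peak_ms"])
              & (b["t_ca_peak_ms"] <= b["t_contraction_peak_ms"]))
        if not bool(ok.all()):
            raise ValueError("event ordering violated in ground truth")


# --------------------------------------------------------------------------
# waveform synthesis
# --------------------------------------------------------------------------

@dataclass
class TransientSim:
    trace: np.ndarray            # normalized fluorescence, baseline 1
    t_rise_ms: np.ndarray        # per-beat true rise-onset times
    t_peak_ms: np.ndarray        # per-beat true peak times
    overlap: bool                # decay <99% complete before a next stimulus


def _rise_profile(u: np.ndarray, shape: str) -> np.ndarray:
    if shape == "linear":
        return u
    if shape == "cosine":
        return 0.5 * (1.0 - np.cos(np.pi * u))
    raise ValueError(f"unknown rise shape {shape!r}")


def simulate_transient(amp_dff: float, rise_ms: float, decay: DecaySpec,
                       stim_times_ms: Sequence[float],
                       times_ms: np.ndarray,
                       rise_shape: str = "linear") -> TransientSim:
    """Ideal normalized fluorescence trace for a train of stimuli.

    The trace is 1 at baseline; each stimulus adds a pulse rising from 0
    to ``amp_dff`` over ``rise_ms`` then decaying per ``decay``.  Pulses
    superpose additively; if a pulse has not decayed to <1% of its
    amplitude before the next stimulus the result is flagged
    ``overlap=True`` (a warning, not a failure).  An empty stimulus list
    yields a flat trace.
    """
    times = np.asarray(times_ms, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("timebase must be strictly increasing")
    if amp_dff < 0 or rise_ms <= 0:
        raise ValueError("need amp_dff >= 0 and rise_ms > 0")
    stims = np.asarray(list(stim_times_ms), dtype=float)
    if stims.size and (stims.min() < times[0] or stims.max() > times[-1]):
        raise ValueError("stimulus times outside the timebase span")

    trace = np.ones_like(times)
    overlap = False
    for i, s in enumerate(stims):
        dt = times - s
        pulse = np.zeros_like(times)
        rising = (dt >= 0) & (dt < rise_ms)
        pulse[rising] = _rise_profile(dt[rising] / rise_ms, rise_shape)
        decaying = dt >= rise_ms
        pulse[decaying] = decay.curve(dt[decaying] - rise_ms)
        trace += amp_dff * pulse
        if i + 1 < stims.size:
            gap = stims[i + 1] - s - rise_ms
            if gap < 0 or decay.curve(np.array([gap]))[0] > 0.01:
                overlap = True
    if overlap:
        warnings.warn("beats overlap: decay <99% complete before next stimulus",
                      stacklevel=2)
    return TransientSim(trace=trace, t_rise_ms=stims,
                        t_peak_ms=stims + rise_ms, overlap=overlap)


@dataclass
class WidthSim:
    width_um: np.ndarray
    t_min_ms: np.ndarray              # true minimum-width times (= peak_times)
    contraction_velocity_um_per_ms: float
    relaxation_velocity_um_per_ms: float
    fall_ms: float
    rise_ms: float


def simulate_width(baseline_width_um: float, shortening_pct: float,
                   contraction_half_ms: float, relaxation_half_ms: float,
                   peak_times_ms: Sequence[float], times_ms: np.ndarray,
                   shape: str = "linear") -> WidthSim:
    """Cell width over time: baseline between beats, one dip per beat.

    Each dip reaches ``baseline * (1 - shortening_pct/100)`` at its peak
    time, falling monotonically over ``2 * contraction_half_ms`` and
    recovering over ``2 * relaxation_half_ms`` so the true half-times
    equal the given parameters exactly.  With the default piecewise-linear
    shape the true velocities are the constant slopes
    ``depth / (2 * half_time)``; with ``shape="cosine"`` the profile is a
    raised cosine and the true peak velocity is ``pi*depth/(4*half_time)``.
    """
    times = np.asarray(times_ms, dtype=float)
    if not 0 <= shortening_pct < 100:
        raise ValueError("shortening_pct must be in [0, 100)")
    if baseline_width_um <= 0 or contraction_half_ms <= 0 or relaxation_half_ms <= 0:
        raise ValueError("width and half-times must be positive")
    peaks = np.asarray(list(peak_times_ms), dtype=float)
    if peaks.size and (peaks.min() < times[0] or peaks.max() > times[-1]):
        raise ValueError("contraction peak time beyond the timebase")

    depth = baseline_width_um * shortening_pct / 100.0
    t_fall = 2.0 * contraction_half_ms
    t_rise = 2.0 * relaxation_half_ms
    dip = np.zeros_like(times)
    for p in peaks:
        u = np.zeros_like(times)
        falling = (times >= p - t_fall) & (times < p)
        rising = (times >= p) & (times <= p + t_rise)
        u[falling] = (times[falling] - (p - t_fall)) / t_fall
        u[rising] = 1.0 - (times[rising] - p) / t_rise
        if shape == "cosine":
            u = 0.5 * (1.0 - np.cos(np.pi * u))
        elif shape != "linear":
            raise ValueError(f"unknown width shape {shape!r}")
        dip = np.maximum(dip, u)
    width = baseline_width_um - depth * dip
    if shape == "linear":
        v_c = depth / t_fall
        v_r = depth / t_rise
    else:
        v_c = math.pi * depth / (2.0 * t_fall)
        v_r = math.pi * depth / (2.0 * t_rise)
    return WidthSim(width_um=width, t_min_ms=peaks,
                    contraction_velocity_um_per_ms=v_c,
                    relaxation_velocity_um_per_ms=v_r,
                    fall_ms=t_fall, rise_ms=t_rise)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def in_cell_pixel_count(width_um: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Number of in-cell pixels per line: ``round(width / pixel_size)``, >= 1."""
    n = np.rint(np.asarray(width_um, dtype=float) / pixel_size_um).astype(int)
    return np.maximum(n, 1)


def render_kymograph(v_trace: np.ndarray, ca_trace: np.ndarray,
                     width_trace_um: np.ndarray,
                     params: SimCellParams) -> Kymograph:
    """Render normalized traces into a noisy 3-channel kymograph."""
    n_lines, n_pixels = params.n_lines, params.n_pixels
    for name, tr in (("v_trace", v_trace), ("ca_trace", ca_trace),
                     ("width_trace_um", width_trace_um)):
        if np.asarray(tr).shape != (n_lines,):
            raise ValueError(f"{name} must have n_lines={n_lines} entries")

    counts = in_cell_pixel_count(width_trace_um, params.pixel_size_um)
    start = params.cell_center_px - (counts - 1) // 2
    stop = start + counts  # exclusive
    if start.min() < 0 or stop.max() > n_pixels:
        raise ValueError(
            "cell extends beyond the scan line; leave empty space on either side")

    cols = np.arange(n_pixels)
    mask = (cols >= start[:, None]) & (cols < stop[:, None])
    rows = np.arange(n_lines)
    cell, bg = params.cell_intensity, params.background_intensity

    voltage = np.where(mask, cell * np.asarray(v_trace)[:, None], bg)
    voltage[rows, start] = params.membrane_gain * cell * np.asarray(v_trace)
    voltage[rows, stop - 1] = params.membrane_gain * cell * np.asarray(v_trace)
    calcium = np.where(mask, cell * np.asarray(ca_trace)[:, None], bg)
    transmitted = np.where(mask, cell, bg)

    rng = np.random.default_rng(params.seed)
    channels = [voltage, calcium, transmitted]
    if params.noise_model == "gaussian":
        if params.noise_sd > 0:
            channels = [c + rng.normal(0.0, params.noise_sd, c.shape)
                        for c in channels]
    elif params.noise_model == "poisson":
        channels = [rng.poisson(np.maximum(c, 0)).astype(float) for c in channels]
    else:
        raise ValueError(f"unknown noise model {params.noise_model!r}")
    channels = [np.clip(c, 0.0, None).astype(np.float32) for c in channels]

    return Kymograph(voltage=channels[0], calcium=channels[1],
                     transmitted=channels[2],
                     line_period_ms=params.line_period_ms,
                     pixel_size_um=params.pixel_size_um)


# --------------------------------------------------------------------------
# whole-cell simulation and cohorts
# --------------------------------------------------------------------------

def _truth_table(params: SimCellParams, v: TransientSim, ca: TransientSim,
                 w: WidthSim) -> pd.DataFrame:
    """Per-beat ground truth; coupling offsets are additive by construction."""
    v_decay, ca_decay = params.v_decay(), params.ca_decay()
    duration = params.n_lines * params.line_period_ms
    rows = []
    n_beats = len(v.t_rise_ms)
    for b in range(n_beats):
        t_vr, t_vp = v.t_rise_ms[b], v.t_peak_ms[b]
        t_cr, t_cp = ca.t_rise_ms[b], ca.t_peak_ms[b]
        t_ctr = w.t_min_ms[b]
        if b + 1 < n_beats:
            v_shift = params.v_amp_dff * float(
                v_decay.curve(np.array([v.t_rise_ms[b + 1] - t_vp]))[0])
            ca_shift = params.ca_amp_dff * float(
                ca_decay.curve(np.array([ca.t_rise_ms[b + 1] - t_cp]))[0])
        else:
            v_shift = ca_shift = np.nan
        rows.append({
            "beat": b,
            "t_v_rise_ms": t_vr, "t_v_peak_ms": t_vp,
            "t_ca_rise_ms": t_cr, "t_ca_peak_ms": t_cp,
            "t_contraction_peak_ms": t_ctr,
            "v_dff_max": params.v_amp_dff,
            "v_rise_time_ms": params.v_rise_ms,
            "v_tau90_ms": params.v_tau90_ms,
            "ca_dff_max": params.ca_amp_dff,
            "ca_rise_time_ms": params.ca_rise_ms,
            "ca_tau50_ms": params.ca_tau50_ms,
            "ca_tau90_ms": params.ca_tau90_ms,
            "v_baseline_shift": v_shift,
            "ca_baseline_shift": ca_shift,
            "percent_shortening": params.shortening_pct,
            "contraction_half_ms": params.contraction_half_ms,
            "relaxation_half_ms": params.relaxation_half_ms,
            "contraction_velocity_um_per_ms": w.contraction_velocity_um_per_ms,
            "relaxation_velocity_um_per_ms": w.relaxation_velocity_um_per_ms,
            "v_rise_to_ca_rise_ms": t_cr - t_vr,
            "v_peak_to_ca_peak_ms": t_cp - t_vp,
            "ca_peak_to_contraction_peak_ms": t_ctr - t_cp,
            "v_peak_to_contraction_peak_ms": t_ctr - t_vp,
            "truncated": t_ctr + w.rise_ms > duration
                         or t_cp + ca_decay.time_to_fraction(0.1) > duration,
        })
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS + ["truncated"])


def simulate_cell(params: SimCellParams, cell_id: str = "sim") \
        -> tuple[Kymograph, GroundTruthRecord]:
    """Simulate one paced cell: kymograph plus per-beat ground truth."""
    times = params.times_ms
    stims = params.stim_times_ms()
    v = simulate_transient(params.v_amp_dff, params.v_rise_ms, params.v_decay(),
                           stims, times, params.rise_shape)
    ca_stims = stims + params.ap_to_ca_rise_delay_ms
    ca_stims = ca_stims[ca_stims <= times[-1]]
    ca = simulate_transient(params.ca_amp_dff, params.ca_rise_ms,
                            params.ca_decay(), ca_stims, times,
                            params.rise_shape)
    n_beats = min(len(v.t_rise_ms), len(ca.t_rise_ms))
    contraction_peaks = ca.t_peak_ms[:n_beats] + params.ca_peak_to_contraction_peak_ms
    keep = contraction_peaks <= times[-1]
    contraction_peaks = contraction_peaks[keep]
    w = simulate_width(params.baseline_width_um, params.shortening_pct,
                       params.contraction_half_ms, params.relaxation_half_ms,
                       contraction_peaks, times, params.width_shape)
    kymo = render_kymograph(v.trace, ca.trace, w.width_um, params)
    kymo = kymo.with_ids(run_id=cell_id)
    n_full = len(contraction_peaks)
    v_cut = TransientSim(v.trace, v.t_rise_ms[:n_full], v.t_peak_ms[:n_full],
                         v.overlap)
    ca_cut = TransientSim(ca.trace, ca.t_rise_ms[:n_full], ca.t_peak_ms[:n_full],
                          ca.overlap)
    truth = GroundTruthRecord(cell_id=cell_id, params=params,
                              beats=_truth_table(params, v_cut, ca_cut, w))
    return kymo, truth


# -- cohorts ----------------------------------------------------------------

#: SimCellParams fields that a cohort spec may vary between cells.
COHORT_FIELDS = (
    "v_amp_dff", "v_rise_ms", "v_tau90_ms",
    "ca_amp_dff", "ca_rise_ms", "ca_tau50_ms", "ca_tau90_ms",
    "ap_to_ca_rise_delay_ms", "shortening_pct",
    "contraction_half_ms", "relaxation_half_ms",
    "ca_peak_to_contraction_peak_ms", "baseline_width_um",
)

#: Fields scaled by one shared per-cell multiplier so that biological
#: ordering constraints (ca_tau90 > ca_tau50) survive random draws.
_PAIRED_FIELDS = {"ca_tau50_ms": "ca_kinetics", "ca_tau90_ms": "ca_kinetics"}


@dataclass(frozen=True)
class CohortGroupSpec:
    """Log-normal population model of one experimental group.

    ``means`` maps :data:`COHORT_FIELDS` entries to the group mean; ``cv``
    is the coefficient of variation of the log-normal draw (0 gives every
    cell exactly the group mean).
    """

    means: Mapping[str, float]
    cv: float = 0.15

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("coefficient of variation must be >= 0")
        unknown = set(self.means) - set(COHORT_FIELDS)
        if unknown:
            raise ValueError(f"unknown cohort fields: {sorted(unknown)}")


def default_group_specs() -> dict[str, CohortGroupSpec]:
    """Female/male group means encoding the reported sex contrasts.

    The female group mean is the representative female parameter set; the
    male group is derived from the reported percent differences: APD90
    37% longer in females (male Tau90 = female / 1.37), peak depolarization
    6% larger in females, Ca2+ release/reuptake ~15% faster in males
    (10 ms shorter Ca2+ rise), AP-to-Ca2+ rise delay 1.1 ms shorter in
    males, contraction velocity 29% and relaxation velocity 31% higher in
    males (encoded via the half-times at equal shortening), and a 7%
    shorter Ca2+-peak-to-contraction-peak offset in males.
    """
    f = SimCellParams()
    female = {
        "v_amp_dff": f.v_amp_dff, "v_rise_ms": f.v_rise_ms,
        "v_tau90_ms": f.v_tau90_ms,
        "ca_amp_dff": f.ca_amp_dff, "ca_rise_ms": f.ca_rise_ms,
        "ca_tau50_ms": f.ca_tau50_ms, "ca_tau90_ms": f.ca_tau90_ms,
        "ap_to_ca_rise_delay_ms": f.ap_to_ca_rise_delay_ms,
        "shortening_pct": f.shortening_pct,
        "contraction_half_ms": f.contraction_half_ms,
        "relaxation_half_ms": f.relaxation_half_ms,
        "ca_peak_to_contraction_peak_ms": f.ca_peak_to_contraction_peak_ms,
        "baseline_width_um": f.baseline_width_um,
    }
    male = dict(female)
    male["v_amp_dff"] = female["v_amp_dff"] / 1.06
    male["v_tau90_ms"] = female["v_tau90_ms"] / 1.37
    male["ca_rise_ms"] = female["ca_rise_ms"] - 10.0
    male["ca_tau50_ms"] = female["ca_tau50_ms"] / 1.15
    male["ca_tau90_ms"] = female["ca_tau90_ms"] / 1.15
    male["ap_to_ca_rise_delay_ms"] = female["ap_to_ca_rise_delay_ms"] - 1.1
    male["contraction_half_ms"] = female["contraction_half_ms"] / 1.29
    male["relaxation_half_ms"] = female["relaxation_half_ms"] / 1.31
    male["ca_peak_to_contraction_peak_ms"] = \
        female["ca_peak_to_contraction_peak_ms"] / 1.07
    return {"female": CohortGroupSpec(means=female),
            "male": CohortGroupSpec(means=male)}


@dataclass
class CohortCell:
    group: str
    animal_id: str
    cell_id: str
    params: SimCellParams
    kymograph: Kymograph
    truth: GroundTruthRecord


def generate_cohort(group_specs: Mapping[str, CohortGroupSpec] | None = None,
                    n_cells_per_group: int | Mapping[str, int] = 10,
                    seed: int = 0,
                    base_params: SimCellParams | None = None,
                    n_animals_per_group: int = 5) -> Iterator[CohortCell]:
    """Yield simulated cells for each group, deterministically from ``seed``.

    Per-cell parameters are drawn log-normally around the group means
    (median-preserving is not required; the draw is mean-preserving:
    ``E[X] = mean``).  The stimulus-to-frame phase is randomized uniformly
    over one pacing period per cell, mirroring unsynchronized field
    stimulation.  Cells are yielded lazily so large cohorts never hold
    every kymograph in memory; collect ground truth with
    :func:`cohort_truth_table`.
    """
    if group_specs is None:
        group_specs = default_group_specs()
    base = base_params if base_params is not None else SimCellParams()
    rng = np.random.default_rng(seed)
    for group, spec in group_specs.items():
        n = (n_cells_per_group[group]
             if isinstance(n_cells_per_group, Mapping) else n_cells_per_group)
        if n < 1:
            raise ValueError("n_cells_per_group must be >= 1")
        sigma = math.sqrt(math.log1p(spec.cv ** 2))
        for i in range(n):
            draw = {}
            shared: dict[str, float] = {}
            for name, mean in spec.means.items():
                if sigma == 0:
                    draw[name] = mean
                    continue
                pair = _PAIRED_FIELDS.get(name)
                if pair is not None:
                    if pair not in shared:
                        shared[pair] = rng.lognormal(-0.5 * sigma ** 2, sigma)
                    mult = shared[pair]
                else:
                    mult = rng.lognormal(-0.5 * sigma ** 2, sigma)
                draw[name] = mean * mult
            phase = rng.uniform(0.0, base.pacing_period_ms)
            cell_seed = int(rng.integers(0, 2 ** 31 - 1))
            # the scan line is drawn to fit each cell with margin on both
            # sides, so long cells get a coarser pixel size (as in real
            # acquisitions, where the line length varied per cell)
            width = draw.get("baseline_width_um", base.baseline_width_um)
            pixel_size = max(base.pixel_size_um, width / (0.8 * base.n_pixels))
            params = replace(base, seed=cell_seed,
                             first_stim_ms=base.first_stim_ms + phase,
                             pixel_size_um=pixel_size, **draw)
            cell_id = f"{group}_{i:03d}"
            animal_id = f"{group}_animal_{i % n_animals_per_group}"
            kymo, truth = simulate_cell(params, cell_id=cell_id)
            kymo = kymo.with_ids(animal_id=animal_id, condition=group)
            yield CohortCell(group=group, animal_id=animal_id, cell_id=cell_id,
                             params=params, kymograph=kymo, truth=truth)


def cohort_truth_table(cells: Sequence[CohortCell]) -> pd.DataFrame:
    """One row per cell per beat of ground truth, with identifiers."""
    frames = []
    for c in cells:
        df = c.truth.beats.copy()
        df.insert(0, "condition", c.group)
        df.insert(1, "animal_id", c.animal_id)
        df.insert(2, "run_id", c.cell_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
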