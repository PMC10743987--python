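"""Per-beat waveform, contraction and coupling parameter extraction.

Works on width-corrected fluorescence traces and the width trace produced
by :mod:`ecckymo.segment`.  The workflow mirrors the semiautomatic
spreadsheet analysis it replaces: a user-set search window locates the
first peak (stimulation is not synchronized to the line clock), later
beats are found by repeating the peak search in successive windows of one
pacing period, rise onsets are detected by a k-sigma threshold with a
persistence requirement (with a manual shift retained for fidelity to the
original workflow), and decay times are the interpolated crossings of the
50% / 90% recovery levels measured from the peak.  The voltage-channel
Tau90 doubles as APD90.

Width-derived timings deserve a caveat: the width trace is quantized to
one pixel, so contraction onset and the half-recovery levels are only
defined to about half a pixel of depth.  Contraction timing therefore
uses a smoothed copy of the width trace, the contraction onset is the
extrapolated foot of the maximum-slope line (exact for a linear
shortening ramp), and the contraction-peak time is the intersection of
the falling and rising maximum-slope lines rather than the raw argmin
(exact for a V-shaped dip, unbiased by the quantization plateau).  See
the methods note for the resulting error floors.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import median_abs_deviation

from .errors import BaselineError, RunRejected, ThresholdError
from .io import Kymograph
from .segment import (CellMaskSeries, WidthTrace, build_mask,
                      select_threshold, width_corrected_trace, width_from_mask)

MAD_TO_SD = 1.4826  # consistent robust SD for Gaussian noise


@dataclass
class AnalysisConfig:
    """Tunable parameters of the per-run analysis.

    ``search_start_ms`` opens the search window for the first peak (one
    pacing period long); ``rise_shift_lines`` is the manual adjustment of
    the detected rise onset; ``rise_k_sigma`` and ``rise_persist_lines``
    set the onset threshold (baseline + k·sigma, sustained); ``fit_points``
    is the odd number of lines in each sliding straight-line fit used for
    contraction/relaxation velocity; ``width_smooth_lines`` is the moving
    average applied to the width trace before contraction timing (0
    disables); ``cell_contrast_min`` rejects runs whose masked/unmasked
    intensity ratio suggests no cell is present; ``rise_floor_rel`` puts
    a floor of ``rise_floor_rel * |F0|`` under the onset threshold so
    that near-noiseless traces do not trigger on sub-noise systematic
    ripple; ``contraction_lead_ms`` opens the contraction beat window
    this far before the voltage rise, because shortening can begin before
    the stimulus-aligned fluorescence peak.

    ``velocity_fit_min_lines`` widens the contraction/relaxation fit
    window to at least this many lines (shrunk to the phase when the
    phase is shorter): the width trace is quantized to one pixel, and a
    straight-line fit only averages that staircase out once it spans
    several quantization steps.  ``fit_points`` still applies whenever it
    is the larger of the two.
    """

    search_start_ms: float = 0.0
    pacing_hz: float = 1.0
    rise_shift_lines: int = 0
    rise_k_sigma: float = 3.0
    rise_persist_lines: int = 5
    fit_points: int = 7
    baseline_window_ms: float = 120.0
    baseline_gap_ms: float = 60.0
    beats_to_analyze: int | None = None
    width_smooth_lines: int = 15
    median_radius_px: int = 1
    threshold: float | None = None
    cell_contrast_min: float = 2.0
    rise_floor_rel: float = 1e-3
    contraction_lead_ms: float = 150.0
    velocity_fit_min_lines: int = 51
    trace_smooth_lines: int = 15

    def __post_init__(self):
        if self.search_start_ms < 0:
            raise ValueError("search_start_ms must be >= 0")
        if self.fit_points < 3 or self.fit_points % 2 == 0:
            raise ValueError("fit_points must be an odd integer >= 3")
        if self.rise_persist_lines < 1:
            raise ValueError("rise_persist_lines must be >= 1")
        if self.pacing_hz <= 0:
            raise ValueError("pacing_hz must be positive")

    @property
    def pacing_period_ms(self) -> float:
        return 1000.0 / self.pacing_hz

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class TransientMetrics:
    """Per-beat fluorescence transient parameters (one channel)."""

    f0: float
    noise_sd: float
    dff_max: float
    rise_time_ms: float
    tau50_ms: float
    tau90_ms: float
    t_rise_ms: float
    t_peak_ms: float
    f_peak: float
    baseline_shift: float = math.nan
    flags: list[str] = field(default_factory=list)


@dataclass
class ContractionMetrics:
    """Per-beat cell shortening parameters."""

    baseline_width_um: float
    min_width_um: float
    percent_shortening: float
    contraction_half_ms: float
    relaxation_half_ms: float
    contraction_velocity_um_per_ms: float
    relaxation_velocity_um_per_ms: float
    t_contraction_peak_ms: float
    flags: list[str] = field(default_factory=list)


@dataclass
class CouplingMetrics:
    """Pairwise event-time differences within one beat.

    By construction from shared event times,
    ``v_peak_to_contraction_peak == v_peak_to_ca_peak +
    ca_peak_to_contraction_peak`` exactly.
    """

    v_rise_to_ca_rise_ms: float
    v_peak_to_ca_peak_ms: float
    ca_peak_to_contraction_peak_ms: float
    v_peak_to_contraction_peak_ms: float


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------


def _onset_margin(config: AnalysisConfig, f0: float, noise_sd: float) -> float:
    """Threshold margin above F0: k*sigma with a relative floor."""
    return max(config.rise_k_sigma * noise_sd, config.rise_floor_rel * abs(f0))

def estimate_baseline(trace: np.ndarray, config: AnalysisConfig, *,
                      line_period_ms: float,
                      end_line: int | None = None) -> tuple[float, float]:
    """Baseline level F0 (median) and robust noise SD (1.4826 * MAD).

    The window is the ``baseline_window_ms`` stretch ending at
    ``end_line`` (exclusive; typically the detected first rise).  Fewer
    than 20 lines in the window raises :class:`BaselineError` advising a
    ``search_start_ms`` adjustment.
    """
    trace = np.asarray(trace, dtype=float)
    n_window = int(round(config.baseline_window_ms / line_period_ms))
    end = trace.size if end_line is None else int(end_line)
    start = max(0, end - n_window)
    window = trace[start:end]
    if window.size < 20:
        raise BaselineError(
            f"baseline window has only {window.size} lines before the first "
            "rise; adjust search_start_ms / baseline_window_ms")
    f0 = float(np.median(window))
    sd = float(MAD_TO_SD * median_abs_deviation(window))
    return f0, sd


def detect_first_peak(trace: np.ndarray, config: AnalysisConfig, *,
                      line_period_ms: float,
                      f0: float | None = None,
                      noise_sd: float | None = None) -> tuple[float, float]:
    """(time, value) of the maximum within the first-peak search window.

    The window is ``[search_start_ms, search_start_ms + pacing period)``;
    ties break toward the earliest line.  If ``f0``/``noise_sd`` are
    given, a peak not exceeding ``f0 + rise_k_sigma * noise_sd`` raises
    :class:`RunRejected` ("no_transient").
    """
    trace = np.asarray(trace, dtype=float)
    start = int(round(config.search_start_ms / line_period_ms))
    stop = min(trace.size,
               start + int(round(config.pacing_period_ms / line_period_ms)))
    if stop <= start:
        raise ValueError("empty search window")
    idx = start + int(np.argmax(trace[start:stop]))
    value = float(trace[idx])
    if f0 is not None and noise_sd is not None:
        if value - f0 <= _onset_margin(config, f0, noise_sd):
            raise RunRejected("no_transient",
                              "first peak does not exceed baseline + k*sigma")
    return idx * line_period_ms, value


def detect_rise_start(trace: np.ndarray, f0: float, noise_sd: float,
                      config: AnalysisConfig, *, line_period_ms: float,
                      peak_line: int,
                      window_start_line: int = 0) -> tuple[float, bool]:
    """Onset of the rise preceding the peak at ``peak_line``.

    Earliest line in ``[window_start_line, peak_line)`` where the trace
    exceeds ``f0 + k*sigma`` and stays above for ``rise_persist_lines``
    consecutive lines; the result is then shifted by ``rise_shift_lines``
    and clamped to lie before the peak.  Returns ``(t_rise_ms,
    fallback)``; ``fallback`` is True when no sustained crossing exists
    and the last sub-threshold line before the peak is used instead.
    """
    trace = np.asarray(trace, dtype=float)
    thresh = f0 + _onset_margin(config, f0, noise_sd)
    above = trace > thresh
    persist = config.rise_persist_lines
    rise_idx, fallback = None, False
    for i in range(window_start_line, peak_line):
        seg = above[i:min(i + persist, trace.size)]
        if seg.size and seg.all():
            rise_idx = i
            break
    if rise_idx is None:
        below = np.flatnonzero(~above[window_start_line:peak_line])
        rise_idx = (window_start_line + int(below[-1])
                    if below.size else window_start_line)
        fallback = True
    rise_idx += config.rise_shift_lines
    rise_idx = int(np.clip(rise_idx, 0, max(peak_line - 1, 0)))
    return rise_idx * line_period_ms, fallback


def _crossing_down(trace: np.ndarray, level: float, start: int,
                   stop: int, line_period_ms: float,
                   persist: int = 1) -> float:
    """First downward crossing of ``level`` in [start, stop); interpolated.

    With ``persist > 1`` the trace must stay at or below the level for
    that many consecutive lines, which stops noise spikes from firing the
    crossing early on shallow decays.
    """
    stop = min(stop, trace.size)
    for i in range(start + 1, stop):
        if trace[i] <= level < trace[i - 1]:
            seg = trace[i:min(i + persist, stop)]
            if seg.size and np.all(seg <= level):
                frac = (trace[i - 1] - level) / (trace[i - 1] - trace[i])
                return (i - 1 + frac) * line_period_ms
    return math.nan


def _crossing_up(trace: np.ndarray, level: float, start: int,
                 stop: int, line_period_ms: float) -> float:
    """First upward crossing of ``level`` in [start, stop); interpolated."""
    for i in range(start + 1, min(stop, trace.size)):
        if trace[i] >= level > trace[i - 1]:
            frac = (level - trace[i - 1]) / (trace[i] - trace[i - 1])
            return (i - 1 + frac) * line_period_ms
    return math.nan


def _refine_peak(trace: np.ndarray, rise_line: int, peak_line: int,
                 limit: int, h: float) -> tuple[float, float]:
    """Sub-line estimate of (t_peak_ms, F_peak) at a rise/decay corner.

    A trace sampled at the line period catches the peak of a fast upstroke
    up to one line late, losing ``1 - exp(-h/tau)`` of the amplitude and
    biasing the decay times.  Fitting a line to the last rise samples and
    another to the first decay samples and intersecting them recovers the
    corner to second order.  Falls back to the raw sample when either side
    has too few samples or the intersection leaves the bracketing lines.
    """
    t_raw, f_raw = peak_line * h, float(trace[peak_line])
    decay_idx = np.arange(peak_line + 1, min(peak_line + 5, limit))
    rise_idx = np.arange(max(rise_line + 1, peak_line - 4), peak_line)
    if len(decay_idx) < 2 or len(rise_idx) < 2:
        return t_raw, f_raw
    pr = np.polyfit(rise_idx * h, trace[rise_idx], 1)
    pd_ = np.polyfit(decay_idx * h, trace[decay_idx], 1)
    if pr[0] <= pd_[0]:
        return t_raw, f_raw
    t_star = (pd_[1] - pr[1]) / (pr[0] - pd_[0])
    f_star = np.polyval(pr, t_star)
    if not (t_raw - h <= t_star <= t_raw + h) or f_star < f_raw:
        return t_raw, f_raw
    return float(t_star), float(f_star)


def transient_metrics(trace: np.ndarray, config: AnalysisConfig, *,
                      line_period_ms: float, f0: float, noise_sd: float,
                      peak_line: int, rise_line: int,
                      decay_limit_line: int | None = None) -> TransientMetrics:
    """Amplitude, rise time and decay times for one beat.

    ``dff_max = (F_peak - F0) / F0``; ``rise_time = t_peak - t_rise``;
    ``tau_f`` is the time from the peak to the first interpolated crossing
    of ``F_peak - f * (F_peak - F0)``.  A trace ending before the 90%
    crossing leaves tau90 missing and flags the beat truncated.
    """
    trace = np.asarray(trace, dtype=float)
    limit = trace.size if decay_limit_line is None else int(decay_limit_line)
    t_peak, f_peak = _refine_peak(trace, rise_line, peak_line, limit,
                                  line_period_ms)
    t_rise = rise_line * line_period_ms
    m = int(config.trace_smooth_lines)
    smoothed = uniform_filter1d(trace, size=m, mode="nearest") if m > 1 else trace
    # the boxcar flattens the sharp peak itself, so crossings are searched
    # from the smoothed maximum near the peak (== the raw peak when
    # smoothing is off); the flattening extends at most m lines
    hi = min(peak_line + max(m, 1) + 1, limit)
    scan_from = peak_line + int(np.argmax(smoothed[peak_line:hi]))
    flags: list[str] = []
    taus = {}
    for frac in (0.5, 0.9):
        level = f_peak - frac * (f_peak - f0)
        t_cross = _crossing_down(smoothed, level, scan_from, limit,
                                 line_period_ms, persist=5)
        if not math.isnan(t_cross):
            # refine by a short local regression: a single interpolated
            # sample under noise systematically fires early on a shallow
            # tail, a fitted line through the neighbourhood does not
            i = int(t_cross / line_period_ms)
            half_w = 32
            lo, hi_ = max(scan_from, i - half_w), min(limit, i + half_w + 1)
            if hi_ - lo >= 9:
                t_loc = (np.arange(lo, hi_) - i) * line_period_ms
                coef = np.polyfit(t_loc, smoothed[lo:hi_], 2)
                roots = np.roots(coef - [0.0, 0.0, level])
                roots = roots[np.isreal(roots)].real
                if roots.size:
                    t_fit = i * line_period_ms + roots[np.argmin(np.abs(roots))]
                    if abs(t_fit - t_cross) <= half_w * line_period_ms:
                        t_cross = t_fit
        if math.isnan(t_cross):
            flags.append("truncated")
            taus[frac] = math.nan
        else:
            taus[frac] = t_cross - t_peak
    return TransientMetrics(
        f0=f0, noise_sd=noise_sd,
        dff_max=(f_peak - f0) / f0,
        rise_time_ms=t_peak - t_rise,
        tau50_ms=taus[0.5], tau90_ms=taus[0.9],
        t_rise_ms=t_rise, t_peak_ms=t_peak, f_peak=f_peak,
        flags=flags)


# --------------------------------------------------------------------------
# per-channel beat-train analysis
# --------------------------------------------------------------------------

@dataclass
class ChannelAnalysis:
    channel: str
    f0: float
    noise_sd: float
    beats: list[TransientMetrics]


def _sliding_slopes(y: np.ndarray, k: int, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope of every k-point window.

    Returns ``(centers, slopes)`` where ``centers`` are the window-centre
    line indices.  Exact for data that are linear within the window.
    """
    n = y.size
    if k > n:
        k = n if n % 2 == 1 else n - 1
    half = (k - 1) // 2
    x = (np.arange(k) - half) * h
    denom = float((x ** 2).sum())
    weights = x / denom
    slopes = np.correlate(y, weights, mode="valid")
    centers = np.arange(half, n - half)
    return centers, slopes


def analyze_trace(values: np.ndarray, config: AnalysisConfig, *,
                  line_period_ms: float, channel: str = "") -> ChannelAnalysis:
    """Find all beats in one corrected fluorescence trace.

    The first beat's peak is searched in the configured window; later
    windows step by one pacing period.  Beats whose peak sits on the very
    first line of a window (a monotone decay tail, not a true peak) or
    fails the amplitude test are skipped with no metrics.
    """
    trace = np.asarray(values, dtype=float)
    h = line_period_ms
    period_lines = int(round(config.pacing_period_ms / h))
    s0 = int(round(config.search_start_ms / h))

    t_peak_ms, _ = detect_first_peak(trace, config, line_period_ms=h)
    first_peak = int(round(t_peak_ms / h))
    gap = int(round(config.baseline_gap_ms / h))
    f0_prov, sd_prov = estimate_baseline(trace, config, line_period_ms=h,
                                         end_line=max(first_peak - gap, 0))
    if trace[first_peak] - f0_prov <= _onset_margin(config, f0_prov, sd_prov):
        raise RunRejected("no_transient",
                          "first peak does not exceed baseline + k*sigma")
    t_rise_ms, _ = detect_rise_start(trace, f0_prov, sd_prov, config,
                                     line_period_ms=h, peak_line=first_peak,
                                     window_start_line=s0)
    first_rise = int(round(t_rise_ms / h))
    f0, noise_sd = estimate_baseline(trace, config, line_period_ms=h,
                                     end_line=first_rise)

    beats: list[TransientMetrics] = []
    k = 0
    while True:
        w_start = s0 + k * period_lines
        w_stop = min(w_start + period_lines, trace.size)
        if w_stop - w_start < max(2 * config.rise_persist_lines, 10):
            break
        if config.beats_to_analyze is not None and len(beats) >= config.beats_to_analyze:
            break
        peak = w_start + int(np.argmax(trace[w_start:w_stop]))
        ok = trace[peak] - f0 > _onset_margin(config, f0, noise_sd)
        interior = peak > w_start
        if k == 0 and not ok:
            raise RunRejected("no_transient",
                              "first peak does not exceed baseline + k*sigma")
        if ok and (interior or k == 0):
            rise_ms, fallback = detect_rise_start(
                trace, f0, noise_sd, config, line_period_ms=h,
                peak_line=peak, window_start_line=w_start)
            limit = min(w_stop + period_lines, trace.size)
            m = transient_metrics(trace, config, line_period_ms=h, f0=f0,
                                  noise_sd=noise_sd, peak_line=peak,
                                  rise_line=int(round(rise_ms / h)),
                                  decay_limit_line=limit)
            if fallback:
                m.flags.append("rise_fallback")
            beats.append(m)
        if w_stop >= trace.size:
            break
        k += 1

    # change in baseline after the first stimulus: window immediately
    # preceding the second beat's rise, compared against F0
    if len(beats) >= 2:
        r1 = int(round(beats[1].t_rise_ms / h))
        n_window = int(round(config.baseline_window_ms / h))
        p0 = int(round(beats[0].t_peak_ms / h))
        start = max(r1 - n_window, p0 + 1)
        if r1 - start >= 5:
            beats[0].baseline_shift = \
                (float(np.median(trace[start:r1])) - f0) / f0
    return ChannelAnalysis(channel=channel, f0=f0, noise_sd=noise_sd,
                           beats=beats)


# --------------------------------------------------------------------------
# contraction
# --------------------------------------------------------------------------

@dataclass
class ContractionContext:
    """Beat window and baseline bounds handed to :func:`contraction_metrics`."""

    baseline_end_line: int        # exclusive end of the diastolic window
    window_start_line: int
    window_stop_line: int


def contraction_metrics(width: WidthTrace, context: ContractionContext,
                        config: AnalysisConfig) -> ContractionMetrics:
    """Shortening amplitude, timing and velocities for one beat.

    ``W0`` is the pre-rise median width and ``W_min`` the raw in-window
    minimum (both quantization-accurate to half a pixel); percent
    shortening is ``100 (W0 - W_min) / W0``.  Velocities are the largest
    magnitude slope among sliding ``fit_points``-line straight-line fits
    on the smoothed width trace, separately for the falling and rising
    phases.  Contraction onset is the extrapolated baseline intercept of
    the maximum-slope falling line; the contraction-peak time is the
    intersection of the two maximum-slope lines; half-times are measured
    from onset (contraction) and from the contraction peak (relaxation)
    to the interpolated crossings of the 50% recovery level.
    """
    w = np.asarray(width.width_um, dtype=float)
    h = float(width.times_ms[1] - width.times_ms[0])
    m = int(config.width_smooth_lines)
    ws = uniform_filter1d(w, size=m, mode="nearest") if m > 1 else w

    b_end = context.baseline_end_line
    n_window = int(round(config.baseline_window_ms / h))
    b_start = max(0, b_end - n_window)
    base = w[b_start:b_end]
    if base.size < 5:
        raise BaselineError("too few diastolic lines before the first rise")
    w0 = float(np.median(base))
    flags: list[str] = []

    a, b = context.window_start_line, min(context.window_stop_line, w.size)
    if b - a < config.fit_points:
        raise ValueError("beat window shorter than the fit window")
    w_min = float(w[a:b].min())
    if w_min >= w0:
        raise RunRejected("no_contraction",
                          "width never falls below its diastolic baseline")
    shortening = 100.0 * (w0 - w_min) / w0

    i_min = a + int(np.argmin(ws[a:b]))

    def best_line(lo: int, hi: int, sign: float):
        """Steepest fit line (slope*sign maximal) over [lo, hi)."""
        nonlocal flags
        seg = ws[lo:hi]
        # the fit must span many one-pixel quantization steps; for the
        # slowest phases that means a window growing with the phase length
        k = max(config.fit_points, config.velocity_fit_min_lines,
                int(round(0.4 * seg.size)) | 1)
        if seg.size < k:
            k = seg.size if seg.size % 2 == 1 else seg.size - 1
            if k < config.fit_points:
                flags.append("fit_window_shrunk")
        if k < 3:
            return math.nan, math.nan, math.nan
        centers, slopes = _sliding_slopes(seg, k, h)
        j = int(np.argmax(sign * slopes))
        centre_idx = lo + centers[j]
        half = (k - 1) // 2
        y_mean = float(seg[centers[j] - half:centers[j] + half + 1].mean())
        return float(slopes[j]), centre_idx * h, y_mean

    # bound the fits to the active part of each phase: outside the dip the
    # trace is flat baseline, and a window leaking onto it dilutes the slope
    depth = w0 - w_min
    active = ws < w0 - 0.05 * depth
    lo_fall = a + int(np.argmax(active[a:i_min + 1])) if active[a:i_min + 1].any() else a
    rise_inactive = ~active[i_min:b]
    hi_rise = i_min + int(np.argmax(rise_inactive)) if rise_inactive.any() else b
    hi_rise = max(hi_rise, i_min + 2)

    s_fall, t_fall, y_fall = best_line(lo_fall, i_min + 1, -1.0)
    s_rise, t_rise_l, y_rise = best_line(i_min, hi_rise, +1.0)

    # contraction-peak time: intersection of the two max-slope lines,
    # falling back to the centre of the raw minimum plateau
    t_min = math.nan
    if s_fall < 0 < s_rise:
        t_star = ((y_rise - y_fall + s_fall * t_fall - s_rise * t_rise_l)
                  / (s_fall - s_rise))
        if t_fall <= t_star <= t_rise_l:
            t_min = t_star
    if math.isnan(t_min):
        plateau = np.flatnonzero(w[a:b] == w_min) + a
        t_min = float(plateau.mean()) * h
        flags.append("vertex_fallback")

    onset = math.nan
    if s_fall < 0:
        onset = t_fall + (w0 - y_fall) / s_fall
        onset = float(np.clip(onset, a * h, t_min))

    half_level = w0 - 0.5 * (w0 - w_min)
    i_on = int(onset / h) if not math.isnan(onset) else a
    t_half_down = _crossing_down(ws, half_level, max(a, i_on), i_min + 1, h)
    t_half_up = _crossing_up(ws, half_level, max(i_min, 1), b, h)
    c_half = t_half_down - onset if not math.isnan(t_half_down) else math.nan
    r_half = t_half_up - t_min if not math.isnan(t_half_up) else math.nan
    if math.isnan(t_half_up):
        flags.append("truncated")

    return ContractionMetrics(
        baseline_width_um=w0, min_width_um=w_min,
        percent_shortening=shortening,
        contraction_half_ms=c_half, relaxation_half_ms=r_half,
        contraction_velocity_um_per_ms=abs(s_fall) if not math.isnan(s_fall) else math.nan,
        relaxation_velocity_um_per_ms=abs(s_rise) if not math.isnan(s_rise) else math.nan,
        t_contraction_peak_ms=t_min, flags=flags)


def coupling_metrics(v: TransientMetrics | None, ca: TransientMetrics | None,
                     contraction: ContractionMetrics | None) -> CouplingMetrics:
    """Pairwise differences of the stored event times; no re-detection."""
    nan = math.nan
    t_vr = v.t_rise_ms if v else nan
    t_vp = v.t_peak_ms if v else nan
    t_cr = ca.t_rise_ms if ca else nan
    t_cp = ca.t_peak_ms if ca else nan
    t_ctr = contraction.t_contraction_peak_ms if contraction else nan
    return CouplingMetrics(
        v_rise_to_ca_rise_ms=t_cr - t_vr,
        v_peak_to_ca_peak_ms=t_cp - t_vp,
        ca_peak_to_contraction_peak_ms=t_ctr - t_cp,
        v_peak_to_contraction_peak_ms=t_ctr - t_vp)


# --------------------------------------------------------------------------
# whole-run driver
# --------------------------------------------------------------------------

@dataclass
class BeatMetrics:
    beat: int
    voltage: TransientMetrics | None
    calcium: TransientMetrics | None
    contraction: ContractionMetrics | None
    coupling: CouplingMetrics
    flags: list[str] = field(default_factory=list)


@dataclass
class RunResult:
    run_id: str
    animal_id: str
    condition: str
    status: str                    # "ok" | "rejected"
    reason_code: str | None
    beats: list[BeatMetrics]
    mask: CellMaskSeries | None = None
    width: WidthTrace | None = None
    search_start_ms: float = 0.0

    def to_rows(self) -> list[dict]:
        """One metrics-CSV row per accepted beat."""
        rows = []
        for bm in self.beats:
            v, ca, ctr, cpl = bm.voltage, bm.calcium, bm.contraction, bm.coupling
            nan = math.nan
            flags = list(bm.flags)
            for part in (v, ca, ctr):
                if part is not None:
                    flags.extend(part.flags)
            rows.append({
                "condition": self.condition, "animal_id": self.animal_id,
                "run_id": self.run_id, "beat": bm.beat,
                "t_stim_window_ms": self.search_start_ms,
                "v_f0": v.f0 if v else nan,
                "v_dff_max": v.dff_max if v else nan,
                "v_rise_time_ms": v.rise_time_ms if v else nan,
                "v_tau90_ms": v.tau90_ms if v else nan,
                "v_t_rise_ms": v.t_rise_ms if v else nan,
                "v_t_peak_ms": v.t_peak_ms if v else nan,
                "v_baseline_shift": v.baseline_shift if v else nan,
                "ca_f0": ca.f0 if ca else nan,
                "ca_dff_max": ca.dff_max if ca else nan,
                "ca_rise_time_ms": ca.rise_time_ms if ca else nan,
                "ca_tau50_ms": ca.tau50_ms if ca else nan,
                "ca_tau90_ms": ca.tau90_ms if ca else nan,
                "ca_t_rise_ms": ca.t_rise_ms if ca else nan,
                "ca_t_peak_ms": ca.t_peak_ms if ca else nan,
                "ca_baseline_shift": ca.baseline_shift if ca else nan,
                "baseline_width_um": ctr.baseline_width_um if ctr else nan,
                "min_width_um": ctr.min_width_um if ctr else nan,
                "percent_shortening": ctr.percent_shortening if ctr else nan,
                "contraction_half_ms": ctr.contraction_half_ms if ctr else nan,
                "relaxation_half_ms": ctr.relaxation_half_ms if ctr else nan,
                "contraction_velocity_um_per_ms":
                    ctr.contraction_velocity_um_per_ms if ctr else nan,
                "relaxation_velocity_um_per_ms":
                    ctr.relaxation_velocity_um_per_ms if ctr else nan,
                "t_contraction_peak_ms":
                    ctr.t_contraction_peak_ms if ctr else nan,
                "v_rise_to_ca_rise_ms": cpl.v_rise_to_ca_rise_ms,
                "v_peak_to_ca_peak_ms": cpl.v_peak_to_ca_peak_ms,
                "ca_peak_to_contraction_peak_ms":
                    cpl.ca_peak_to_contraction_peak_ms,
                "v_peak_to_contraction_peak_ms":
                    cpl.v_peak_to_contraction_peak_ms,
                "qc_flags": ";".join(sorted(set(flags))),
            })
        return rows


def analyze_run(kymo: Kymograph, config: AnalysisConfig | None = None) -> RunResult:
    """Segment a kymograph and extract every per-beat parameter.

    Runs the full chain — threshold, mask, width trace, width-corrected
    voltage and Ca2+ traces, per-beat transient, contraction and coupling
    metrics — and returns a :class:`RunResult`; run-level rejections are
    reported with machine-readable reason codes instead of raising.
    """
    config = config or AnalysisConfig()
    result = RunResult(run_id=kymo.run_id, animal_id=kymo.animal_id,
                       condition=kymo.condition, status="ok",
                       reason_code=None, beats=[],
                       search_start_ms=config.search_start_ms)

    def rejected(code: str) -> RunResult:
        result.status, result.reason_code = "rejected", code
        return result

    try:
        threshold = (config.threshold if config.threshold is not None else
                     select_threshold(kymo.voltage, "auto",
                                      config.median_radius_px))
    except ThresholdError:
        return rejected("no_cell")
    try:
        mask = build_mask(kymo.voltage, threshold, config.median_radius_px)
    except RunRejected as err:
        return rejected(err.reason_code)
    in_mean = float(kymo.voltage[mask.mask].mean())
    out_mean = float(kymo.voltage[~mask.mask].mean()) if (~mask.mask).any() else 0.0
    if out_mean > 0 and in_mean / out_mean < config.cell_contrast_min:
        return rejected("no_cell")

    result.mask = mask
    width = width_from_mask(mask, kymo.pixel_size_um, kymo.line_period_ms)
    result.width = width
    v_trace = width_corrected_trace(kymo.voltage, mask, channel="voltage")
    ca_trace = width_corrected_trace(kymo.calcium, mask, channel="calcium")

    h = kymo.line_period_ms
    try:
        v_an = analyze_trace(v_trace.values, config, line_period_ms=h,
                             channel="voltage")
        ca_an = analyze_trace(ca_trace.values, config, line_period_ms=h,
                              channel="calcium")
    except (RunRejected, BaselineError) as err:
        code = err.reason_code if isinstance(err, RunRejected) else "no_transient"
        return rejected(code)

    period_lines = int(round(config.pacing_period_ms / h))
    n_beats = min(len(v_an.beats), len(ca_an.beats))
    first_rise_line = int(round(v_an.beats[0].t_rise_ms / h)) if v_an.beats else 0
    lead_lines = int(round(config.contraction_lead_ms / h))
    for b in range(n_beats):
        v_m, ca_m = v_an.beats[b], ca_an.beats[b]
        # shortening can begin before the stimulus-aligned fluorescence
        # peak, so the contraction window opens before the voltage rise
        w_start = max(int(round(v_m.t_rise_ms / h)) - lead_lines, 0)
        ctx = ContractionContext(
            baseline_end_line=max(first_rise_line - lead_lines, 0),
            window_start_line=w_start,
            window_stop_line=min(w_start + period_lines, kymo.n_lines))
        beat_flags: list[str] = []
        try:
            ctr = contraction_metrics(width, ctx, config)
        except RunRejected as err:
            ctr = None
            beat_flags.append(err.reason_code)
        except (ValueError, BaselineError):
            ctr = None
            beat_flags.append("contraction_failed")
        cpl = coupling_metrics(v_m, ca_m, ctr)
        result.beats.append(BeatMetrics(beat=b, voltage=v_m, calcium=ca_m,
                                        contraction=ctr, coupling=cpl,
                                        flags=beat_flags))
    if not result.beats:
        return rejected("no_transient")
    return result
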