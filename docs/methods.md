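# Methods

This note documents the models, estimators and numerical choices behind
`ecckymo`, in the order data flows through the package.

## Acquisition model

A kymograph is an XT image: rows are successive line scans (line *i* at
time *i·h*, line period *h* = 1.24 ms for a three-channel scan, ~806 Hz),
columns are positions along a scan line drawn through the long axis of
one isolated cardiomyocyte. Three channels are registered per line:
voltage reporter (green; also outlines the cell because the dye
concentrates on membranes), Ca²⁺ reporter (red), transmitted light. The
default geometry is 512 pixels at 0.25 µm and 5000 lines (6.2 s) with
1 Hz field pacing. Field stimulation is not synchronized to the line
clock, so the stimulus phase relative to the line grid is arbitrary; the
simulator randomizes it per run, and the analysis exposes the same
operator-set first-peak search window the original spreadsheet workflow
used.

## The simulator (`ecckymo.sim`)

**Fluorescence.** Traces are normalized to a diastolic baseline of 1.
Each stimulus adds a pulse rising linearly (optionally half-cosine) from
0 to `amp_dff` over `rise_ms`, then decaying per a decay law. Pulses
superpose additively; incomplete decay (<99%) before the next stimulus
sets an `overlap` warning flag.

*Decay laws.* The AP decays single-exponentially with τ = Tau90/ln 10.
The Ca²⁺ transient's measured half-recovery pair (Tau1/2 = 90.5 ms,
Tau90 = 235.6 ms; ratio 0.384) cannot come from any single exponential
(which forces ln 2/ln 10 ≈ 0.301) nor from any positive-weight mixture of
two exponentials (completely monotone decays only lower the ratio). The
solver `decay_from_half_times` therefore admits weights above 1 — a
compensating negative fast component that produces an initial shoulder —
scans the tail time constant over a grid, root-solves (weight, fast τ)
for each candidate, keeps the first *monotone* curve, and verifies both
half-times by bisection on the analytic curve.

**Shortening.** Cell width along the scan line is baseline *W₀* with one
dip per beat: a piecewise-linear fall over `2·contraction_half_ms` to
`W₀·(1 − shortening/100)` and a linear recovery over
`2·relaxation_half_ms` (half-cosine optional). The true velocities are
the segment slopes `depth/(2·half_time)`. The representative
velocities are not independent inputs: a maximum relaxation velocity of
0.013 µm/ms is arithmetically incompatible with a 110.36 ms half-time at
any shortening depth above 2.87 µm (the *mean* slope to the half level
would exceed the claimed *maximum*), so the pulse is parametrized by
depth and half-times only and velocities are derived ground truth. The
default diastolic length, 92.8 µm, is chosen so the default pulse's
contraction velocity equals the representative 0.037 µm/ms; the implied
relaxation velocity is then 0.0143 µm/ms.

**Rendering.** Per line the cell occupies `round(width/pixel_size)`
contiguous pixels centred on `cell_center_px` (so the in-cell pixel count
conserves `round(width/pixel_size)` exactly, which the tests verify
against a geometric oracle). Voltage in-cell intensity is
`cell_intensity·v(t)` with the outermost pixel on each side multiplied by
`membrane_gain` (default 2.0; a minimal one-pixel model of membrane
accumulation, sufficient for thresholding). Ca²⁺ is
`cell_intensity·ca(t)`; transmitted is a constant plateau; background is
`background_intensity` (default 20 vs 200 in-cell). Additive Gaussian
noise of `noise_sd` (default 10, i.e. 5% of cell intensity; PMT noise at
these intensities is near-Gaussian; Poisson available behind
`noise_model="poisson"`) is applied from the stored seed and intensities
are clipped at 0. Identical parameters and seed give bit-identical
images.

**Cohorts.** `generate_cohort` draws per-cell parameters log-normally
around group means with a coefficient of variation (default 0.15,
mean-preserving; CV 0 reproduces the means exactly). The Ca²⁺ τ pair
shares one multiplier per cell so the Tau90 > Tau1/2 ordering survives
sampling. The stimulus phase is uniform over one pacing period per cell;
the pixel size grows for cells longer than 80% of the scan line
(acquisitions chose the line length per cell). The default female group
mean is the representative single-cell parameter set; the male group
encodes the reported percent contrasts (APD90/1.37, peak depolarization
/1.06, Ca²⁺ rise 10 ms faster, Ca²⁺ τ pair /1.15, AP→Ca rise delay
−1.1 ms, contraction and relaxation half-times /1.29 and /1.31 — i.e.
+29%/+31% velocity at equal shortening — and Ca-peak→contraction /1.07).
Group means ± SD are not published for most metrics, so these cohorts
are plausible reconstructions of the stated contrasts, not calibrated
fits; passing contrast tests shows the pipeline resolves contrasts of
this size at this n, nothing more.

## Segmentation (`ecckymo.segment`)

One threshold per animal montage (runs placed side by side), selected by
Otsu's method on the median-filtered (3×3 by default) voltage channel,
with a manual override; the threshold must fall strictly inside the
intensity range. The mask keeps, per line, only the longest contiguous
above-threshold run (single-cell assumption; detached speckles excluded;
left-most run on ties). Lines with an empty mask are flagged invalid and
linearly interpolated; runs with more than 5% invalid lines are rejected.
Width is the in-run pixel count times the pixel size — deliberately the
macro-style pixel-count estimate, so it is quantized to one pixel.
Width-corrected traces are per-line means over in-mask pixels only,
computed over the compacted pixel vector so they are bit-identical to a
naive masked mean.

## Metric extraction (`ecckymo.transients`)

Baseline F0 is the median (noise = 1.4826·MAD) of a 120 ms window ending
at the detected first rise. Peaks are windowed argmaxes (ties to the
earliest line), one pacing period per beat starting at the operator-set
`search_start_ms`; a peak must exceed F0 by `max(k·σ, 10⁻³·F0)` (k = 3).
The absolute floor exists because a noiseless width-corrected voltage
trace is not perfectly flat: the two membrane-rim pixels gain weight as
the cell narrows, a ~3·10⁻⁵ relative systematic that would otherwise
trigger a σ = 0 threshold. Rise onset is the earliest line before the
peak that exceeds the threshold for 5 consecutive lines, then shifted by
the manual `rise_shift_lines` (kept for fidelity to the semiautomatic
workflow) and clamped before the peak.

**Peak refinement.** Sampling a sharp AP peak at 1.24 ms loses up to
`1 − e^(−h/τ)` ≈ 2% of amplitude and biases Tau90 by −2× the sampling
phase. `transient_metrics` therefore estimates (t_peak, F_peak) as the
intersection of a line fit to the last rise samples with a line fit to
the first decay samples — exact to second order at a rise/decay corner —
falling back to the raw sample when either side has fewer than two
points.

**Decay times.** Tau1/2 / Tau90 are the times from the peak to the first
crossing of `F_peak − f·(F_peak − F0)` (f = 0.5, 0.9), linearly
interpolated. The crossing is located on a 15-line boxcar-smoothed copy
of the trace, scanned from the smoothed local maximum, with a 5-line
below-level persistence requirement and a final local quadratic fit
(±32 lines) — a raw first crossing under 5% noise fires up to ~13 ms
early on the shallow AP tail, while the smoothing itself biases an
exponential crossing by well under a line period (ratio
sinh(u)/u, u = m·h/2τ). A trace ending before the 90% crossing leaves
Tau90 missing and flags the beat truncated. APD90 ≡ voltage Tau90.
The baseline-shift metric is the median of the window immediately
preceding the second beat's rise, relative to F0 (undefined for
single-beat analyses).

**Contraction.** The beat window opens `contraction_lead_ms` (150 ms)
before the voltage rise, because with slow kinetics the linear fall
begins before the stimulus-aligned fluorescence peak. W₀ is the pre-rise
median width; W_min the raw in-window minimum; percent shortening is
`100·(W₀ − W_min)/W₀`. All timing runs on a 15-line smoothed width trace:

* *velocities* — the largest-magnitude least-squares slope among sliding
  windows, where the window is the largest of `fit_points` (default 7,
  the exposed spreadsheet parameter), `velocity_fit_min_lines` (51) and
  40% of the active phase, bounded to the part of the phase below 95%
  recovery. Short windows on a one-pixel staircase lock onto quantization
  ripple (a 7-point fit overestimates a slow ramp by >80% unsmoothed,
  ~14% smoothed); a fit spanning many quantization steps averages it out.
* *contraction onset* — the extrapolated intercept of the maximum-slope
  falling line with W₀ (exact for a linear ramp; a threshold crossing on
  quantized data is only defined to half a pixel of depth, ≈ 5 ms at the
  representative slope).
* *contraction-peak time* — the intersection of the falling and rising
  maximum-slope lines (exact for a V-shaped dip; the raw argmin sits on a
  quantization plateau whose asymmetric edges bias it by up to ~7 ms).
  Falls back to the plateau centre when the slopes do not bracket a
  minimum.
* *half-times* — from onset (contraction) and from the contraction peak
  (relaxation) to the interpolated crossings of
  `W₀ − 0.5·(W₀ − W_min)`.

**Quantization floors.** Width is a pixel count, so W₀, W_min and the
half level each carry up to half a pixel (q/2 = 0.125 µm) of rounding.
Mapped through the phase slope *v*, half-times have an irreducible error
floor of roughly `0.75·q/v + h` (≈ 9 ms for the representative
contraction, ≈ 14 ms for relaxation) and percent shortening a floor of
one pixel over the baseline width (≈ 0.27 percentage points at 92.8 µm).
The recovery tests assert these derived bounds for width-derived
half-times and shortening, and the stricter one-line-period / 2% bounds
for everything else. Sub-pixel accuracy would require edge interpolation
rather than pixel counting, which the pixel-count width definition
deliberately forgoes.

**Coupling.** The four offsets are plain differences of the stored event
times (no re-detection), so the additivity identity is exact.

**Run handling.** Runs are rejected with machine-readable codes: no
auto-threshold or in/out intensity contrast below 2 (`no_cell`), >5%
invalid lines (`too_many_invalid_lines`), first peak below threshold
(`no_transient`); a beat whose width never falls below W₀ is flagged
`no_contraction` but the run continues. Windows whose maximum sits on
their first line (a decaying tail, not a beat) are skipped.

## EKG (`ecckymo.ekg`)

Fiducials are inputs (annotation-tool CSV), not detected from raw
voltage. At least four consecutive beats are averaged field-wise before
intervals are computed: QT = Tend − Qonset, QRS = QRSend − Qonset,
JT = QT − QRS (exact), PR, Tpeak–Tend, heart rate = 60000/RR, and
Bazett's correction QTc = QT/√RR_s. JTc applies the same Bazett scaling
to JT; no formula is published for it, so this is a documented package
convention. The sex × age comparison delegates to statsmodels (two-factor
OLS ANOVA, Tukey HSD) and reports mean ± SEM per design cell.

## Cohort statistics (`ecckymo.stats`)

The inference unit is the cell: beats are averaged within a cell before
any test (the animal and condition levels are explicit nested means, and
per-animal summaries are provided to expose pseudoreplication — no
hierarchical test is performed). `compare_conditions` runs a two-sided
Mann–Whitney U (SciPy; exact null for small tie-free samples, verified
in the tests against a full enumeration oracle for n₁+n₂ ≤ 12) and
reports medians and their percent difference. Missing beats are dropped,
never imputed.

## Problem sizes in tests

Recovery sweeps use single-beat runs of 1800–2000 lines (one full
transient plus complete relaxation after a randomized stimulus phase),
50 cells per condition; the contrast cohorts use the full 86 female / 84
male cells at 2000 lines with one analyzed beat per cell. These sizes
keep the whole suite at a few minutes while leaving every assertion at
the tolerances stated above.

## Known limitations

Single rod-shaped cell per line; no Ca²⁺ spark/wave simulation or
detection; no photobleaching, optical point-spread or motion along the
scan line in the simulator; relative (ΔF/F0) readouts only, no absolute
calibration; the synthetic cohorts reproduce stated percent contrasts
with assumed log-normal spread, so they validate sensitivity, not the
biological effect sizes themselves.
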