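"""Cell segmentation, width tracking and width-corrected traces.

The voltage-dye channel demarcates the cell from the background (the dye
concentrates on membranes, so borders are bright).  A single threshold per
animal montage, applied to a median-filtered copy of the voltage channel,
yields a per-line mask; per line only the longest contiguous run of
above-threshold pixels is kept (single-cell assumption: the imaged cell
touches no neighbours).  Cell width is the in-run pixel count times the
pixel size, and the width-corrected fluorescence of a channel is its mean
over the in-mask pixels only — which removes the systematic dip a
fixed-size region of interest shows whenever the cell shortens and
background pixels enter the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu

from .errors import RunRejected, ThresholdError

#: Runs with more than this fraction of invalid (empty-mask) lines are rejected.
MAX_INVALID_FRACTION = 0.05


@dataclass
class CellMaskSeries:
    """Per-line in-cell mask derived from the voltage channel."""

    mask: np.ndarray              # bool, n_lines x n_pixels
    threshold: float
    median_radius_px: int
    invalid_lines: np.ndarray     # bool, n_lines; True where no in-cell pixel

    @property
    def counts(self) -> np.ndarray:
        """In-cell pixel count per line (0 on invalid lines)."""
        return self.mask.sum(axis=1)


@dataclass
class WidthTrace:
    """Cell width over time, invalid lines linearly interpolated."""

    width_um: np.ndarray
    times_ms: np.ndarray
    interpolated: np.ndarray      # bool flags for interpolated lines


@dataclass
class CorrectedTrace:
    """Per-line mean fluorescence over in-mask pixels only."""

    values: np.ndarray
    channel: str
    corrected: bool = True
    interpolated: np.ndarray | None = None


def _median_filtered(image: np.ndarray, radius_px: int) -> np.ndarray:
    if radius_px < 0:
        raise ValueError("median_radius_px must be >= 0")
    if radius_px == 0:
        return np.asarray(image, dtype=float)
    size = 2 * radius_px + 1
    return median_filter(np.asarray(image, dtype=float), size=size)


def select_threshold(voltage_image: np.ndarray, mode="auto",
                     median_radius_px: int = 1) -> float:
    """Choose the cell/background threshold for an animal's montage.

    ``mode="auto"`` returns Otsu's threshold on the median-filtered
    voltage channel; a numeric mode (or ``"manual:<value>"``) returns that
    value.  Either way the threshold must lie strictly between the image
    minimum and maximum; a constant image cannot be auto-thresholded and
    raises :class:`ThresholdError` advising a manual value.
    """
    img = np.asarray(voltage_image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = float(img.min()), float(img.max())
    if isinstance(mode, str) and mode.startswith("manual:"):
        mode = float(mode.split(":", 1)[1])
    if isinstance(mode, (int, float)) and not isinstance(mode, bool):
        t = float(mode)
        if not lo < t < hi:
            raise ThresholdError(
                f"manual threshold {t} not strictly inside intensity range "
                f"({lo}, {hi})")
        return t
    if mode != "auto":
        raise ValueError(f"unknown threshold mode {mode!r}")
    filt = _median_filtered(img, median_radius_px)
    flo, fhi = float(filt.min()), float(filt.max())
    if fhi <= flo:
        raise ThresholdError(
            "constant image: automatic thresholding impossible; supply a "
            "manual threshold")
    t = float(threshold_otsu(filt))
    if not flo < t < fhi:
        raise ThresholdError(
            "image appears unimodal; supply a manual threshold")
    return t


def _longest_run(row: np.ndarray) -> tuple[int, int]:
    """(start, stop) of the longest True run; stop exclusive; (0, 0) if none.

    Ties are broken toward the leftmost run.
    """
    padded = np.concatenate(([False], row, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    if edges.size == 0:
        return 0, 0
    starts, stops = edges[::2], edges[1::2]
    best = int(np.argmax(stops - starts))
    return int(starts[best]), int(stops[best])


def build_mask(voltage_channel: np.ndarray, threshold: float,
               median_radius_px: int = 1) -> CellMaskSeries:
    """Threshold the median-filtered voltage channel into a per-line mask.

    Per line only the longest contiguous above-threshold run survives,
    which excludes detached noise speckles.  Lines with no in-cell pixel
    are flagged invalid; a run with more than 5% invalid lines is
    rejected with a diagnostic.
    """
    img = np.asarray(voltage_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("voltage channel must be 2D (lines x pixels)")
    if not img.min() <= threshold <= img.max():
        raise ValueError(
            f"threshold {threshold} outside intensity range "
            f"[{img.min()}, {img.max()}]")
    above = _median_filtered(img, median_radius_px) > threshold
    mask = np.zeros_like(above)
    invalid = np.zeros(above.shape[0], dtype=bool)
    for i in range(above.shape[0]):
        start, stop = _longest_run(above[i])
        if stop == start:
            invalid[i] = True
        else:
            mask[i, start:stop] = True
    frac = invalid.mean()
    if frac == 1.0:
        raise RunRejected("no_cell", "no in-cell pixels on any line")
    if frac > MAX_INVALID_FRACTION:
        raise RunRejected(
            "too_many_invalid_lines",
            f"{frac:.1%} of lines have an empty mask "
            f"(limit {MAX_INVALID_FRACTION:.0%})")
    return CellMaskSeries(mask=mask, threshold=float(threshold),
                          median_radius_px=int(median_radius_px),
                          invalid_lines=invalid)


def _interpolate_invalid(values: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    """Linearly interpolate flagged entries from nearest valid neighbours."""
    if not invalid.any():
        return values
    if invalid.all():
        raise RunRejected("no_cell", "every line is invalid")
    idx = np.arange(values.size)
    out = values.astype(float).copy()
    out[invalid] = np.interp(idx[invalid], idx[~invalid], values[~invalid])
    return out


def width_from_mask(mask_series: CellMaskSeries, pixel_size_um: float,
                    line_period_ms: float) -> WidthTrace:
    """Cell width per line: in-run pixel count times the pixel size."""
    if pixel_size_um <= 0 or line_period_ms <= 0:
        raise ValueError("pixel_size_um and line_period_ms must be positive")
    counts = mask_series.counts.astype(float)
    width = _interpolate_invalid(counts * pixel_size_um,
                                 mask_series.invalid_lines)
    times = np.arange(width.size) * line_period_ms
    return WidthTrace(width_um=width, times_ms=times,
                      interpolated=mask_series.invalid_lines.copy())


def width_corrected_trace(channel_image: np.ndarray,
                          mask_series: CellMaskSeries,
                          channel: str = "") -> CorrectedTrace:
    """Mean fluorescence per line over that line's in-mask pixels only."""
    img = np.asarray(channel_image, dtype=float)
    if img.shape != mask_series.mask.shape:
        raise ValueError(
            f"channel shape {img.shape} != mask shape {mask_series.mask.shape}")
    # per-line mean over the compacted in-mask pixels: bit-identical to a
    # naive masked mean (a vectorized sum over the padded row is not)
    values = np.full(img.shape[0], np.nan)
    for i in range(img.shape[0]):
        if not mask_series.invalid_lines[i]:
            values[i] = img[i, mask_series.mask[i]].mean()
    values = _interpolate_invalid(values, mask_series.invalid_lines)
    return CorrectedTrace(values=values, channel=channel, corrected=True,
                          interpolated=mask_series.invalid_lines.copy())


def fixed_roi_trace(channel_image: np.ndarray, roi_columns: np.ndarray,
                    channel: str = "") -> CorrectedTrace:
    """Mean over a fixed set of columns on every line (no width correction).

    This is the naive region-of-interest average the width correction
    replaces; it dips whenever the cell shrinks out of the region.
    """
    img = np.asarray(channel_image, dtype=float)
    roi = np.asarray(roi_columns, dtype=bool)
    if roi.shape != (img.shape[1],):
        raise ValueError("roi_columns must be a boolean vector over pixels")
    values = img[:, roi].mean(axis=1)
    return CorrectedTrace(values=values, channel=channel, corrected=False,
                          interpolated=np.zeros(img.shape[0], dtype=bool))
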