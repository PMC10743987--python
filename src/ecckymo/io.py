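"""Kymograph container, file I/O and per-animal montages.

The native on-disk format is a 3-channel TIFF (channel axis first, then
lines = time, then pixels = space; channel order voltage, calcium,
transmitted light) together with a JSON sidecar that carries acquisition
metadata TIFF tags do not hold reliably: the line period in ms, the pixel
size in um, the channel order and free-form identifiers.  Axis convention
throughout the package: rows are time (line 0 at t = 0, line i at
``i * line_period_ms``), columns are space, all indices 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ChannelCountError, SidecarError

DEFAULT_CHANNELS = ("voltage", "calcium", "transmitted")

#: Stable column order of the per-beat metrics CSV.  Identification columns
#: first, then voltage-transient, calcium-transient, contraction and
#: coupling parameters, then QC flags.  Times in ms, widths in um,
#: velocities in um/ms, amplitudes dimensionless.
METRIC_COLUMNS = [
    "condition",
    "animal_id",
    "run_id",
    "beat",
    "t_stim_window_ms",
    "v_f0",
    "v_dff_max",
    "v_rise_time_ms",
    "v_tau90_ms",
    "v_t_rise_ms",
    "v_t_peak_ms",
    "v_baseline_shift",
    "ca_f0",
    "ca_dff_max",
    "ca_rise_time_ms",
    "ca_tau50_ms",
    "ca_tau90_ms",
    "ca_t_rise_ms",
    "ca_t_peak_ms",
    "ca_baseline_shift",
    "baseline_width_um",
    "min_width_um",
    "percent_shortening",
    "contraction_half_ms",
    "relaxation_half_ms",
    "contraction_velocity_um_per_ms",
    "relaxation_velocity_um_per_ms",
    "t_contraction_peak_ms",
    "v_rise_to_ca_rise_ms",
    "v_peak_to_ca_peak_ms",
    "ca_peak_to_contraction_peak_ms",
    "v_peak_to_contraction_peak_ms",
    "qc_flags",
]


@dataclass
class Kymograph:
    """A 3-channel XT line-scan image of a single cardiomyocyte.

    ``voltage``, ``calcium`` and ``transmitted`` are 2D non-negative
    arrays of identical shape ``(n_lines, n_pixels)``.
    """

    voltage: np.ndarray
    calcium: np.ndarray
    transmitted: np.ndarray
    line_period_ms: float
    pixel_size_um: float
    run_id: str = ""
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        shapes = {self.voltage.shape, self.calcium.shape, self.transmitted.shape}
        if len(shapes) != 1 or self.voltage.ndim != 2:
            raise ValueError(f"all three channels must share one 2D shape, got {shapes}")
        if self.line_period_ms <= 0:
            raise ValueError("line_period_ms must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_lines(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.voltage.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Acquisition time of each line, line 0 at t = 0."""
        return np.arange(self.n_lines) * self.line_period_ms

    @property
    def duration_ms(self) -> float:
        return self.n_lines * self.line_period_ms

    def channel(self, name: str) -> np.ndarray:
        return {"voltage": self.voltage, "calcium": self.calcium,
                "transmitted": self.transmitted}[name]

    def with_ids(self, **ids) -> "Kymograph":
        return replace(self, **ids)


def _default_sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_kymograph(kymo: Kymograph, path, sidecar_path=None) -> None:
    """Write a kymograph as 3-channel TIFF plus JSON sidecar."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _default_sidecar_path(path)
    stack = np.stack([kymo.voltage, kymo.calcium, kymo.transmitted])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "line_period_ms": kymo.line_period_ms,
        "pixel_size_um": kymo.pixel_size_um,
        "channels": list(DEFAULT_CHANNELS),
        "run_id": kymo.run_id,
        "animal_id": kymo.animal_id,
        "condition": kymo.condition,
    }
    sidecar_path.write_text(json.dumps(meta, indent=1))


def read_kymograph(path, sidecar_path=None) -> Kymograph:
    """Read a 3-channel TIFF + JSON sidecar written by :func:`write_kymograph`.

    Raises :class:`ChannelCountError` if the TIFF does not hold exactly
    three channels and :class:`SidecarError` naming any missing metadata
    field.  Truncated files raise rather than returning partial images.
    """
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _default_sidecar_path(path)
    if not sidecar_path.exists():
        raise SidecarError(f"sidecar file not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for fld in ("line_period_ms", "pixel_size_um"):
        if fld not in meta:
            raise SidecarError(f"sidecar is missing required field '{fld}'")
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise ChannelCountError(
            f"expected 3 channels (channel axis first), got shape {arr.shape}")
    order = meta.get("channels", list(DEFAULT_CHANNELS))
    if sorted(order) != sorted(DEFAULT_CHANNELS):
        raise SidecarError(f"unrecognized channel order {order}")
    by_name = {name: arr[i] for i, name in enumerate(order)}
    return Kymograph(
        voltage=by_name["voltage"],
        calcium=by_name["calcium"],
        transmitted=by_name["transmitted"],
        line_period_ms=float(meta["line_period_ms"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        run_id=str(meta.get("run_id", "")),
        animal_id=str(meta.get("animal_id", "")),
        condition=str(meta.get("condition", "")),
    )


@dataclass
class Montage:
    """Horizontal concatenation of an animal's runs, used for threshold
    selection.  ``offsets[i]`` is the first montage column of run ``i``."""

    voltage: np.ndarray
    calcium: np.ndarray
    transmitted: np.ndarray
    offsets: tuple[int, ...]
    run_widths: tuple[int, ...] = field(default=())

    @property
    def n_runs(self) -> int:
        return len(self.offsets)

    def column_to_run(self, col: int) -> tuple[int, int]:
        """Map a montage column back to ``(run_index, pixel)``."""
        if col < 0 or col >= self.voltage.shape[1]:
            raise IndexError(f"column {col} outside montage")
        run = int(np.searchsorted(np.asarray(self.offsets), col, side="right")) - 1
        return run, col - self.offsets[run]

    def run_to_column(self, run: int, pixel: int) -> int:
        if pixel < 0 or pixel >= self.run_widths[run]:
            raise IndexError(f"pixel {pixel} outside run {run}")
        return self.offsets[run] + pixel


def build_montage(runs: Sequence[Kymograph]) -> Montage:
    """Place all of one animal's kymographs side by side (input order)."""
    if len(runs) == 0:
        raise ValueError("need at least one run")
    widths = {r.n_pixels for r in runs}
    if len(widths) != 1:
        raise ValueError(f"mixed pixel counts in montage group: {sorted(widths)}")
    lines = {r.n_lines for r in runs}
    if len(lines) != 1:
        raise ValueError(f"mixed line counts in montage group: {sorted(lines)}")
    w = widths.pop()
    offsets = tuple(i * w for i in range(len(runs)))
    return Montage(
        voltage=np.concatenate([r.voltage for r in runs], axis=1),
        calcium=np.concatenate([r.calcium for r in runs], axis=1),
        transmitted=np.concatenate([r.transmitted for r in runs], axis=1),
        offsets=offsets,
        run_widths=tuple(r.n_pixels for r in runs),
    )


def write_metrics(rows: Iterable[Mapping] | pd.DataFrame, path) -> None:
    """Write per-beat metrics to CSV in the documented column order.

    One row per cell per beat; missing values become empty fields; columns
    outside the schema are appended after it in their incoming order.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows))
    for col in METRIC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col != "qc_flags" else ""
    extra = [c for c in df.columns if c not in METRIC_COLUMNS]
    df = df[METRIC_COLUMNS + extra]
    df.to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
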