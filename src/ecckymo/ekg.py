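"""Rodent surface-EKG interval computation from annotated fiducials.

Wave detection itself is out of scope: the inputs are per-beat fiducial
times (ms from recording start) exported from an annotation tool, one row
per beat.  This module averages consecutive beats, computes the standard
intervals (QT, QRS, JT, PR, Tpeak-Tend), applies Bazett's rate correction
``QTc = QT / sqrt(RR)`` with RR in seconds (and the same correction for
JTc), and runs the two-factor sex-by-age comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

MIN_BEATS_TO_AVERAGE = 4

_ORDERED_FIDUCIALS = ("p_onset", "q_onset", "r_peak", "qrs_end",
                      "t_peak", "t_end")


@dataclass
class EkgBeat:
    """Fiducial times of one cardiac cycle, ms relative to recording start."""

    p_onset: float
    q_onset: float
    r_peak: float
    qrs_end: float
    t_peak: float
    t_end: float
    rr_ms: float
    s_trough: float | None = None
    s_amplitude: float | None = None
    st_height: float | None = None

    def __post_init__(self):
        seq = [getattr(self, f) for f in _ORDERED_FIDUCIALS]
        # strict ordering except qrs_end <= t_peak (the J point may
        # coincide with an early T peak in rodent EKGs)
        pairs = list(zip(_ORDERED_FIDUCIALS, _ORDERED_FIDUCIALS[1:], seq, seq[1:]))
        bad = [(a, b) for a, b, x, y in pairs
               if (x > y if (a, b) == ("qrs_end", "t_peak") else x >= y)]
        if bad:
            raise ValueError(f"fiducial ordering violated: {bad}")
        if self.rr_ms <= 0:
            raise ValueError("rr_ms must be positive")


@dataclass
class EkgIntervals:
    qt_ms: float
    qtc_ms: float
    jt_ms: float
    jtc_ms: float
    pr_ms: float
    qrs_ms: float
    tpeak_tend_ms: float
    heart_rate_bpm: float


def average_beats(beats: Sequence[EkgBeat]) -> EkgBeat:
    """Arithmetic mean of each fiducial over >= 4 consecutive beats."""
    if len(beats) < MIN_BEATS_TO_AVERAGE:
        raise ValueError(
            f"need at least {MIN_BEATS_TO_AVERAGE} consecutive beats, "
            f"got {len(beats)}")
    values = {}
    for f in fields(EkgBeat):
        vals = [getattr(b, f.name) for b in beats]
        if any(v is None for v in vals):
            values[f.name] = None
        else:
            values[f.name] = float(np.mean(vals))
    return EkgBeat(**values)


def compute_intervals(beat: EkgBeat) -> EkgIntervals:
    """Standard intervals; Bazett's correction for QTc and JTc.

    ``QTc = QT / sqrt(RR_s)``; JTc applies the same correction to
    ``JT = QT - QRS`` (so ``jt + qrs = qt`` holds exactly).
    """
    qt = beat.t_end - beat.q_onset
    qrs = beat.qrs_end - beat.q_onset
    jt = qt - qrs
    pr = beat.q_onset - beat.p_onset
    tpe = beat.t_end - beat.t_peak
    rr_s = beat.rr_ms / 1000.0
    return EkgIntervals(
        qt_ms=qt, qtc_ms=qt / math.sqrt(rr_s),
        jt_ms=jt, jtc_ms=jt / math.sqrt(rr_s),
        pr_ms=pr, qrs_ms=qrs, tpeak_tend_ms=tpe,
        heart_rate_bpm=60000.0 / beat.rr_ms)


def read_fiducials(path) -> list[EkgBeat]:
    """Read a fiducial CSV (one row per beat, columns named as EkgBeat)."""
    df = pd.read_csv(path)
    required = [f.name for f in fields(EkgBeat)
                if f.name not in ("s_trough", "s_amplitude", "st_height")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"fiducial CSV is missing columns: {missing}")
    beats = []
    for _, row in df.iterrows():
        kwargs = {f.name: (float(row[f.name]) if f.name in df.columns
                           and pd.notna(row[f.name]) else None)
                  for f in fields(EkgBeat)}
        beats.append(EkgBeat(**kwargs))
    return beats


@dataclass
class SexAgeComparison:
    anova: pd.DataFrame           # two-factor ANOVA table
    tukey: pd.DataFrame           # Tukey HSD pairwise comparisons
    summary: pd.DataFrame         # mean, SEM, n per (sex, age) cell


def compare_sex_age(table: pd.DataFrame, value: str = "qtc_ms",
                    sex: str = "sex", age: str = "age_weeks",
                    alpha: float = 0.05) -> SexAgeComparison:
    """Two-factor (sex x age) ANOVA with Tukey's multiple comparisons.

    Delegates to statsmodels; reports mean +- SEM per design cell.
    Requires at least two levels of each factor.
    """
    import statsmodels.api as sm  # deferred: keeps import cost off the hot path
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table[[sex, age, value]].dropna().copy()
    for factor in (sex, age):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    df = df.rename(columns={sex: "sex_", age: "age_", value: "y_"})
    model = ols("y_ ~ C(sex_) * C(age_)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    cell = df["sex_"].astype(str) + ":" + df["age_"].astype(str)
    tk = pairwise_tukeyhsd(df["y_"].to_numpy(), cell.to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])

    summary = (df.groupby(["sex_", "age_"])["y_"]
               .agg(mean="mean", sem=lambda s: s.std(ddof=1) / math.sqrt(len(s)),
                    n="count")
               .reset_index()
               .rename(columns={"sex_": sex, "age_": age}))
    return SexAgeComparison(anova=anova, tukey=tukey, summary=summary)
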