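"""Cohort aggregation and group comparison of per-cell metrics.

The primary inference unit is the cell: beats are averaged within a cell
before any between-group test, matching a per-cell Mann-Whitney workflow.
Per-animal summaries are available alongside to expose pseudoreplication
(cells from one animal are not independent), though no hierarchical test
is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ID_COLUMNS = ("condition", "animal_id", "run_id", "beat")

LEVELS = ("beat", "cell", "animal", "condition")


def _metric_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns
            if c not in ID_COLUMNS and pd.api.types.is_numeric_dtype(table[c])]


def units_frame(table: pd.DataFrame, level: str) -> pd.DataFrame:
    """Collapse a beat-level metric table to the requested unit of analysis.

    ``beat`` returns the table unchanged; ``cell`` averages beats within
    each (condition, animal, run); ``animal`` then averages cells within
    each animal; ``condition`` averages animals within each condition.
    Each stage is a plain mean, so the nesting is explicit two-stage
    (three-stage) averaging rather than a pooled mean.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    table = table.copy()
    for col in ("condition", "animal_id", "run_id"):
        if col in table.columns:
            # empty identifiers read back from CSV as NaN; a NaN group key
            # would silently drop the rows
            table[col] = table[col].fillna("")
    metrics = _metric_columns(table)
    if level == "beat":
        return table.copy()
    cells = (table.groupby(["condition", "animal_id", "run_id"], sort=False)
             [metrics].mean().reset_index())
    if level == "cell":
        return cells
    animals = (cells.groupby(["condition", "animal_id"], sort=False)
               [metrics].mean().reset_index())
    if level == "animal":
        return animals
    return (animals.groupby(["condition"], sort=False)
            [metrics].mean().reset_index())


def summarize(table: pd.DataFrame, level: str = "cell") -> pd.DataFrame:
    """Per-condition mean, SEM, n, median and IQR for every metric.

    The unit of observation is set by ``level`` (beats are averaged
    within a cell first for the cell level, and so on up the hierarchy).
    Conditions with no observations are omitted with a warning.
    """
    units = units_frame(table, level)
    metrics = _metric_columns(units)
    rows = []
    for condition, grp in units.groupby("condition", sort=False):
        for metric in metrics:
            vals = grp[metric].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                warnings.warn(f"condition {condition!r} has no values for "
                              f"{metric!r}; omitted", stacklevel=2)
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({
                "condition": condition, "metric": metric,
                "mean": vals.mean(),
                "sem": (vals.std(ddof=1) / np.sqrt(vals.size)
                        if vals.size > 1 else np.nan),
                "n": vals.size,
                "median": med, "iqr": q3 - q1,
            })
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    metric: str
    conditions: tuple[str, str]
    n: tuple[int, int]
    u_statistic: float
    p_value: float
    medians: tuple[float, float]
    percent_difference_of_medians: float


def compare_conditions(table: pd.DataFrame, metric: str,
                       level: str = "cell") -> ComparisonResult:
    """Two-sided Mann-Whitney U between exactly two conditions.

    Cell-level values (beats averaged within cell) are compared; the
    exact null distribution is used whenever SciPy's method selection
    allows it (small samples, no ties).  More than two conditions is an
    error — run pairwise calls instead.
    """
    units = units_frame(table, level)
    conditions = list(dict.fromkeys(units["condition"]))
    if len(conditions) != 2:
        raise ValueError(
            f"need exactly two conditions, got {conditions}; compare "
            "pairwise")
    a = units.loc[units["condition"] == conditions[0], metric].dropna()
    b = units.loc[units["condition"] == conditions[1], metric].dropna()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 cells per condition")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    med_a, med_b = float(a.median()), float(b.median())
    pct = 100.0 * (med_b - med_a) / med_a if med_a != 0 else np.nan
    return ComparisonResult(
        metric=metric, conditions=(conditions[0], conditions[1]),
        n=(len(a), len(b)),
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        medians=(med_a, med_b), percent_difference_of_medians=pct)
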