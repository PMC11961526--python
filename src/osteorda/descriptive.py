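"""Exploratory osteometric statistics: group summaries, percent differences,
range overlaps, and boxplot five-number summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import MeasurementMatrix

__all__ = [
    "SummaryRow",
    "group_summary",
    "percent_difference",
    "overlap_range",
    "boxplot_stats",
    "isize_boxplot_table",
]


@dataclass
class SummaryRow:
    group: str
    element: str
    code: str
    n: int
    mean: float
    min: float
    max: float


def group_summary(matrix: MeasurementMatrix, unit: str = "mm") -> pd.DataFrame:
    """Per-(group, variable) n / mean / min / max for one element matrix.

    ``unit`` may be ``mm`` (canonical) or ``cm``.
    """
    if matrix.n == 0:
        raise ValueError("empty matrix")
    factor = {"mm": 1.0, "cm": 0.1}[unit]
    frame = matrix.to_frame()
    rows: list[SummaryRow] = []
    for group, sub in frame.groupby("group", sort=True):
        for code in matrix.variable_codes:
            vals = sub[code].to_numpy(dtype=float) * factor
            rows.append(
                SummaryRow(
                    group=group,
                    element=matrix.element.value,
                    code=code,
                    n=len(vals),
                    mean=float(vals.mean()),
                    min=float(vals.min()),
                    max=float(vals.max()),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def percent_difference(mean_a: float, mean_b: float, symmetric: bool = False) -> float:
    """Percent difference of ``mean_a`` relative to reference ``mean_b``.

    Default convention: ``100 * (a - b) / b`` (asymmetric, second argument
    is the reference group).  With ``symmetric=True`` the denominator is the
    mean of the two values instead.
    """
    if mean_b <= 0 or (symmetric and mean_a + mean_b <= 0):
        raise ValueError("reference mean must be positive")
    denom = (mean_a + mean_b) / 2.0 if symmetric else mean_b
    return 100.0 * (mean_a - mean_b) / denom


def overlap_range(
    range_a: tuple[float, float], range_b: tuple[float, float]
) -> tuple[float, float] | None:
    """Intersection of two min-max ranges, or None when disjoint.

    A single shared point is returned as a degenerate interval.
    """
    (lo_a, hi_a), (lo_b, hi_b) = range_a, range_b
    if lo_a > hi_a or lo_b > hi_b:
        raise ValueError("malformed interval: lo > hi")
    lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
    if lo > hi:
        return None
    return (lo, hi)


def boxplot_stats(values: np.ndarray) -> dict[str, float]:
    """Median, quartiles and Tukey whiskers (1.5 x IQR, clipped to data)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inliers.min()),
        "whisker_hi": float(inliers.max()),
        "n": int(v.size),
    }


def isize_boxplot_table(isize_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Boxplot summary of per-specimen isometric size per group."""
    rows = []
    for group, vals in isize_by_group.items():
        row = {"group": group}
        row.update(boxplot_stats(np.asarray(vals)))
        rows.append(row)
    return pd.DataFrame(rows)
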