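"""Mosimann isometric size / log-shape-ratio decomposition.

For a specimen with positive measurements V_1..V_n:

    iSize  = (1/n) * sum_v ln V_v          (isometric size, log units)
    LSR_v  = ln V_v - iSize                (log shape ratio per variable)

The LSR vector sums to zero by construction, so one component is redundant;
classifier feature vectors drop one LSR (deterministically, the last
variable in registry order) and prepend iSize, giving p features for p
variables.  Scaling every measurement by c > 0 adds ln c to iSize and
leaves every LSR unchanged: size and shape separate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import MeasurementMatrix

__all__ = ["isize", "log_shape_ratios", "SizeShapeFeatures", "size_shape_features", "FeatureTable"]


def _validated(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("values must be a nonempty 1-D vector")
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("all measurement values must be positive and finite")
    return v


def isize(values) -> float:
    """Isometric size: arithmetic mean of natural logs of the measurements."""
    return float(np.mean(np.log(_validated(values))))


def log_shape_ratios(values) -> np.ndarray:
    """Log shape ratios: elementwise ln(value) minus the specimen's iSize."""
    logs = np.log(_validated(values))
    return logs - logs.mean()


@dataclass
class SizeShapeFeatures:
    specimen_id: str
    isize: float
    lsr: np.ndarray  # over all variable codes, in matrix order
    dropped_code: str


@dataclass
class FeatureTable:
    """Classifier feature matrix: [iSize, LSR of all codes but one]."""

    specimen_ids: list[str]
    groups: list  # GroupLabel per specimen
    feature_names: list[str]  # "isize" + "lsr_<code>" retained
    X: np.ndarray  # (n, p)
    dropped_code: str
    element: str
    subset_id: str

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame.insert(0, "specimen_id", self.specimen_ids)
        frame.insert(1, "group", [g.key for g in self.groups])
        return frame


def size_shape_features(
    matrix: MeasurementMatrix, drop_policy: str = "last"
) -> tuple[list[SizeShapeFeatures], FeatureTable]:
    """Per-specimen size/shape features for a complete-case matrix.

    iSize is computed over exactly the matrix's variable subset, so
    fragment-based and complete-bone analyses stay internally consistent.
    ``drop_policy`` picks the redundant LSR component to exclude from the
    classifier features: "last" (default) or "first" in registry order.
    """
    if matrix.p < 2:
        raise ValueError("at least 2 variables required for a shape decomposition")
    logs = np.log(matrix.values)
    sizes = logs.mean(axis=1)
    lsr = logs - sizes[:, None]
    if drop_policy == "last":
        drop_idx = matrix.p - 1
    elif drop_policy == "first":
        drop_idx = 0
    else:
        raise ValueError(f"unknown drop_policy {drop_policy!r}")
    dropped = matrix.variable_codes[drop_idx]
    keep = [i for i in range(matrix.p) if i != drop_idx]
    X = np.column_stack([sizes, lsr[:, keep]])
    names = ["isize"] + [f"lsr_{matrix.variable_codes[i]}" for i in keep]
    per_specimen = [
        SizeShapeFeatures(sid, float(s), r, dropped)
        for sid, s, r in zip(matrix.specimen_ids, sizes, lsr)
    ]
    table = FeatureTable(
        specimen_ids=list(matrix.specimen_ids),
        groups=list(matrix.groups),
        feature_names=names,
        X=X,
        dropped_code=dropped,
        element=matrix.element.value,
        subset_id=matrix.subset_id,
    )
    return per_specimen, table
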