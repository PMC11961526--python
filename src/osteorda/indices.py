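"""Mennerich slenderness indices and two-variable scatter constructions.

ME1 = SD x 100 / GL (smallest diaphysis breadth over greatest length) and
ME3 = Bd / GL x 100 (distal breadth over greatest length) are dimensionless
shape ratios: low values mean slender (gracile) bones.  Plotted against a
raw measurement they give a size-by-shape view that separates sexes and
ecotypes visually.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .filters import MeasurementMatrix
from .io import SpecimenRecord

__all__ = [
    "mennerich_index1",
    "mennerich_index3",
    "IndexPoint",
    "build_scatter",
    "bounding_box_overlap",
]

INDEX_REQUIREMENTS = {"ME1": ("SD", "GL"), "ME3": ("Bd", "GL")}


def _check_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v!r}")


def mennerich_index1(SD: float, GL: float) -> float:
    """Slenderness index 1: smallest diaphysis breadth x 100 / greatest length."""
    _check_positive(SD=SD, GL=GL)
    return SD * 100.0 / GL


def mennerich_index3(Bd: float, GL: float) -> float:
    """Slenderness index 3: distal breadth / greatest length x 100."""
    _check_positive(Bd=Bd, GL=GL)
    return Bd / GL * 100.0


@dataclass
class IndexPoint:
    specimen_id: str
    group: str
    x: float
    y: float
    x_label: str
    y_label: str


def _resolve(spec: str, values: dict[str, float]) -> float | None:
    """Value of a measurement code or index for one specimen, or None."""
    if spec in INDEX_REQUIREMENTS:
        needed = INDEX_REQUIREMENTS[spec]
        if any(c not in values for c in needed):
            return None
        if spec == "ME1":
            return mennerich_index1(values["SD"], values["GL"])
        return mennerich_index3(values["Bd"], values["GL"])
    return values.get(spec)


def build_scatter(
    source: MeasurementMatrix | Sequence[SpecimenRecord],
    x_spec: str,
    y_spec: str,
    unit: str = "mm",
) -> pd.DataFrame:
    """One (x, y) point per specimen possessing every code the specs need.

    ``x_spec`` / ``y_spec`` name a measurement code or an index (ME1, ME3).
    Raw-measurement axes are reported in ``unit`` (mm or cm); indices are
    dimensionless and unaffected.
    """
    factor = {"mm": 1.0, "cm": 0.1}[unit]
    if isinstance(source, MeasurementMatrix):
        known = set(source.variable_codes)
        per_specimen = [
            (sid, g.key, dict(zip(source.variable_codes, row)))
            for sid, g, row in zip(source.specimen_ids, source.groups, source.values)
        ]
    else:
        known = {c for rec in source for c in rec.values}
        per_specimen = [(rec.individual_id, rec.group.key, rec.values) for rec in source]

    for spec in (x_spec, y_spec):
        needed = INDEX_REQUIREMENTS.get(spec, (spec,))
        unknown = [c for c in needed if c not in known]
        if unknown:
            raise ValueError(
                f"{spec!r} needs codes {unknown} absent from this data; "
                f"available: {sorted(known)}"
            )

    points: list[IndexPoint] = []
    for sid, group, values in per_specimen:
        x = _resolve(x_spec, values)
        y = _resolve(y_spec, values)
        if x is None or y is None:
            continue
        if x_spec not in INDEX_REQUIREMENTS:
            x *= factor
        if y_spec not in INDEX_REQUIREMENTS:
            y *= factor
        points.append(IndexPoint(sid, group, float(x), float(y), x_spec, y_spec))
    return pd.DataFrame(
        [p.__dict__ for p in points],
        columns=["specimen_id", "group", "x", "y", "x_label", "y_label"],
    )


def bounding_box_overlap(scatter: pd.DataFrame) -> pd.DataFrame:
    """Non-canonical separability diagnostic: pairwise 2-D bounding-box
    overlap fraction between groups (0 = disjoint boxes, 1 = nested).

    Cluster separation in these plots is conventionally judged by eye; this
    quantitative summary is auxiliary plumbing, not part of the protocol.
    """
    boxes = {}
    for group, sub in scatter.groupby("group"):
        boxes[group] = (
            sub["x"].min(), sub["x"].max(), sub["y"].min(), sub["y"].max()
        )
    rows = []
    groups = sorted(boxes)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            ax0, ax1, ay0, ay1 = boxes[a]
            bx0, bx1, by0, by1 = boxes[b]
            ox = max(0.0, min(ax1, bx1) - max(ax0, bx0))
            oy = max(0.0, min(ay1, by1) - max(ay0, by0))
            area = ox * oy
            denom = min(
                max(ax1 - ax0, 1e-12) * max(ay1 - ay0, 1e-12),
                max(bx1 - bx0, 1e-12) * max(by1 - by0, 1e-12),
            )
            rows.append({"group_a": a, "group_b": b, "overlap": area / denom})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "overlap"])
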