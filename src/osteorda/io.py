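"""Readers and writers for wide-format measurement tables.

Schema (CSV, UTF-8, comma, header row; XLSX first sheet identical):
``individual_id, element, side, ecotype, variety, sex, castrated,
fusion_state, castration_age, collection_year, locality`` followed by one
column per measurement code.  Empty cells mean "not recorded".  Measurements
are stored internally in millimetres; a per-column unit policy converts on
load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .registry import Element, GroupLabel, Registry

__all__ = [
    "SpecimenRecord",
    "ValidationError",
    "load_table",
    "write_table",
    "records_to_frame",
    "frame_to_records",
    "META_COLUMNS",
]

META_COLUMNS = [
    "individual_id",
    "element",
    "side",
    "ecotype",
    "variety",
    "sex",
    "castrated",
    "fusion_state",
    "castration_age",
    "collection_year",
    "locality",
]

_UNIT_FACTORS = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


class ValidationError(ValueError):
    """A table failed record-level validation; message lists row and code."""


@dataclass
class SpecimenRecord:
    """One specimen-element: labels, life history and measurement values (mm)."""

    individual_id: str
    element: Element
    side: str  # left | right | unknown
    group: GroupLabel
    fusion_state: str = "fused"  # fused | unfused | unknown
    castration_age_years: float | None = None
    collection_year: int | None = None
    locality: str | None = None
    values: dict[str, float] = field(default_factory=dict)

    def n_values(self) -> int:
        return len(self.values)

    def validate(self, registry: Registry | None = None, row: object = "?") -> None:
        problems = []
        for code, v in self.values.items():
            if not (isinstance(v, (int, float)) and math.isfinite(v)) or v <= 0:
                problems.append(f"row {row}: nonpositive or non-finite {code}={v!r}")
            elif registry is not None and not registry.has(self.element, code):
                problems.append(f"row {row}: {code!r} not defined for {self.element.value}")
        if problems:
            raise ValidationError("; ".join(problems))


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n", "", "nan"):
        return False
    raise ValidationError(f"cannot parse boolean {x!r}")


def frame_to_records(
    frame: pd.DataFrame,
    registry: Registry | None = None,
    unit_policy: Mapping[str, str] | None = None,
) -> tuple[list[SpecimenRecord], list[str]]:
    """Convert a wide DataFrame to records.

    Returns ``(records, unknown_columns)``.  Columns that are neither
    metadata nor known measurement codes are reported, never silently
    dropped.  Raises :class:`ValidationError` on nonpositive measurements,
    naming the offending row and code.
    """
    unit_policy = dict(unit_policy or {})
    measurement_cols = [c for c in frame.columns if c not in META_COLUMNS]
    unknown: list[str] = []
    if registry is not None:
        all_codes = {d.code for d in registry}
        unknown = [c for c in measurement_cols if c not in all_codes]

    records: list[SpecimenRecord] = []
    for idx, row in frame.iterrows():
        element = Element(str(row["element"]).strip().lower())
        ecotype = str(row["ecotype"]).strip().lower()
        variety = str(row.get("variety", "")).strip().lower()
        if ecotype == "fennicus":
            variety = "not_applicable"
        group = GroupLabel(
            ecotype=ecotype,
            variety=variety,
            sex=str(row["sex"]).strip().lower(),
            castrated=_parse_bool(row.get("castrated", False)),
        )
        values: dict[str, float] = {}
        for code in measurement_cols:
            raw = row[code]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                continue
            v = float(raw)
            factor = _UNIT_FACTORS.get(unit_policy.get(code, "mm"))
            if factor is None:
                raise ValidationError(f"unknown unit {unit_policy[code]!r} for column {code}")
            values[code] = v * factor
        cast_age = row.get("castration_age")
        year = row.get("collection_year")
        locality = row.get("locality")
        rec = SpecimenRecord(
            individual_id=str(row["individual_id"]),
            element=element,
            side=str(row.get("side", "unknown")).strip().lower() or "unknown",
            group=group,
            fusion_state=str(row.get("fusion_state", "unknown")).strip().lower() or "unknown",
            castration_age_years=None if _isna(cast_age) else float(cast_age),
            collection_year=None if _isna(year) else int(year),
            locality=None if _isna(locality) else str(locality),
            values=values,
        )
        rec.validate(registry=None, row=idx)  # positivity always enforced
        if registry is not None:
            bad = [c for c in rec.values if c not in unknown and not registry.has(element, c)]
            if bad:
                raise ValidationError(
                    f"row {idx}: codes {bad} not defined for {element.value}"
                )
        records.append(rec)
    return records, unknown


def load_table(
    path: str | Path,
    format: str | None = None,
    unit_policy: Mapping[str, str] | None = None,
    registry: Registry | None = None,
) -> tuple[list[SpecimenRecord], list[str]]:
    """Load a wide measurement table from CSV or XLSX.

    ``unit_policy`` maps a column code to its unit in the file (``mm``,
    ``cm`` or ``m``); unlisted columns are assumed mm.  Returns
    ``(records, unknown_columns)`` with all values converted to mm and row
    order preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        frame = pd.read_csv(path)
    elif fmt in ("xlsx", "xls"):
        frame = pd.read_excel(path, sheet_name=0)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return frame_to_records(frame, registry=registry, unit_policy=unit_policy)


def records_to_frame(records: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Wide DataFrame in the canonical schema (mm, empty cell = absent)."""
    codes: list[str] = []
    seen = set()
    for r in records:
        for c in r.values:
            if c not in seen:
                seen.add(c)
                codes.append(c)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "individual_id": r.individual_id,
            "element": r.element.value,
            "side": r.side,
            "ecotype": r.group.ecotype,
            "variety": r.group.variety,
            "sex": r.group.sex,
            "castrated": r.group.castrated,
            "fusion_state": r.fusion_state,
            "castration_age": r.castration_age_years,
            "collection_year": r.collection_year,
            "locality": r.locality,
        }
        for c in codes:
            row[c] = r.values.get(c)
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + codes)


def write_table(records: Sequence[SpecimenRecord], path: str | Path, format: str | None = None) -> Path:
    """Write records as wide CSV or XLSX (mm)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    frame = records_to_frame(records)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "xlsx":
        frame.to_excel(path, index=False)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path


def _isna(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    s = str(x).strip().lower()
    return s in ("", "nan", "none")
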