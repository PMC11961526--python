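"""Sample-inclusion filters and complete-case matrix construction.

Three rules define the analytical sample:

* only osteologically mature specimens (fused epiphyses) enter the analysis,
  because castration and sex effects on bone dimensions are fixed at fusion;
* castrates are informative only if castrated before skeletal maturity,
  so castrates with castration age at or above the cutoff (default 4.5 y)
  are excluded;
* one element per individual — when both sides were measured the more
  complete side is kept (ties to the left).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SpecimenRecord
from .registry import AxisClass, Element, GroupLabel, Region, Registry

__all__ = [
    "ExclusionLog",
    "apply_inclusion_rules",
    "dedupe_sides",
    "MeasurementMatrix",
    "select_matrix",
    "SUBSET_IDS",
    "COMPLETE_REDUCED_CODES",
]

logger = logging.getLogger(__name__)

SUBSET_IDS = ("all", "proximal", "distal", "shaft", "complete_reduced")

#: Default reduced variable set for complete bones: one length plus one
#: variable from each bone region.  Overridable per element via
#: ``subset_overrides`` in :func:`select_matrix`.
COMPLETE_REDUCED_CODES: dict[Element, list[str]] = {
    Element.HUMERUS: ["GL", "Bp", "SD", "Bd"],
    Element.RADIOULNA: ["GL", "Bp", "SD", "Bd"],
    Element.METACARPUS: ["GL", "Bp", "SD", "Bd"],
    Element.FEMUR: ["GL", "Bp", "SD", "Bd"],
    Element.TIBIA: ["GL", "Bp", "SD", "Bd"],
    Element.METATARSUS: ["GL", "Bp", "SD", "Bd"],
    Element.PELVIS: ["GL", "SB", "DPS", "Dam"],
}


@dataclass
class ExclusionLog:
    """Rows dropped by a filter, with a reason each."""

    entries: list[tuple[str, str]]  # (row id, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["row_id", "reason"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.entries)


def _row_id(rec: SpecimenRecord, i: int) -> str:
    return f"{i}:{rec.individual_id}/{rec.element.value}/{rec.side}"


def apply_inclusion_rules(
    records: Sequence[SpecimenRecord],
    castration_age_cutoff_years: float = 4.5,
    allow_unknown_fusion: bool = False,
) -> tuple[list[SpecimenRecord], ExclusionLog]:
    """Apply maturity and castration-age inclusion rules.

    Unfused specimens are dropped; castrates with
    ``castration_age >= cutoff`` are dropped (strict: age just below the
    cutoff is kept).  The age rule never touches non-castrates.  Idempotent.
    """
    kept: list[SpecimenRecord] = []
    log: list[tuple[str, str]] = []
    for i, rec in enumerate(records):
        if rec.fusion_state == "unfused":
            log.append((_row_id(rec, i), "unfused"))
            continue
        if rec.fusion_state == "unknown" and not allow_unknown_fusion:
            log.append((_row_id(rec, i), "unknown_fusion"))
            continue
        if (
            rec.group.castrated
            and rec.castration_age_years is not None
            and rec.castration_age_years >= castration_age_cutoff_years
        ):
            log.append((_row_id(rec, i), "castration_age"))
            continue
        kept.append(rec)
    return kept, ExclusionLog(log)


def dedupe_sides(
    records: Sequence[SpecimenRecord],
    preference: str = "max_complete",
) -> list[SpecimenRecord]:
    """Keep at most one record per (individual, element).

    ``max_complete`` keeps the side with more recorded values; ties and the
    other preferences break deterministically to the left side.  Output
    preserves first-appearance order of the kept pairs.
    """
    if preference not in ("left_first", "right_first", "max_complete"):
        raise ValueError(f"unknown preference {preference!r}")

    side_rank = {"left": 0, "right": 1, "unknown": 2}
    if preference == "right_first":
        side_rank = {"right": 0, "left": 1, "unknown": 2}

    best: dict[tuple[str, Element], SpecimenRecord] = {}
    order: list[tuple[str, Element]] = []
    for rec in records:
        key = (rec.individual_id, rec.element)
        if key not in best:
            best[key] = rec
            order.append(key)
            continue
        cur = best[key]
        if preference == "max_complete":
            better = (rec.n_values(), -side_rank.get(rec.side, 2)) > (
                cur.n_values(),
                -side_rank.get(cur.side, 2),
            )
        else:
            better = side_rank.get(rec.side, 2) < side_rank.get(cur.side, 2)
        if better:
            best[key] = rec
    return [best[k] for k in order]


@dataclass
class MeasurementMatrix:
    """Complete-case numeric matrix for one element and variable subset."""

    element: Element
    subset_id: str
    variable_codes: list[str]
    specimen_ids: list[str]
    values: np.ndarray  # (n_specimens, n_variables), mm
    groups: list[GroupLabel]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.specimen_ids), len(self.variable_codes)):
            raise ValueError("values shape does not match ids/codes")
        if np.isnan(self.values).any():
            raise ValueError("measurement matrix must be complete-case")

    @property
    def n(self) -> int:
        return len(self.specimen_ids)

    @property
    def p(self) -> int:
        return len(self.variable_codes)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.variable_codes)
        frame.insert(0, "specimen_id", self.specimen_ids)
        frame.insert(1, "group", [g.key for g in self.groups])
        return frame


def subset_codes(
    registry: Registry,
    element: Element,
    subset_id: str,
    subset_overrides: dict[str, list[str]] | None = None,
) -> list[str]:
    """Resolve a subset id to an ordered code list for ``element``.

    Region subsets come from registry region tags; ``complete_reduced``
    defaults to a small cross-region set.  Explicit per-subset lists in
    ``subset_overrides`` take precedence (the authoritative region lists for
    a given study may differ from the registry's tags).
    """
    if subset_overrides and subset_id in subset_overrides:
        codes = [c for c in subset_overrides[subset_id]]
    elif subset_id == "all":
        codes = registry.codes(element)
    elif subset_id in ("proximal", "distal"):
        codes = registry.region_codes(element, Region(subset_id))
    elif subset_id == "shaft":
        codes = registry.region_codes(element, Region.SHAFT)
    elif subset_id == "complete_reduced":
        codes = COMPLETE_REDUCED_CODES[element]
    else:
        raise ValueError(f"unknown subset {subset_id!r}; choose from {SUBSET_IDS}")
    # registry order, validated
    order = {c: i for i, c in enumerate(registry.codes(element))}
    missing = [c for c in codes if c not in order]
    if missing:
        raise ValueError(f"codes {missing} not in registry for {element.value}")
    return sorted(codes, key=order.__getitem__)


def select_matrix(
    records: Sequence[SpecimenRecord],
    element: Element,
    subset_id: str,
    registry: Registry,
    subset_overrides: dict[str, list[str]] | None = None,
) -> tuple[MeasurementMatrix, ExclusionLog]:
    """Build the complete-case matrix for one element and variable subset.

    Specimens missing any subset variable are dropped and logged.  Raises if
    fewer than 2 variables resolve or no specimen survives.
    """
    codes = subset_codes(registry, element, subset_id, subset_overrides)
    if len(codes) < 2:
        raise ValueError(
            f"subset {subset_id!r} resolves to {len(codes)} variable(s) for "
            f"{element.value}; at least 2 required"
        )
    ids: list[str] = []
    groups: list[GroupLabel] = []
    rows: list[list[float]] = []
    log: list[tuple[str, str]] = []
    for i, rec in enumerate(records):
        if rec.element is not element:
            continue
        missing = [c for c in codes if c not in rec.values]
        if missing:
            log.append((_row_id(rec, i), f"missing:{','.join(missing)}"))
            continue
        ids.append(rec.individual_id)
        groups.append(rec.group)
        rows.append([rec.values[c] for c in codes])
    if not ids:
        raise ValueError(
            f"no complete-case specimens for {element.value} subset {subset_id!r}"
        )
    matrix = MeasurementMatrix(
        element=element,
        subset_id=subset_id,
        variable_codes=codes,
        specimen_ids=ids,
        values=np.array(rows, dtype=float),
        groups=groups,
    )
    return matrix, ExclusionLog(log)
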