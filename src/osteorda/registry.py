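"""Measurement registry and group taxonomy for reindeer long-bone osteometry.

The registry enumerates the standard osteometric measurement codes used for
Fennoscandian reindeer (Von den Driesch-style caliper measurements plus the
metapodial condyle measurements of Davis and the diaphysis dimensions used in
reindeer work).  Each code carries its skeletal element, an axis class
(length / breadth / depth / circumference / other) and a bone-region tag
(proximal / distal / shaft / whole) that drives the fragment-oriented
variable subsets.

The packaged default registry holds 99 definitions across six long bones and
the pelvis.  The exact membership is configurable: analyses accept any
registry with the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Element",
    "AxisClass",
    "Region",
    "MeasurementDefinition",
    "Registry",
    "GroupLabel",
    "CANONICAL_GROUPS",
    "SIZE_ORDER",
    "default_registry",
]


class Element(str, Enum):
    HUMERUS = "humerus"
    RADIOULNA = "radioulna"
    METACARPUS = "metacarpus"
    FEMUR = "femur"
    TIBIA = "tibia"
    METATARSUS = "metatarsus"
    PELVIS = "pelvis"


LONG_BONES: tuple[Element, ...] = (
    Element.HUMERUS,
    Element.RADIOULNA,
    Element.METACARPUS,
    Element.FEMUR,
    Element.TIBIA,
    Element.METATARSUS,
)


class AxisClass(str, Enum):
    LENGTH = "length"
    BREADTH = "breadth"
    DEPTH = "depth"
    CIRCUMFERENCE = "circumference"
    OTHER = "other"


class Region(str, Enum):
    PROXIMAL = "proximal"
    DISTAL = "distal"
    SHAFT = "shaft"
    WHOLE = "whole"


@dataclass(frozen=True)
class MeasurementDefinition:
    """One osteometric measurement code on one skeletal element.

    ``canonical_unit`` is always millimetres; readers convert on load.
    """

    code: str
    element: Element
    axis_class: AxisClass
    region: Region
    canonical_unit: str = "mm"

    def __post_init__(self) -> None:
        if self.region is Region.WHOLE and self.axis_class is not AxisClass.LENGTH:
            raise ValueError(
                f"{self.element.value}.{self.code}: region 'whole' is reserved "
                "for length-type measurements spanning the bone"
            )


# (code, axis, region) triples per element.  Length codes spanning the bone are
# region 'whole'; everything else is tied to the proximal end, distal end or
# diaphysis (shaft).
_L, _B, _D, _C, _O = (
    AxisClass.LENGTH,
    AxisClass.BREADTH,
    AxisClass.DEPTH,
    AxisClass.CIRCUMFERENCE,
    AxisClass.OTHER,
)
_P, _DI, _S, _W = Region.PROXIMAL, Region.DISTAL, Region.SHAFT, Region.WHOLE

_DEFAULT_TABLE: dict[Element, list[tuple[str, AxisClass, Region]]] = {
    Element.HUMERUS: [
        ("GL", _L, _W), ("GLl", _L, _W), ("GLC", _L, _W), ("PL", _L, _W),
        ("Bp", _B, _P), ("Dp", _D, _P),
        ("SD", _B, _S), ("SDD", _D, _S), ("CD", _C, _S),
        ("Bd", _B, _DI), ("BT", _B, _DI), ("Dd", _D, _DI),
        ("HT", _O, _DI), ("HTC", _O, _DI),
    ],
    Element.RADIOULNA: [
        ("GL", _L, _W), ("Ll", _L, _W), ("PL", _L, _W),
        ("LO", _L, _P), ("DPA", _D, _P), ("SDO", _D, _P), ("BPC", _B, _P),
        ("Bp", _B, _P), ("BFp", _B, _P), ("Dp", _D, _P),
        ("SD", _B, _S), ("SDD", _D, _S), ("CD", _C, _S),
        ("Bd", _B, _DI), ("BFd", _B, _DI), ("Dd", _D, _DI),
    ],
    Element.METACARPUS: [
        ("GL", _L, _W), ("Ll", _L, _W),
        ("Bp", _B, _P), ("BAp", _B, _P), ("Dp", _D, _P),
        ("SD", _B, _S), ("SDD", _D, _S), ("CD", _C, _S),
        ("Bd", _B, _DI), ("BFd", _B, _DI), ("Dd", _D, _DI),
        ("DVl", _D, _DI), ("DVm", _D, _DI), ("WCM", _B, _DI), ("WCL", _B, _DI),
    ],
    Element.FEMUR: [
        ("GL", _L, _W), ("GLC", _L, _W), ("PL", _L, _W),
        ("Bp", _B, _P), ("BTr", _B, _P), ("DC", _D, _P), ("Dp", _D, _P),
        ("SD", _B, _S), ("SDD", _D, _S), ("CD", _C, _S),
        ("Bd", _B, _DI), ("BFd", _B, _DI), ("Dd", _D, _DI),
    ],
    Element.TIBIA: [
        ("GL", _L, _W), ("Ll", _L, _W), ("PL", _L, _W),
        ("Bp", _B, _P), ("BFp", _B, _P), ("Dp", _D, _P),
        ("SD", _B, _S), ("SDD", _D, _S), ("CD", _C, _S),
        ("Bd", _B, _DI), ("BFd", _B, _DI), ("Dd", _D, _DI),
    ],
    Element.METATARSUS: [
        ("GL", _L, _W), ("Ll", _L, _W),
        ("Bp", _B, _P), ("BAp", _B, _P), ("Dp", _D, _P),
        ("SD", _B, _S), ("SDD", _D, _S), ("CD", _C, _S), ("BDF", _B, _S),
        ("Bd", _B, _DI), ("BFd", _B, _DI), ("Dd", _D, _DI),
        ("DVl", _D, _DI), ("DVm", _D, _DI), ("WCM", _B, _DI),
    ],
    Element.PELVIS: [
        ("GL", _L, _W), ("LS", _L, _W),
        ("LA", _L, _P), ("LAR", _L, _P), ("Dam", _D, _P),
        ("GBA", _B, _P), ("GBTc", _B, _P),
        ("SB", _B, _S), ("SBI", _B, _S), ("SH", _O, _S), ("SC", _C, _S),
        ("DPS", _D, _DI), ("GBTi", _B, _DI), ("LFo", _L, _DI),
    ],
}


class Registry:
    """An ordered collection of :class:`MeasurementDefinition`.

    Order is meaningful: measurement matrices and feature vectors follow
    registry order, so two analyses built from the same registry are
    column-compatible.
    """

    def __init__(self, definitions: Iterable[MeasurementDefinition]):
        self._defs: list[MeasurementDefinition] = list(definitions)
        self._by_element: dict[Element, dict[str, MeasurementDefinition]] = {}
        for d in self._defs:
            bucket = self._by_element.setdefault(d.element, {})
            if d.code in bucket:
                raise ValueError(f"duplicate code {d.code!r} for {d.element.value}")
            bucket[d.code] = d

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self):
        return iter(self._defs)

    def elements(self) -> list[Element]:
        return list(self._by_element)

    def codes(self, element: Element) -> list[str]:
        """Codes for ``element`` in registry order."""
        return list(self._by_element.get(element, {}))

    def get(self, element: Element, code: str) -> MeasurementDefinition:
        try:
            return self._by_element[element][code]
        except KeyError:
            raise KeyError(f"unknown measurement {code!r} for {element.value}") from None

    def has(self, element: Element, code: str) -> bool:
        return code in self._by_element.get(element, {})

    def region_codes(self, element: Element, region: Region) -> list[str]:
        return [c for c, d in self._by_element.get(element, {}).items() if d.region is region]

    def axis_codes(self, element: Element, axis: AxisClass) -> list[str]:
        return [c for c, d in self._by_element.get(element, {}).items() if d.axis_class is axis]


def default_registry() -> Registry:
    """The packaged 99-measurement registry (six long bones + pelvis)."""
    defs = [
        MeasurementDefinition(code, element, axis, region)
        for element, rows in _DEFAULT_TABLE.items()
        for code, axis, region in rows
    ]
    assert len(defs) == 99
    return Registry(defs)


@dataclass(frozen=True)
class GroupLabel:
    """Ecotype / variety / sex / castration label for one specimen.

    The sample splits into seven canonical groups: castrated male, intact
    male and female domestic tundra reindeer (tarandus); male and female
    wild mountain reindeer (tarandus); male and female wild forest reindeer
    (fennicus, for which the domestic/wild variety axis does not apply).
    """

    ecotype: str  # "tarandus" | "fennicus"
    variety: str  # "domestic" | "wild" | "not_applicable"
    sex: str      # "male" | "female"
    castrated: bool = False

    def __post_init__(self) -> None:
        if self.ecotype not in ("tarandus", "fennicus"):
            raise ValueError(f"unknown ecotype {self.ecotype!r}")
        if self.variety not in ("domestic", "wild", "not_applicable"):
            raise ValueError(f"unknown variety {self.variety!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.ecotype == "fennicus" and self.variety != "not_applicable":
            raise ValueError("fennicus has no domestic/wild variety")
        if self.ecotype == "tarandus" and self.variety == "not_applicable":
            raise ValueError("tarandus requires a domestic/wild variety")
        if self.castrated and (self.sex != "male" or self.variety != "domestic"):
            raise ValueError("castrates are domestic males")

    @property
    def key(self) -> str:
        """Short unique name, e.g. ``dom_castrate``, ``fen_female``."""
        if self.ecotype == "fennicus":
            return f"fen_{self.sex}"
        prefix = "dom" if self.variety == "domestic" else "wild"
        if self.castrated:
            return f"{prefix}_castrate"
        return f"{prefix}_{self.sex}"

    @property
    def ecovar(self) -> str:
        """The three-way ecotype/variety class: domestic, wild or fennicus."""
        if self.ecotype == "fennicus":
            return "fennicus"
        return self.variety


def _g(ecotype: str, variety: str, sex: str, castrated: bool = False) -> GroupLabel:
    return GroupLabel(ecotype=ecotype, variety=variety, sex=sex, castrated=castrated)


#: The seven canonical groups, indexed 1-7 in sample-table order.
CANONICAL_GROUPS: dict[int, GroupLabel] = {
    1: _g("tarandus", "domestic", "male", castrated=True),
    2: _g("tarandus", "domestic", "male"),
    3: _g("tarandus", "domestic", "female"),
    4: _g("tarandus", "wild", "male"),
    5: _g("tarandus", "wild", "female"),
    6: _g("fennicus", "not_applicable", "male"),
    7: _g("fennicus", "not_applicable", "female"),
}

#: Group keys from largest to smallest overall skeletal size.
SIZE_ORDER: tuple[str, ...] = (
    "fen_male",
    "dom_male",
    "dom_castrate",
    "fen_female",
    "wild_male",
    "dom_female",
    "wild_female",
)

GROUP_BY_KEY: Mapping[str, GroupLabel] = {g.key: g for g in CANONICAL_GROUPS.values()}
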