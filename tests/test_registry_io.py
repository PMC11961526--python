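"""Registry structure, table I/O, and sample-inclusion filters."""

import numpy as np
import pandas as pd
import pytest

from osteorda import (
    CANONICAL_GROUPS,
    GroupLabel,
    SpecimenRecord,
    ValidationError,
    apply_inclusion_rules,
    dedupe_sides,
    load_table,
    select_matrix,
    write_table,
)
from osteorda.registry import AxisClass, Element, Region
from osteorda.io import records_to_frame, frame_to_records


def _record(individual="A", element=Element.FEMUR, side="left", values=None,
            group=None, fusion="fused", cast_age=None):
    return SpecimenRecord(
        individual_id=individual,
        element=element,
        side=side,
        group=group or CANONICAL_GROUPS[2],
        fusion_state=fusion,
        castration_age_years=cast_age,
        values=values or {"GL": 250.0, "SD": 25.0},
    )


class TestRegistry:
    def test_packaged_registry_has_99_unique_definitions(self, registry):
        assert len(registry) == 99
        for element in registry.elements():
            codes = registry.codes(element)
            assert len(codes) == len(set(codes))

    def test_whole_region_is_reserved_for_lengths(self, registry):
        from osteorda import MeasurementDefinition

        for d in registry:
            if d.region is Region.WHOLE:
                assert d.axis_class is AxisClass.LENGTH
        with pytest.raises(ValueError):
            MeasurementDefinition("XX", Element.FEMUR, AxisClass.BREADTH, Region.WHOLE)

    def test_seven_canonical_groups_and_label_invariants(self):
        assert len(CANONICAL_GROUPS) == 7
        assert len({g.key for g in CANONICAL_GROUPS.values()}) == 7
        with pytest.raises(ValueError):
            GroupLabel("fennicus", "domestic", "male")
        with pytest.raises(ValueError):
            GroupLabel("tarandus", "domestic", "female", castrated=True)
        with pytest.raises(ValueError):
            GroupLabel("tarandus", "wild", "male", castrated=True)


class TestLoadTable:
    def test_unit_policy_converts_cm_columns_to_mm(self, tmp_path, registry):
        frame = pd.DataFrame(
            {
                "individual_id": ["a", "b", "c"],
                "element": "femur",
                "side": "left",
                "ecotype": "tarandus",
                "variety": "domestic",
                "sex": "male",
                "castrated": False,
                "fusion_state": "fused",
                "GL": [25.0, 26.0, 27.0],  # cm in the file
                "SD": [24.0, 25.0, 26.0],  # already mm
            }
        )
        path = tmp_path / "t.csv"
        frame.to_csv(path, index=False)
        records, unknown = load_table(path, unit_policy={"GL": "cm"}, registry=registry)
        assert unknown == []
        assert [r.values["GL"] for r in records] == [250.0, 260.0, 270.0]
        assert [r.values["SD"] for r in records] == [24.0, 25.0, 26.0]

    def test_nonpositive_measurement_names_the_row(self, tmp_path):
        frame = pd.DataFrame(
            {
                "individual_id": ["a", "b"],
                "element": "femur",
                "side": "left",
                "ecotype": "tarandus",
                "variety": "domestic",
                "sex": "male",
                "SD": [25.0, -1.0],
            }
        )
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="row 1.*SD"):
            load_table(path)

    def test_unknown_columns_reported_not_dropped(self, tmp_path, registry):
        frame = pd.DataFrame(
            {
                "individual_id": ["a"],
                "element": "femur",
                "side": "left",
                "ecotype": "tarandus",
                "variety": "domestic",
                "sex": "male",
                "GL": [250.0],
                "MYSTERY": [4.0],
            }
        )
        path = tmp_path / "u.csv"
        frame.to_csv(path, index=False)
        records, unknown = load_table(path, registry=registry)
        assert unknown == ["MYSTERY"]
        assert records[0].values["MYSTERY"] == 4.0

    @pytest.mark.parametrize("fmt", ["csv", "xlsx"])
    def test_round_trip_preserves_records(self, tmp_path, registry, small_assemblage, fmt):
        subset = small_assemblage[:40]
        path = write_table(subset, tmp_path / f"rt.{fmt}", format=fmt)
        reloaded, unknown = load_table(path, registry=registry)
        assert unknown == []
        assert len(reloaded) == len(subset)
        for orig, back in zip(subset, reloaded):
            assert back.individual_id == orig.individual_id
            assert back.element == orig.element
            assert back.group == orig.group
            assert set(back.values) == set(orig.values)
            for code, v in orig.values.items():
                assert back.values[code] == pytest.approx(v, rel=1e-12)


class TestInclusionRules:
    def test_castration_age_cutoff_is_strict_at_4_5_years(self):
        castrate = CANONICAL_GROUPS[1]
        young = _record("y", group=castrate, cast_age=3.0)
        late = _record("l", group=castrate, cast_age=5.0)
        boundary = _record("b", group=castrate, cast_age=4.5)
        kept, log = apply_inclusion_rules([young, late, boundary])
        assert [r.individual_id for r in kept] == ["y"]
        assert {reason for _, reason in log.entries} == {"castration_age"}

    def test_age_rule_never_touches_intact_animals(self):
        intact = _record("i", cast_age=10.0)  # age field present but not a castrate
        kept, log = apply_inclusion_rules([intact])
        assert kept == [intact] and len(log) == 0

    def test_unfused_removed_and_unknown_fusion_configurable(self):
        unfused = _record("u", fusion="unfused")
        unknown = _record("k", fusion="unknown")
        kept, log = apply_inclusion_rules([unfused, unknown])
        assert kept == []
        assert dict(log.entries).values() is not None
        kept2, _ = apply_inclusion_rules([unknown], allow_unknown_fusion=True)
        assert kept2 == [unknown]

    def test_idempotent(self, small_assemblage):
        once, _ = apply_inclusion_rules(small_assemblage)
        twice, log = apply_inclusion_rules(once)
        assert twice == once and len(log) == 0


class TestDedupeSides:
    def test_more_complete_side_wins(self):
        left = _record(side="left", values={"GL": 250.0, "SD": 25.0, "Bd": 60.0})
        right = _record(side="right", values={"GL": 251.0, "SD": 25.0})
        assert dedupe_sides([right, left]) == [left]

    def test_tie_breaks_to_left_and_singletons_kept(self):
        left = _record(side="left")
        right = _record(side="right")
        assert dedupe_sides([right, left]) == [left]
        only_right = _record("solo", element=Element.TIBIA, side="right")
        assert dedupe_sides([only_right]) == [only_right]

    def test_eight_femur_records_from_five_individuals_give_five(self):
        records = []
        for i in range(5):
            records.append(_record(f"ind{i}", side="left"))
        for i in range(3):
            records.append(_record(f"ind{i}", side="right"))
        deduped = dedupe_sides(records)
        assert len(deduped) == 5
        pairs = [(r.individual_id, r.element) for r in deduped]
        assert len(set(pairs)) == len(pairs)

    def test_no_duplicate_pairs_on_random_fixture(self, rng, small_assemblage):
        # duplicate a random half of the records onto the other side
        doubled = list(small_assemblage)
        for rec in small_assemblage:
            if rng.random() < 0.5:
                import dataclasses

                doubled.append(dataclasses.replace(rec, side="right"))
        deduped = dedupe_sides(doubled)
        pairs = [(r.individual_id, r.element) for r in deduped]
        assert len(set(pairs)) == len(pairs)


class TestSelectMatrix:
    def test_proximal_humerus_excludes_lengths_and_other_regions(self, registry, small_assemblage):
        matrix, _ = select_matrix(small_assemblage, Element.HUMERUS, "proximal", registry)
        assert set(matrix.variable_codes) == {"Bp", "Dp"}
        assert "GL" not in matrix.variable_codes

    def test_specimen_missing_subset_variable_dropped_and_logged(self, registry):
        complete = _record("c", element=Element.HUMERUS,
                           values={"Bp": 55.0, "Dp": 60.0})
        partial = _record("p", element=Element.HUMERUS, values={"Bp": 55.0})
        matrix, log = select_matrix([complete, partial], Element.HUMERUS, "proximal", registry)
        assert matrix.specimen_ids == ["c"]
        assert len(log) == 1 and "Dp" in log.entries[0][1]

    def test_shaft_subset_counts(self, registry):
        shaft_values = {"SD": 25.0, "SDD": 22.0, "CD": 80.0}
        records = []
        for i in range(20):
            vals = dict(shaft_values)
            if i < 4:
                vals.pop("CD")  # 4 specimens missing one shaft code
            records.append(_record(f"s{i}", values=vals))
        matrix, log = select_matrix(records, Element.FEMUR, "shaft", registry)
        assert matrix.n == 16 and len(log) == 4

    def test_complete_case_and_registry_order_for_all_subsets(self, registry, small_assemblage):
        order = {c: i for i, c in enumerate(registry.codes(Element.TIBIA))}
        for subset in ("all", "proximal", "distal", "shaft", "complete_reduced"):
            matrix, _ = select_matrix(small_assemblage, Element.TIBIA, subset, registry)
            assert not np.isnan(matrix.values).any()
            ranks = [order[c] for c in matrix.variable_codes]
            assert ranks == sorted(ranks)

    def test_errors_on_empty_result(self, registry):
        with pytest.raises(ValueError, match="no complete-case"):
            select_matrix([], Element.FEMUR, "all", registry)


def test_frame_conversion_round_trip(small_assemblage, registry):
    frame = records_to_frame(small_assemblage[:30])
    back, unknown = frame_to_records(frame, registry=registry)
    assert unknown == []
    assert [r.individual_id for r in back] == [r.individual_id for r in small_assemblage[:30]]
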