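"""Floor-plan geometry: schema validation, mirroring, angles, lint."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orsim import fixtures
from orsim.geometry import (
    AgentPose,
    LayoutError,
    layout_to_dict,
    lint_layout,
    load_layout,
    mirror_layout,
    relative_angle,
)
from orsim.trm import unsigned_angle


def _dicts_close(a, b, tol=1e-9):
    if isinstance(a, dict):
        return set(a) == set(b) and all(_dicts_close(a[k], b[k], tol) for k in a)
    if isinstance(a, (list, tuple)):
        return len(a) == len(b) and all(_dicts_close(x, y, tol) for x, y in zip(a, b))
    if isinstance(a, float) or isinstance(b, float):
        return abs(float(a) - float(b)) <= tol
    return a == b


class TestLoadLayout:
    def test_minimal_document_roundtrip(self, minimal_doc):
        layout = load_layout(minimal_doc)
        assert len(layout.instrument_tables) == 3
        assert _dicts_close(layout_to_dict(load_layout(layout_to_dict(layout))), layout_to_dict(layout))

    def test_two_scrub_nurses_rejected(self, minimal_doc):
        minimal_doc["agents"].append({"role": "SN", "position": [1.0, 1.0], "facing": [1, 0]})
        with pytest.raises(LayoutError, match="SN"):
            load_layout(minimal_doc)

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda d: d["room"].update(width=-1), "width"),
            (lambda d: d["furniture"][1].update(table_angle=400), "table_angle"),
            (lambda d: d["furniture"][1].update(footprint=[0.6, 0]), "footprint"),
            (lambda d: d["destinations"].update(WP1=[9.0, 0.6]), "WP1"),
            (lambda d: d["agents"][0].update(facing=[0, 0]), "facing"),
            (lambda d: d.pop("procedure"), "procedure"),
        ],
    )
    def test_validation_errors_name_offending_field(self, minimal_doc, mutate, match):
        mutate(minimal_doc)
        with pytest.raises(LayoutError, match=match):
            load_layout(minimal_doc)

    def test_overlapping_furniture_rejected(self, minimal_doc):
        minimal_doc["furniture"][2]["center"] = minimal_doc["furniture"][1]["center"]
        with pytest.raises(LayoutError, match="overlap"):
            load_layout(minimal_doc)

    def test_tka1_fixture_has_canonical_table_angles(self, tka1):
        assert len(tka1.instrument_tables) == 4
        angles = sorted(unsigned_angle(t.table_angle) for t in tka1.instrument_tables)
        assert angles == [0.0, 45.0, 90.0, 180.0]

    def test_every_bundled_fixture_validates(self, any_setup_id):
        for side in fixtures.SIDES:
            layout = fixtures.load_fixture(any_setup_id, side)
            layout.validate()
            assert layout.side == side


class TestMirror:
    def test_involution(self, any_setup_id):
        layout = fixtures.load_fixture(any_setup_id, "left")
        back = mirror_layout(mirror_layout(layout))
        assert _dicts_close(layout_to_dict(back), layout_to_dict(layout))

    def test_reflection_identity(self, tka1):
        y0 = tka1.mirror_axis_y
        mirrored = mirror_layout(tka1)
        for a, b in zip(tka1.agents, mirrored.agents):
            assert b.position[0] == pytest.approx(a.position[0])
            assert b.position[1] == pytest.approx(2 * y0 - a.position[1])

    def test_left_fixture_mirrors_to_right_fixture(self, any_setup_id):
        left = fixtures.load_fixture(any_setup_id, "left")
        right = fixtures.load_fixture(any_setup_id, "right")
        assert _dicts_close(layout_to_dict(mirror_layout(left)), layout_to_dict(right))

    def test_room_fixed_destinations_do_not_move(self, tha3):
        mirrored = mirror_layout(tha3)
        assert mirrored.plan.destinations == tha3.plan.destinations


class TestRelativeAngle:
    @pytest.mark.parametrize(
        "facing, target, expected",
        [((1, 0), (3.0, 1.0), 0.0), ((1, 0), (-1.0, 1.0), 180.0), ((1, 0), (2.0, 2.0), 45.0)],
    )
    def test_reference_directions(self, facing, target, expected):
        obs = AgentPose.create("SN", (1.0, 1.0), facing)
        assert relative_angle(obs, target) == pytest.approx(expected)

    def test_coincident_target_rejected(self):
        obs = AgentPose.create("SN", (1.0, 1.0), (1, 0))
        with pytest.raises(ValueError):
            relative_angle(obs, (1.0, 1.0))

    @given(
        theta=st.floats(0, 2 * math.pi),
        rot=st.floats(0, 2 * math.pi),
        r=st.floats(0.1, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_invariant_under_rigid_rotation(self, theta, rot, r):
        obs = AgentPose.create("SN", (0.0, 0.0), (1.0, 0.0))
        target = (r * math.cos(theta), r * math.sin(theta))
        base = relative_angle(obs, target)
        obs_rot = AgentPose.create("SN", (0.0, 0.0), (math.cos(rot), math.sin(rot)))
        target_rot = (
            r * math.cos(theta + rot),
            r * math.sin(theta + rot),
        )
        assert relative_angle(obs_rot, target_rot) == pytest.approx(base, abs=1e-6)


class TestLint:
    def test_compliant_layout_all_pass(self, compliant_layout):
        findings = lint_layout(compliant_layout)
        assert {f.requirement_id for f in findings} == {2, 6, 7, 8}
        assert all(f.status == "pass" for f in findings), [f.to_dict() for f in findings]

    def test_table_behind_surgeon_warns(self, compliant_layout):
        doc = layout_to_dict(compliant_layout)
        # move a table squarely behind the surgeon (he faces +y)
        doc["furniture"][3]["center"] = [3.0, 1.2]
        doc["furniture"][3]["table_angle"] = 180
        findings = lint_layout(load_layout(doc))
        req6 = next(f for f in findings if f.requirement_id == 6)
        assert req6.status == "warn"
        assert req6.measured_value > req6.threshold

    def test_tka1_right_warns_about_paths_near_tables(self):
        layout = fixtures.load_fixture("TKA1", "right")
        req7 = next(f for f in lint_layout(layout) if f.requirement_id == 7)
        assert req7.status == "warn"
        assert req7.measured_value < req7.threshold
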