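"""Handover-time simulation: decomposition, linearity, calibration."""

import numpy as np
import pytest

from orsim import fixtures
from orsim.geometry import load_layout, mirror_layout
from orsim.handover import (
    MotionParams,
    calibrate,
    compare_sim_measured,
    iht,
    total_handover_time,
)

# Published sim-vs-measured handover times (seconds) for the redesigned setups.
TABLE2_TKA3 = {
    "sim": {"table1": 0.70, "table2": 1.24, "table3": 1.66},
    "measured": {"table1": 0.65, "table2": 1.14, "table3": 1.46},
}
TABLE2_THA3 = {
    "sim": {"table1": 0.79, "table2": 1.42, "table3": 1.20},
    "measured": {"table1": 0.72, "table2": 1.44, "table3": 1.86},
}


def right_angle_layout():
    """SN and SU half a meter apart, every rotation angle 90 degrees."""
    return load_layout(
        {
            "id": "RIGHTANGLE",
            "procedure": "TKA",
            "side": "left",
            "room": {"width": 6.0, "height": 6.0},
            "destinations": {},
            "furniture": [
                {"id": "or_table", "kind": "or_table", "center": [3.0, 4.5], "footprint": [2.0, 0.9]},
                {"id": "table1", "kind": "instrument_table", "center": [1.0, 2.0], "footprint": [0.6, 0.4], "table_angle": 90},
                {"id": "table2", "kind": "instrument_table", "center": [2.0, 2.0], "footprint": [0.6, 0.4], "table_angle": 45},
                {"id": "table3", "kind": "instrument_table", "center": [4.0, 2.0], "footprint": [0.6, 0.4], "table_angle": 0},
            ],
            "agents": [
                {"role": "SN", "position": [1.0, 1.0], "facing": [0.0, 1.0]},
                {"role": "SU", "position": [1.5, 1.0], "facing": [0.0, 1.0]},
            ],
        }
    )


class TestIht:
    def test_decomposition_of_the_right_angle_case(self):
        # (90+90+90)/180 + 0.5/1.0 + 0.3 + 0.2  =  2.5 s
        layout = right_angle_layout()
        params = MotionParams(rotation_speed=180, arm_speed=1.0, grasp_time=0.3, transfer_time=0.2)
        assert iht(layout, "table1", params) == pytest.approx(2.5)

    def test_rotation_free_handover_costs_grasp_plus_transfer_plus_pass(self):
        layout = right_angle_layout()
        params = MotionParams(rotation_speed=1e12, arm_speed=1.0, grasp_time=0.3, transfer_time=0.2)
        # angles contribute ~0; only the 0.5 m pass and the handling times remain
        assert iht(layout, "table1", params) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_table_rejected(self, tka1):
        with pytest.raises(KeyError, match="no instrument table"):
            iht(tka1, "table99")

    def test_monotone_in_table_angle_within_every_fixture(self, any_setup_id):
        from orsim.trm import unsigned_angle

        layout = fixtures.load_fixture(any_setup_id)
        pairs = sorted(
            (unsigned_angle(t.table_angle), iht(layout, t.id)) for t in layout.instrument_tables
        )
        values = [v for _, v in pairs]
        assert values == sorted(values)

    def test_mirror_invariant(self, any_setup_id):
        layout = fixtures.load_fixture(any_setup_id)
        mirrored = mirror_layout(layout)
        for t in layout.instrument_tables:
            assert iht(mirrored, t.id) == pytest.approx(iht(layout, t.id), abs=1e-9)

    def test_strictly_increasing_in_grasp_time(self, tka1):
        lo = iht(tka1, "table1", MotionParams(grasp_time=0.2))
        hi = iht(tka1, "table1", MotionParams(grasp_time=0.4))
        assert hi - lo == pytest.approx(0.2)


class TestTotalHandoverTime:
    def test_zero_counts_zero_total(self, tka1):
        result = total_handover_time(tka1, {})
        assert result.total_handover_time == 0
        assert result.event_log == ()

    def test_linear_in_counts(self, tka1):
        counts = {"table1": 3, "table2": 1}
        single = total_handover_time(tka1, counts).total_handover_time
        double = total_handover_time(tka1, {k: 2 * v for k, v in counts.items()}).total_handover_time
        assert double == pytest.approx(2 * single)

    def test_total_matches_count_iht_dot_product(self, tka1):
        counts = {"table1": 108.3, "table2": 5.7, "table3": 5.0, "table4": 2.7}
        result = total_handover_time(tka1, counts)
        expected = float(
            np.dot(list(counts.values()), [result.per_table_iht[k] for k in counts])
        )
        assert result.total_handover_time == pytest.approx(expected, abs=1e-9)

    def test_event_log_is_sequential_and_sums_to_total(self, tka1):
        result = total_handover_time(tka1, {"table1": 2.5, "table2": 1})
        times = [e.time for e in result.event_log]
        assert times == sorted(times)
        assert sum(e.duration for e in result.event_log) == pytest.approx(
            result.total_handover_time
        )

    def test_unknown_table_count_rejected(self, tka1):
        with pytest.raises(KeyError, match="unknown table"):
            total_handover_time(tka1, {"nope": 1})


class TestCalibrate:
    def test_recovers_its_own_forward_model(self, tha3):
        truth = MotionParams(rotation_speed=120, arm_speed=0.8, grasp_time=0.4, transfer_time=0.3)
        measured = {t.id: iht(tha3, t.id, truth) for t in tha3.instrument_tables}
        result = calibrate(MotionParams(), tha3, measured)
        for tid, value in measured.items():
            assert iht(tha3, tid, result.params) == pytest.approx(value, abs=1e-6)
        assert result.cost <= result.initial_cost

    def test_single_table_rejected(self, tha3):
        with pytest.raises(ValueError, match="at least two"):
            calibrate(MotionParams(), tha3, {"table1": 0.72})

    def test_identical_geometry_rejected(self):
        layout = right_angle_layout()
        # tables 1 and a twin of it share the same angle: no rotation signal
        from dataclasses import replace

        twin = replace(layout.furniture_by_id("table2"), table_angle=90.0)
        degenerate = replace(
            layout, furniture=tuple(twin if f.id == "table2" else f for f in layout.furniture)
        )
        with pytest.raises(ValueError, match="degenerate"):
            calibrate(MotionParams(), degenerate, {"table1": 1.0, "table2": 1.2})

    def test_fit_to_clinical_measurements_improves_on_defaults(self, tha3):
        result = calibrate(MotionParams(), tha3, TABLE2_THA3["measured"])
        assert result.cost <= result.initial_cost


class TestCompareSimMeasured:
    def test_published_deltas_for_both_redesigns(self):
        assert compare_sim_measured(TABLE2_TKA3["sim"], TABLE2_TKA3["measured"]) == {
            "table1": 0.05,
            "table2": 0.10,
            "table3": 0.20,
        }
        assert compare_sim_measured(TABLE2_THA3["sim"], TABLE2_THA3["measured"]) == {
            "table1": 0.07,
            "table2": 0.02,
            "table3": 0.66,
        }

    def test_identical_inputs_give_zero(self):
        assert compare_sim_measured({"t": 1.2}, {"t": 1.2}) == {"t": 0.0}

    def test_key_mismatch_rejected(self):
        with pytest.raises(KeyError, match="table ids differ"):
            compare_sim_measured({"a": 1.0}, {"b": 1.0})
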