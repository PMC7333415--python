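import pytest

from orsim import fixtures
from orsim.geometry import load_layout


def minimal_layout_doc() -> dict:
    """Smallest schema-valid layout: one SN, one SU, OR table, 3 tables."""
    return {
        "id": "MINI",
        "procedure": "TKA",
        "side": "left",
        "room": {"width": 6.0, "height": 6.0},
        "obstacles": [],
        "destinations": {"WP1": [0.6, 0.6]},
        "furniture": [
            {"id": "or_table", "kind": "or_table", "center": [3.0, 3.0], "footprint": [2.0, 0.9]},
            {"id": "table1", "kind": "instrument_table", "center": [1.5, 4.0], "footprint": [0.6, 0.4], "table_angle": 0},
            {"id": "table2", "kind": "instrument_table", "center": [1.5, 4.8], "footprint": [0.6, 0.4], "table_angle": 45},
            {"id": "table3", "kind": "instrument_table", "center": [1.5, 2.0], "footprint": [0.6, 0.4], "table_angle": 90},
        ],
        "agents": [
            {"role": "SN", "position": [2.2, 4.4], "facing": [1.0, 0.0]},
            {"role": "SU", "position": [3.0, 3.8], "facing": [0.0, -1.0]},
        ],
    }


def compliant_layout_doc() -> dict:
    """A layout authored to satisfy every lint requirement."""
    return {
        "id": "GOOD",
        "procedure": "TKA",
        "side": "left",
        "room": {"width": 6.5, "height": 6.5},
        "obstacles": [],
        "destinations": {"WP1": [0.6, 0.6], "sterile_room_door": [6.25, 0.6]},
        "furniture": [
            {"id": "or_table", "kind": "or_table", "center": [3.25, 3.4], "footprint": [2.0, 0.9]},
            {"id": "table1", "kind": "instrument_table", "center": [2.35, 2.1], "footprint": [0.5, 0.35], "table_angle": 90},
            {"id": "table2", "kind": "instrument_table", "center": [3.65, 2.1], "footprint": [0.5, 0.35], "table_angle": 270},
            {"id": "table3", "kind": "instrument_table", "center": [3.0, 2.7], "footprint": [0.5, 0.35], "table_angle": 0},
        ],
        "agents": [
            {"role": "SN", "position": [2.9, 2.35], "facing": [0.0, 1.0]},
            {"role": "SU", "position": [3.0, 2.05], "facing": [0.0, 1.0]},
        ],
    }


@pytest.fixture
def minimal_doc():
    return minimal_layout_doc()


@pytest.fixture
def compliant_layout():
    return load_layout(compliant_layout_doc())


@pytest.fixture(scope="session")
def tka1():
    return fixtures.load_fixture("TKA1", "left")


@pytest.fixture(scope="session")
def tka3():
    return fixtures.load_fixture("TKA3", "left")


@pytest.fixture(scope="session")
def tha3():
    return fixtures.load_fixture("THA3", "left")


@pytest.fixture(scope="session", params=fixtures.SETUP_IDS)
def any_setup_id(request):
    return request.param
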