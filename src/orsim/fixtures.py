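"""Bundled OR-setup fixtures: seven arthroplasty setups, both sides.

The study's floor plans were published only as schematic top views, so
these fixtures are to-scale reconstructions in a 6.5 m x 6.5 m room:
furniture positions are authored so that every qualitative statement
about the setups holds under computation (table-angle labels, blocked
workplaces, the right-side THA-3 detour), while absolute distances are
reconstruction-dependent.  Left-side fixtures are the authored originals;
right-side files are their exact mirrors.
"""

from __future__ import annotations

from importlib import resources

from .geometry import LayoutSetup, load_layout

__all__ = ["SETUP_IDS", "TKA_SETUPS", "THA_SETUPS", "SIDES", "fixture_text", "load_fixture", "all_fixtures"]

TKA_SETUPS = ("TKA1", "TKA2", "TKA3", "TKA4")
THA_SETUPS = ("THA1", "THA2", "THA3")
SETUP_IDS = TKA_SETUPS + THA_SETUPS
SIDES = ("left", "right")


def fixture_text(setup_id: str, side: str = "left") -> str:
    if setup_id not in SETUP_IDS:
        raise KeyError(f"unknown setup id {setup_id!r}; expected one of {SETUP_IDS}")
    if side not in SIDES:
        raise KeyError(f"unknown side {side!r}; expected 'left' or 'right'")
    name = f"{setup_id}_{side}.yaml"
    return resources.files("orsim").joinpath("data", name).read_text()


def load_fixture(setup_id: str, side: str = "left") -> LayoutSetup:
    """Load one bundled setup fixture as a validated layout."""
    return load_layout(fixture_text(setup_id, side))


def all_fixtures(procedure: str | None = None) -> list[LayoutSetup]:
    """All bundled fixtures (optionally one procedure), both sides."""
    ids = SETUP_IDS if procedure is None else tuple(s for s in SETUP_IDS if s.startswith(procedure))
    if not ids:
        raise ValueError(f"no fixtures for procedure {procedure!r}")
    return [load_fixture(sid, side) for sid in ids for side in SIDES]
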