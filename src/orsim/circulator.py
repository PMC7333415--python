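"""Circulator travel: round trips from the working place to supply points.

The circulator fetches materials during surgery: trips to the supply
racks (R1, R2), the supply stocks (ST1 outside the OR, ST2 in the sterile
room), the anesthesia room (AR) and to the scrub nurse (SN).  Travel is
modelled as independent round trips from a fixed origin (WP1 by default),
with path lengths from the obstacle-aware grid planner; per-surgery trip
counts are multiplied in, so the total is linear in the counts.

ST1 lies beyond the sterile-room door and its corridor is not part of the
floor plan; a fixed corridor allowance is added per leg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from . import navigation
from .geometry import LayoutSetup, Point

__all__ = ["TripProfile", "TravelResult", "total_travel_distance", "ST1_CORRIDOR_M"]

ST1_CORRIDOR_M = 4.0  # one-way corridor allowance beyond the door, meters


@dataclass(frozen=True)
class TripProfile:
    """Per-surgery trip counts by destination name (may be means)."""

    counts: Mapping[str, float]
    origin: str = "WP1"

    def validate(self) -> None:
        for name, count in self.counts.items():
            if count < 0:
                raise ValueError(f"TripProfile.counts[{name!r}]: negative trip count")


@dataclass(frozen=True)
class TravelResult:
    per_destination: dict[str, float]  # meters contributed by each destination
    total_distance: float
    unreachable: tuple[str, ...] = ()


def _resolve(layout: LayoutSetup, name: str) -> Point:
    if name == "SN":
        return layout.agent("SN").position
    try:
        return layout.plan.destinations[name]
    except KeyError:
        raise KeyError(f"destination {name!r} not defined in layout {layout.id!r}") from None


def total_travel_distance(
    layout: LayoutSetup,
    trips: TripProfile,
    cell_size: float = navigation.DEFAULT_CELL_SIZE,
    agent_radius: float = navigation.DEFAULT_AGENT_RADIUS,
    st1_corridor: float = ST1_CORRIDOR_M,
    on_unreachable: str = "error",
) -> TravelResult:
    """Total distance traveled by the circulator during one surgery.

    Each destination contributes ``count * 2 * path_length`` (round trips).
    Goals whose exact point is crowded shut by furniture inflation are
    approached to the nearest free spot.  Destinations with no path at all
    raise by default (``on_unreachable="error"``); with ``"skip"`` they are
    listed in ``unreachable`` and contribute no distance.
    """
    trips.validate()
    if on_unreachable not in ("error", "skip"):
        raise ValueError(f"on_unreachable must be 'error' or 'skip', got {on_unreachable!r}")
    grid = navigation.rasterize(layout, cell_size=cell_size, agent_radius=agent_radius)
    origin = navigation.approach_point(grid, _resolve(layout, trips.origin))
    dist = navigation.distance_map(grid, origin)
    per_destination: dict[str, float] = {}
    unreachable: list[str] = []
    for name in sorted(trips.counts):
        count = float(trips.counts[name])
        try:
            length = navigation.reachable_distance(grid, dist, _resolve(layout, name))
        except navigation.UnreachableError as exc:
            if on_unreachable == "error":
                raise navigation.UnreachableError(
                    f"circulator destination {name!r} unreachable in layout "
                    f"{layout.id!r} ({layout.side}): {exc}"
                ) from exc
            unreachable.append(name)
            per_destination[name] = 0.0
            continue
        leg = length + (st1_corridor if name == "ST1" else 0.0)
        per_destination[name] = count * 2.0 * leg
    return TravelResult(
        per_destination=per_destination,
        total_distance=float(sum(per_destination.values())),
        unreachable=tuple(unreachable),
    )
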