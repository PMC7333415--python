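"""Operating-room floor-plan geometry: layouts, furniture, staff poses.

The room is modelled in 2D (top view), in meters, with the origin at the
south-west corner.  An OR layout couples a room-fixed :class:`FloorPlan`
(walls, racks, anesthesia equipment, named destinations such as supply
racks R1/R2 or the circulator working places WP1/WP2) with the
procedure-specific furniture (the OR table and 3-4 instrument tables) and
the poses of the surgical team (scrub nurse SN, surgeon SU, assistants,
anesthesiologist, circulator).

Left-side and right-side variants of the same setup are exact mirror
images across the long axis of the OR table; the room itself (and hence
every destination the circulator walks to) stays fixed under mirroring,
which is what makes left/right travel distances differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon, box

__all__ = [
    "LayoutError",
    "FloorPlan",
    "Obstacle",
    "Furniture",
    "AgentPose",
    "LayoutSetup",
    "Finding",
    "load_layout",
    "save_layout",
    "mirror_layout",
    "relative_angle",
    "lint_layout",
    "REACH_THRESHOLD_M",
    "CLEARANCE_MARGIN_M",
    "PROXIMITY_RADIUS_M",
    "BEHIND_ANGLE_DEG",
]

Point = tuple[float, float]

AGENT_ROLES = ("SU", "SN", "A1", "A2", "AN", "CIRC")
FURNITURE_KINDS = ("or_table", "instrument_table", "equipment")

# Lint thresholds (Table-1-style requirements, machine-checkable subset).
REACH_THRESHOLD_M = 1.0     # req 2: instrument tables within reach of the surgeon
CLEARANCE_MARGIN_M = 1.0    # req 7: circulator paths keep clear of instrument tables
PROXIMITY_RADIUS_M = 2.5    # req 8: instrument tables close to the OR table
BEHIND_ANGLE_DEG = 90.0     # req 6: tables not behind the surgeon (+ tolerance)
BEHIND_TOLERANCE_DEG = 5.0


class LayoutError(ValueError):
    """A layout document violates the schema or a geometric invariant."""


def _as_point(value, *, field_name: str) -> Point:
    try:
        x, y = float(value[0]), float(value[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise LayoutError(f"{field_name}: expected a 2D point, got {value!r}") from exc
    return (x, y)


@dataclass(frozen=True)
class Obstacle:
    """A solid room-fixed region (wall section, rack, anesthesia equipment)."""

    id: str
    polygon: Polygon

    @classmethod
    def from_rect(cls, id: str, xmin: float, ymin: float, xmax: float, ymax: float) -> "Obstacle":
        return cls(id=id, polygon=box(xmin, ymin, xmax, ymax))


@dataclass(frozen=True)
class FloorPlan:
    """Room extent, solid obstacles and the named circulator destinations."""

    width: float
    height: float
    obstacles: tuple[Obstacle, ...] = ()
    destinations: Mapping[str, Point] = field(default_factory=dict)

    def validate(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise LayoutError(f"room: width/height must be positive, got {self.width} x {self.height}")
        seen = set()
        for obs in self.obstacles:
            if obs.id in seen:
                raise LayoutError(f"obstacles: duplicate obstacle id {obs.id!r}")
            seen.add(obs.id)
        for name, pt in self.destinations.items():
            if not self.contains(pt):
                raise LayoutError(f"destinations.{name}: point {pt} outside the room")
            for obs in self.obstacles:
                if obs.polygon.contains(_ShapelyPoint(pt)):
                    raise LayoutError(f"destinations.{name}: point {pt} inside obstacle {obs.id!r}")

    def contains(self, pt: Point) -> bool:
        return 0.0 <= pt[0] <= self.width and 0.0 <= pt[1] <= self.height


@dataclass(frozen=True)
class Furniture:
    """A piece of furniture with an axis-aligned rectangular footprint.

    ``table_angle`` (instrument tables only) is the angular position of the
    table relative to the scrub nurse's neutral facing direction, clockwise
    positive, in degrees -- the "0deg / 45deg / 90deg / 180deg table" naming
    used on the ward.
    """

    id: str
    kind: str
    center: Point
    footprint: tuple[float, float]  # (x extent, y extent) in meters
    table_angle: float | None = None

    def validate(self) -> None:
        if self.kind not in FURNITURE_KINDS:
            raise LayoutError(f"furniture.{self.id}.kind: unknown kind {self.kind!r}")
        w, h = self.footprint
        if not (w > 0 and h > 0):
            raise LayoutError(f"furniture.{self.id}.footprint: must have positive area, got {self.footprint}")
        if self.kind == "instrument_table":
            if self.table_angle is None:
                raise LayoutError(f"furniture.{self.id}.table_angle: required for instrument tables")
            if not (0.0 <= self.table_angle < 360.0):
                raise LayoutError(
                    f"furniture.{self.id}.table_angle: must lie in [0, 360), got {self.table_angle}"
                )

    @property
    def polygon(self) -> Polygon:
        cx, cy = self.center
        w, h = self.footprint
        return box(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


@dataclass(frozen=True)
class AgentPose:
    """Position and facing direction of one member of the surgical team."""

    role: str
    position: Point
    facing: Point

    def validate(self, plan: FloorPlan) -> None:
        if self.role not in AGENT_ROLES:
            raise LayoutError(f"agents.{self.role}: unknown role (expected one of {AGENT_ROLES})")
        if not plan.contains(self.position):
            raise LayoutError(f"agents.{self.role}.position: {self.position} outside the room")
        for obs in plan.obstacles:
            if obs.polygon.contains(_ShapelyPoint(self.position)):
                raise LayoutError(f"agents.{self.role}.position: inside obstacle {obs.id!r}")
        norm = math.hypot(*self.facing)
        if abs(norm - 1.0) > 1e-9:
            raise LayoutError(f"agents.{self.role}.facing: not a unit vector (norm {norm:.12f})")

    @classmethod
    def create(cls, role: str, position: Point, facing: Point) -> "AgentPose":
        """Build a pose, normalising ``facing`` (must be non-zero)."""
        norm = math.hypot(*facing)
        if norm < 1e-12:
            raise LayoutError(f"agents.{role}.facing: zero-length direction")
        return cls(role=role, position=position, facing=(facing[0] / norm, facing[1] / norm))


@dataclass(frozen=True)
class LayoutSetup:
    """One named OR configuration: room, furniture and staff poses."""

    id: str
    procedure: str
    side: str
    plan: FloorPlan
    furniture: tuple[Furniture, ...]
    agents: tuple[AgentPose, ...]

    def validate(self) -> None:
        if self.procedure not in ("THA", "TKA"):
            raise LayoutError(f"procedure: must be THA or TKA, got {self.procedure!r}")
        if self.side not in ("left", "right"):
            raise LayoutError(f"side: must be left or right, got {self.side!r}")
        self.plan.validate()
        ids = set()
        for f in self.furniture:
            f.validate()
            if f.id in ids:
                raise LayoutError(f"furniture: duplicate id {f.id!r}")
            ids.add(f.id)
        or_tables = [f for f in self.furniture if f.kind == "or_table"]
        if len(or_tables) != 1:
            raise LayoutError(f"furniture: expected exactly one or_table, found {len(or_tables)}")
        n_tables = len(self.instrument_tables)
        if n_tables not in (3, 4):
            raise LayoutError(f"furniture: instrument-table count must be 3 or 4, found {n_tables}")
        items = list(self.furniture)
        for i, a in enumerate(items):
            for b in items[i + 1:]:
                inter = a.polygon.intersection(b.polygon)
                if inter.area > 1e-9:
                    raise LayoutError(
                        f"furniture: footprints of {a.id!r} and {b.id!r} overlap "
                        f"(area {inter.area:.4f} m^2)"
                    )
        for role in ("SN", "SU"):
            n = sum(1 for a in self.agents if a.role == role)
            if n != 1:
                raise LayoutError(f"agents: expected exactly one {role}, found {n}")
        for a in self.agents:
            a.validate(self.plan)

    # -- convenience accessors -------------------------------------------------

    @property
    def or_table(self) -> Furniture:
        return next(f for f in self.furniture if f.kind == "or_table")

    @property
    def instrument_tables(self) -> list[Furniture]:
        return [f for f in self.furniture if f.kind == "instrument_table"]

    def agent(self, role: str) -> AgentPose:
        for a in self.agents:
            if a.role == role:
                return a
        raise LayoutError(f"agents: no agent with role {role!r}")

    def furniture_by_id(self, table_id: str) -> Furniture:
        for f in self.furniture:
            if f.id == table_id:
                return f
        raise LayoutError(f"furniture: no furniture with id {table_id!r}")

    @property
    def mirror_axis_y(self) -> float:
        """y coordinate of the OR-table long axis (the mirror line)."""
        return self.or_table.center[1]


# ---------------------------------------------------------------------------
# I/O


def _layout_from_dict(doc: Mapping) -> LayoutSetup:
    for key in ("id", "procedure", "side", "room", "furniture", "agents"):
        if key not in doc:
            raise LayoutError(f"{key}: missing required top-level key")
    room = doc["room"]
    obstacles = []
    for entry in doc.get("obstacles", []) or []:
        oid = entry.get("id")
        if oid is None:
            raise LayoutError("obstacles: every obstacle needs an 'id'")
        if "rect" in entry:
            xmin, ymin, xmax, ymax = (float(v) for v in entry["rect"])
            if not (xmax > xmin and ymax > ymin):
                raise LayoutError(f"obstacles.{oid}.rect: degenerate rectangle {entry['rect']}")
            obstacles.append(Obstacle.from_rect(oid, xmin, ymin, xmax, ymax))
        elif "polygon" in entry:
            pts = [_as_point(p, field_name=f"obstacles.{oid}.polygon") for p in entry["polygon"]]
            poly = Polygon(pts)
            if poly.area <= 0:
                raise LayoutError(f"obstacles.{oid}.polygon: degenerate polygon")
            obstacles.append(Obstacle(id=oid, polygon=poly))
        else:
            raise LayoutError(f"obstacles.{oid}: needs either 'rect' or 'polygon'")
    destinations = {
        str(name): _as_point(pt, field_name=f"destinations.{name}")
        for name, pt in (doc.get("destinations", {}) or {}).items()
    }
    plan = FloorPlan(
        width=float(room["width"]),
        height=float(room["height"]),
        obstacles=tuple(obstacles),
        destinations=destinations,
    )
    furniture = []
    for entry in doc["furniture"]:
        fid = entry.get("id")
        if fid is None:
            raise LayoutError("furniture: every piece needs an 'id'")
        furniture.append(
            Furniture(
                id=str(fid),
                kind=str(entry.get("kind", "")),
                center=_as_point(entry["center"], field_name=f"furniture.{fid}.center"),
                footprint=_as_point(entry["footprint"], field_name=f"furniture.{fid}.footprint"),
                table_angle=(None if entry.get("table_angle") is None else float(entry["table_angle"])),
            )
        )
    agents = []
    for entry in doc["agents"]:
        role = str(entry.get("role", ""))
        agents.append(
            AgentPose.create(
                role=role,
                position=_as_point(entry["position"], field_name=f"agents.{role}.position"),
                facing=_as_point(entry["facing"], field_name=f"agents.{role}.facing"),
            )
        )
    layout = LayoutSetup(
        id=str(doc["id"]),
        procedure=str(doc["procedure"]),
        side=str(doc["side"]),
        plan=plan,
        furniture=tuple(furniture),
        agents=tuple(agents),
    )
    layout.validate()
    return layout


def load_layout(source) -> LayoutSetup:
    """Load and validate a layout from a YAML/JSON file path, string or dict."""
    if isinstance(source, Mapping):
        return _layout_from_dict(source)
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))):
        text = Path(source).read_text()
    else:
        text = str(source)
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise LayoutError("document: expected a mapping at top level")
    return _layout_from_dict(doc)


def layout_to_dict(layout: LayoutSetup) -> dict:
    """Serialise a layout back to the schema dict (round-trips with load)."""

    def _rect(obs: Obstacle):
        xmin, ymin, xmax, ymax = obs.polygon.bounds
        if abs(obs.polygon.area - (xmax - xmin) * (ymax - ymin)) < 1e-12:
            return {"id": obs.id, "rect": [xmin, ymin, xmax, ymax]}
        return {"id": obs.id, "polygon": [list(p) for p in obs.polygon.exterior.coords[:-1]]}

    return {
        "id": layout.id,
        "procedure": layout.procedure,
        "side": layout.side,
        "room": {"width": layout.plan.width, "height": layout.plan.height},
        "obstacles": [_rect(o) for o in layout.plan.obstacles],
        "destinations": {k: [v[0], v[1]] for k, v in layout.plan.destinations.items()},
        "furniture": [
            {
                "id": f.id,
                "kind": f.kind,
                "center": [f.center[0], f.center[1]],
                "footprint": [f.footprint[0], f.footprint[1]],
                **({"table_angle": f.table_angle} if f.table_angle is not None else {}),
            }
            for f in layout.furniture
        ],
        "agents": [
            {
                "role": a.role,
                "position": [a.position[0], a.position[1]],
                "facing": [a.facing[0], a.facing[1]],
            }
            for a in layout.agents
        ],
    }


def save_layout(layout: LayoutSetup, path) -> None:
    Path(path).write_text(yaml.safe_dump(layout_to_dict(layout), sort_keys=False))


# ---------------------------------------------------------------------------
# Operations


def mirror_layout(layout: LayoutSetup) -> LayoutSetup:
    """Reflect a setup across the OR-table long axis (contralateral variant).

    Furniture and staff mirror; the room (obstacles and destinations) is
    fixed to the building and does not.  Table angles flip sign (clockwise
    becomes counter-clockwise), so the unsigned ergonomic angle -- and with
    it every rotation-based score -- is preserved.  The operation is an
    involution.
    """
    y0 = layout.mirror_axis_y

    def refl(pt: Point) -> Point:
        return (pt[0], 2.0 * y0 - pt[1])

    furniture = tuple(
        replace(
            f,
            center=refl(f.center),
            table_angle=(None if f.table_angle is None else (360.0 - f.table_angle) % 360.0),
        )
        for f in layout.furniture
    )
    agents = tuple(
        replace(a, position=refl(a.position), facing=(a.facing[0], -a.facing[1]))
        for a in layout.agents
    )
    mirrored = replace(
        layout,
        side=("right" if layout.side == "left" else "left"),
        furniture=furniture,
        agents=agents,
    )
    mirrored.validate()
    return mirrored


def relative_angle(observer: AgentPose, target: Point) -> float:
    """Unsigned angle in degrees, in [0, 180], between the observer's facing
    direction and the direction to ``target``."""
    dx = target[0] - observer.position[0]
    dy = target[1] - observer.position[1]
    norm = math.hypot(dx, dy)
    if norm < 1e-12:
        raise ValueError("relative_angle: target coincides with observer position")
    fx, fy = observer.facing
    dot = fx * dx + fy * dy
    cross = fx * dy - fy * dx
    # atan2 form: numerically stable near 0 and 180 degrees
    return math.degrees(math.atan2(abs(cross), dot))


@dataclass(frozen=True)
class Finding:
    """Outcome of one layout-requirement check."""

    requirement_id: int
    status: str  # "pass" | "warn"
    measured_value: float
    threshold: float
    detail: str

    def to_dict(self) -> dict:
        return {
            "requirement_id": self.requirement_id,
            "status": self.status,
            "measured_value": round(self.measured_value, 3),
            "threshold": self.threshold,
            "detail": self.detail,
        }


def lint_layout(
    layout: LayoutSetup,
    *,
    reach_threshold: float = REACH_THRESHOLD_M,
    clearance_margin: float = CLEARANCE_MARGIN_M,
    proximity_radius: float = PROXIMITY_RADIUS_M,
    behind_angle: float = BEHIND_ANGLE_DEG,
    behind_tolerance: float = BEHIND_TOLERANCE_DEG,
) -> list[Finding]:
    """Check the machine-checkable layout requirements.

    Emits one pass/warn finding per requirement: tables within reach of the
    surgeon (2), tables not behind the surgeon (6), circulator paths keeping
    a clearance margin from the instrument tables (7, path-based), and
    tables within a proximity radius of the OR table (8).
    """
    from . import navigation  # deferred: navigation depends on this module

    su = layout.agent("SU")
    tables = layout.instrument_tables
    su_pt = _ShapelyPoint(su.position)

    reach = max(t.polygon.distance(su_pt) for t in tables)
    findings = [
        Finding(
            requirement_id=2,
            status="pass" if reach <= reach_threshold else "warn",
            measured_value=reach,
            threshold=reach_threshold,
            detail="max distance from the surgeon to an instrument-table edge",
        )
    ]

    worst_angle = max(relative_angle(su, t.center) for t in tables)
    findings.append(
        Finding(
            requirement_id=6,
            status="pass" if worst_angle <= behind_angle + behind_tolerance else "warn",
            measured_value=worst_angle,
            threshold=behind_angle + behind_tolerance,
            detail="max angular offset of an instrument table from the surgeon's facing",
        )
    )

    # req 7: simulate the circulator's paths and measure the closest approach
    # to any instrument table.
    grid = navigation.rasterize(layout)
    clearance = math.inf
    origin = layout.plan.destinations.get("WP1")
    if origin is not None:
        for name in layout.plan.destinations:
            if name == "WP1":
                continue
            try:
                path = navigation.shortest_path(
                    grid,
                    navigation.approach_point(grid, origin),
                    navigation.approach_point(grid, layout.plan.destinations[name]),
                )
            except navigation.UnreachableError:
                continue
            for wp in path.waypoints:
                p = _ShapelyPoint(wp)
                for t in tables:
                    clearance = min(clearance, t.polygon.distance(p))
    if math.isinf(clearance):
        clearance = clearance_margin  # no resolvable path: nothing to flag
    findings.append(
        Finding(
            requirement_id=7,
            status="pass" if clearance >= clearance_margin else "warn",
            measured_value=clearance,
            threshold=clearance_margin,
            detail="min clearance between simulated circulator paths and instrument tables",
        )
    )

    or_poly = layout.or_table.polygon
    proximity = max(t.polygon.distance(or_poly) for t in tables)
    findings.append(
        Finding(
            requirement_id=8,
            status="pass" if proximity <= proximity_radius else "warn",
            measured_value=proximity,
            threshold=proximity_radius,
            detail="max distance from an instrument table to the OR table",
        )
    )
    return findings
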