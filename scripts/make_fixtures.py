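"""Author the bundled OR-setup fixtures.

Builds the seven left-side setups to scale from their schematic
descriptions, derives each instrument table's angle label from the
geometry at the scrub nurse (snapped to 5 degrees), writes the left
YAML files and their mirrored right-side counterparts, and prints the
diagnostic quantities (rotational-movement totals, travel distances,
lint findings) used to verify the reconstruction.

Run from the repository root:  python scripts/make_fixtures.py
"""

from __future__ import annotations

import math
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from orsim import circulator, trm
from orsim.geometry import (
    AgentPose,
    FloorPlan,
    Furniture,
    LayoutSetup,
    Obstacle,
    lint_layout,
    mirror_layout,
    save_layout,
)

OUT = Path(__file__).resolve().parents[1] / "src" / "orsim" / "data"

ROOM = dict(width=6.5, height=6.5)

# Room-fixed equipment (never mirrors).
OBSTACLES = [
    ("rack_r1", 1.2, 6.3, 1.8, 6.5),
    ("rack_r2", 4.3, 6.3, 4.9, 6.5),
    ("anesthesia_station", 5.9, 4.0, 6.5, 5.0),
    ("solution_stand", 0.0, 1.9, 0.35, 2.4),
]

DESTINATIONS = {
    "R1": (1.5, 5.85),
    "R2": (4.6, 5.85),
    "AR": (6.25, 3.0),
    "sterile_room_door": (0.25, 3.0),
    "ST1": (0.25, 2.8),
    "ST2": (0.35, 3.6),
    "WP1": (0.75, 0.9),
    "WP2": (0.75, 4.6),
}

OR_TABLE = dict(center=(3.9, 3.0), footprint=(2.0, 0.9))
TABLE_FP = (0.6, 0.4)
WOUND = {"TKA": (3.5, 3.0), "THA": (4.0, 3.0)}  # knee resp. hip, head at east end


def unit(v):
    n = math.hypot(*v)
    return (v[0] / n, v[1] / n)


def towards(a, b):
    return unit((b[0] - a[0], b[1] - a[1]))


def stored_angle(facing, origin, target, snap=5.0):
    """Clockwise-positive angle label of a table seen from the nurse."""
    dx, dy = target[0] - origin[0], target[1] - origin[1]
    dot = facing[0] * dx + facing[1] * dy
    cross = facing[0] * dy - facing[1] * dx
    ang = (-math.degrees(math.atan2(cross, dot))) % 360.0
    return round(ang / snap) * snap % 360.0


# Per-setup definitions (left side).  SN facing is the nurse's neutral
# working direction: along her instrument row for the classic setups,
# towards the surgeon for the face-to-face designs.
def build_setups():
    setups = {}

    def agents(proc, sn_pos, sn_face, su_pos, extra):
        su_face = towards(su_pos, WOUND[proc])
        out = [
            AgentPose.create("SN", sn_pos, sn_face),
            AgentPose.create("SU", su_pos, su_face),
        ]
        for role, pos in extra:
            face = towards(pos, WOUND[proc]) if role in ("A1", "A2") else ((-1.0, 0.0) if role == "AN" else (1.0, 0.0))
            out.append(AgentPose.create(role, pos, face))
        return out

    # --- TKA setup 1 (initial): U of four tables around the nurse at the
    # foot, nurse beside the surgeon, tables at 0/45/90/180 degrees.
    sn, su = (2.3, 3.9), (3.8, 3.75)
    setups["TKA1"] = dict(
        procedure="TKA",
        sn=sn,
        sn_face=(1.0, 0.0),
        su=su,
        extra=[("A1", (4.5, 3.75)), ("A2", (3.8, 2.25)), ("AN", (5.3, 3.9)), ("CIRC", (0.75, 0.9))],
        tables=[("table1", (3.2, 3.9)), ("table2", (2.6, 3.6)), ("table3", (2.3, 3.1)), ("table4", (1.45, 3.9))],
    )

    # --- TKA setup 2 (new): tables in a U behind the surgeon, nurse behind
    # him; one table crowds workplace 2.
    sn = (3.9, 4.7)
    setups["TKA2"] = dict(
        procedure="TKA",
        sn=sn,
        sn_face=towards(sn, su),
        su=su,
        extra=[("A1", (4.5, 3.75)), ("A2", (3.8, 2.25)), ("AN", (5.3, 3.9)), ("CIRC", (0.75, 0.9))],
        tables=[("table1", (3.15, 4.25)), ("table2", (4.65, 4.25)), ("table3", (1.35, 4.6)), ("table4", (4.9, 4.9))],
    )

    # --- TKA setup 3 (new, best): compact U at the foot, nurse facing the
    # surgeon directly across her main table.
    sn = (2.4, 3.0)
    setups["TKA3"] = dict(
        procedure="TKA",
        sn=sn,
        sn_face=towards(sn, su),
        su=su,
        extra=[("A1", (4.5, 3.75)), ("A2", (3.8, 2.25)), ("AN", (5.3, 3.9)), ("CIRC", (0.75, 0.9))],
        tables=[("table1", (3.2, 3.75)), ("table2", (2.4, 3.75)), ("table3", (2.4, 2.25)), ("table4", (1.55, 3.0))],
    )

    # --- TKA setup 4 (new): the setup-1 table row moved with the nurse to
    # the contralateral side, nurse working along the row opposite the
    # surgeon.
    sn = (2.3, 2.1)
    setups["TKA4"] = dict(
        procedure="TKA",
        sn=sn,
        sn_face=(1.0, 0.0),
        su=su,
        extra=[("A1", (4.5, 3.75)), ("A2", (4.4, 2.25)), ("AN", (5.3, 3.9)), ("CIRC", (0.75, 0.9))],
        tables=[("table1", (3.2, 2.1)), ("table2", (2.6, 2.4)), ("table3", (2.3, 2.9)), ("table4", (1.45, 2.1))],
    )

    # --- THA setup 1 (initial): J-shape of four tables at the foot.
    su = (3.9, 3.75)
    sn = (2.3, 3.9)
    setups["THA1"] = dict(
        procedure="THA",
        sn=sn,
        sn_face=(1.0, 0.0),
        su=su,
        extra=[("A1", (4.6, 3.75)), ("A2", (3.9, 2.25)), ("AN", (5.3, 3.9)), ("CIRC", (0.75, 0.9))],
        tables=[("table1", (3.2, 3.9)), ("table2", (2.3, 4.7)), ("table3", (1.55, 4.45)), ("table4", (1.45, 3.9))],
    )

    # --- THA setup 2 (initial): three tables in a U behind the surgeon.
    sn = (4.3, 4.7)
    setups["THA2"] = dict(
        procedure="THA",
        sn=sn,
        sn_face=towards(sn, su),
        su=su,
        extra=[("A1", (4.7, 3.75)), ("A2", (3.9, 2.25)), ("AN", (5.3, 3.9)), ("CIRC", (0.75, 0.9))],
        tables=[("table1", (4.05, 4.1)), ("table2", (5.1, 4.6)), ("table3", (3.5, 5.35))],
    )

    # --- THA setup 3 (new, best): three tables in a U at the foot, nurse
    # facing the surgeon.
    sn = (2.4, 3.5)
    setups["THA3"] = dict(
        procedure="THA",
        sn=sn,
        sn_face=towards(sn, su),
        su=su,
        extra=[("A1", (4.6, 3.75)), ("A2", (3.9, 2.25)), ("AN", (5.3, 3.9)), ("CIRC", (0.75, 0.9))],
        tables=[("table1", (3.3, 3.65)), ("table2", (2.55, 3.0)), ("table3", (1.35, 3.35))],
    )

    built = {}
    for setup_id, spec in setups.items():
        plan = FloorPlan(
            width=ROOM["width"],
            height=ROOM["height"],
            obstacles=tuple(Obstacle.from_rect(*o) for o in OBSTACLES),
            destinations=dict(DESTINATIONS),
        )
        furniture = [Furniture(id="or_table", kind="or_table", center=OR_TABLE["center"], footprint=OR_TABLE["footprint"])]
        for tid, center in spec["tables"]:
            furniture.append(
                Furniture(
                    id=tid,
                    kind="instrument_table",
                    center=center,
                    footprint=TABLE_FP,
                    table_angle=stored_angle(unit(spec["sn_face"]), spec["sn"], center),
                )
            )
        layout = LayoutSetup(
            id=setup_id,
            procedure=spec["procedure"],
            side="left",
            plan=plan,
            furniture=tuple(furniture),
            agents=tuple(agents(spec["procedure"], spec["sn"], spec["sn_face"], spec["su"], spec["extra"])),
        )
        layout.validate()
        built[setup_id] = layout
    return built


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    setups = build_setups()
    from orsim.synthetic import TRIP_PRESETS

    for setup_id, left in setups.items():
        right = mirror_layout(left)
        save_layout(left, OUT / f"{setup_id}_left.yaml")
        save_layout(right, OUT / f"{setup_id}_right.yaml")

        t = trm.trm_setup(trm.derive_rotation_specs(left))
        counts = {k: m for k, (m, _) in TRIP_PRESETS[left.procedure].items()}
        trips = circulator.TripProfile(counts=counts)
        travel_l = circulator.total_travel_distance(left, trips)
        travel_r = circulator.total_travel_distance(right, trips)
        warns = [f.requirement_id for f in lint_layout(left) if f.status == "warn"]
        warns_r = [f.requirement_id for f in lint_layout(right) if f.status == "warn"]
        angles = {f.id: f.table_angle for f in left.instrument_tables}
        print(
            f"{setup_id}: angles={angles} TRM={t.total:7.1f}  "
            f"travel L={travel_l.total_distance:6.1f} R={travel_r.total_distance:6.1f}  "
            f"lint warn L={warns} R={warns_r}"
        )

    for proc in ("TKA", "THA"):
        totals = {
            sid: trm.trm_setup(trm.derive_rotation_specs(lay)).total
            for sid, lay in setups.items()
            if lay.procedure == proc
        }
        best = min(totals, key=totals.get)
        print(f"{proc}: TRM ranking {sorted(totals.items(), key=lambda kv: kv[1])} -> best {best}")


if __name__ == "__main__":
    main()
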