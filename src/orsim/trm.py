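"""Total Rotational Movement (TRM): a torso-rotation ergonomics score.

Each instrument handover makes the scrub nurse rotate towards the table
holding the instrument (angle ``alpha``), rotate towards the surgeon to
pass it (``beta``), and makes the surgeon rotate towards the nurse to
take it (``gamma``).  Each rotation is performed up to twice per handover
cycle -- once towards the target and once back to the neutral pose -- so
every angle carries an integer movement count in {0, 1, 2}.

Per table the score is ``i*alpha + j*beta + k*gamma`` (degrees); the
setup score is the sum over its instrument tables.  Lower is better: a
compact U-shaped table arrangement in front of the nurse, with the nurse
facing the surgeon, minimises the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .geometry import LayoutSetup, relative_angle

__all__ = [
    "RotationSpec",
    "TRMResult",
    "trm_table",
    "trm_setup",
    "derive_rotation_specs",
    "unsigned_angle",
    "DEFAULT_MOVEMENT_COUNTS",
]

DEFAULT_MOVEMENT_COUNTS = (2, 2, 2)


def unsigned_angle(angle_deg: float) -> float:
    """Fold a signed/stored angle in [0, 360) to a rotation magnitude in [0, 180]."""
    a = angle_deg % 360.0
    return min(a, 360.0 - a)


@dataclass(frozen=True)
class RotationSpec:
    """Rotation angles and movement counts for the handovers of one table."""

    table_id: str
    alpha: float  # scrub-nurse rotation to grab from the table, degrees
    beta: float   # scrub-nurse rotation to hand to the surgeon, degrees
    gamma: float  # surgeon rotation to grab from the nurse, degrees
    i: int = 2
    j: int = 2
    k: int = 2

    def validate(self) -> None:
        for name, count in (("i", self.i), ("j", self.j), ("k", self.k)):
            if not (isinstance(count, int) and 0 <= count <= 2):
                raise ValueError(f"RotationSpec.{name}: movement count must be an integer in 0..2, got {count!r}")
        for name, ang in (("alpha", self.alpha), ("beta", self.beta), ("gamma", self.gamma)):
            if not (0.0 <= ang < 360.0):
                raise ValueError(f"RotationSpec.{name}: angle must lie in [0, 360), got {ang}")


@dataclass(frozen=True)
class TRMResult:
    per_table: dict[str, float]
    total: float


def trm_table(spec: RotationSpec) -> float:
    """Rotational load of one table's handovers: ``i*alpha + j*beta + k*gamma``."""
    spec.validate()
    return spec.i * spec.alpha + spec.j * spec.beta + spec.k * spec.gamma


def trm_setup(specs: Sequence[RotationSpec]) -> TRMResult:
    """Sum of the per-table rotational loads over a whole OR setup."""
    per_table: dict[str, float] = {}
    for spec in specs:
        if spec.table_id in per_table:
            raise ValueError(f"trm_setup: duplicate table_id {spec.table_id!r}")
        per_table[spec.table_id] = trm_table(spec)
    return TRMResult(per_table=per_table, total=float(sum(per_table.values())))


def derive_rotation_specs(
    layout: LayoutSetup,
    movement_counts: tuple[int, int, int] = DEFAULT_MOVEMENT_COUNTS,
    turn_direction: str | None = None,
) -> list[RotationSpec]:
    """Derive per-table rotation specs from the layout geometry.

    The scrub nurse is assumed to rotate her torso by each table's angular
    position (``alpha`` = table angle); ``beta`` is her rotation towards
    the surgeon and ``gamma`` the surgeon's rotation towards her, both
    measured from the respective facing directions.

    ``turn_direction`` selects how off-axis tables are reached: ``None``
    (default) takes the shorter rotation (unsigned angle, mirror
    invariant); ``"right"``/``"left"`` force a clockwise respectively
    counter-clockwise turn, which penalises tables on the far side and
    models a nurse with a preferred turning side.
    """
    if turn_direction not in (None, "right", "left"):
        raise ValueError(f"turn_direction must be None, 'right' or 'left', got {turn_direction!r}")
    sn = layout.agent("SN")
    su = layout.agent("SU")
    i, j, k = movement_counts
    beta = relative_angle(sn, su.position)
    gamma = relative_angle(su, sn.position)
    specs = []
    for table in layout.instrument_tables:
        stored = table.table_angle % 360.0
        if turn_direction is None:
            alpha = unsigned_angle(stored)
        elif turn_direction == "right":
            alpha = stored  # table angles are stored clockwise-positive
        else:
            alpha = (360.0 - stored) % 360.0
        specs.append(
            RotationSpec(table_id=table.id, alpha=alpha, beta=beta, gamma=gamma, i=i, j=j, k=k)
        )
    return specs
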