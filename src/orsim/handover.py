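"""Discrete-event simulation of scrub-nurse-to-surgeon instrument handovers.

One handover decomposes into: the nurse rotates to the table (``alpha``),
grasps the instrument, rotates to the surgeon (``beta``), passes it over
the nurse-surgeon gap, the surgeon rotates towards her (``gamma``) and
takes it.  With a constant torso rotation speed ``omega`` and arm speed
``v`` the instrument handover time (IHT) of a table is

    IHT = (alpha + beta + gamma) / omega + d_pass / v + t_grasp + t_transfer

where ``d_pass`` is the nurse-surgeon distance clipped to arm reach.
Handovers never overlap: events are scheduled sequentially on a monotone
clock.  Total handover time per surgery is the count-weighted sum of the
per-table IHTs; counts may be fractional (per-surgery means), in which
case totals are expected values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .geometry import LayoutSetup
from .trm import derive_rotation_specs

__all__ = [
    "MotionParams",
    "HandoverEvent",
    "SimResult",
    "iht",
    "total_handover_time",
    "calibrate",
    "CalibrationResult",
    "compare_sim_measured",
]


@dataclass(frozen=True)
class MotionParams:
    """Kinematic constants that turn handover geometry into seconds."""

    rotation_speed: float = 180.0  # torso rotation, degrees / s
    arm_speed: float = 1.0         # instrument pass, m / s
    grasp_time: float = 0.3        # s, picking the instrument off the table
    transfer_time: float = 0.2     # s, placing it in the surgeon's hand
    arm_reach: float = 0.8         # m, pass distance is clipped to this

    def validate(self) -> None:
        for name in ("rotation_speed", "arm_speed", "grasp_time", "transfer_time", "arm_reach"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MotionParams.{name} must be strictly positive")


@dataclass(frozen=True)
class HandoverEvent:
    time: float      # seconds since incision (event start)
    table_id: str
    duration: float  # seconds


@dataclass(frozen=True)
class SimResult:
    per_table_iht: dict[str, float]
    total_handover_time: float
    event_log: tuple[HandoverEvent, ...]


def _pass_distance(layout: LayoutSetup, params: MotionParams) -> float:
    sn = layout.agent("SN").position
    su = layout.agent("SU").position
    return min(math.hypot(su[0] - sn[0], su[1] - sn[1]), params.arm_reach)


def iht(
    layout: LayoutSetup,
    table_id: str,
    params: MotionParams = MotionParams(),
    turn_direction: str | None = None,
) -> float:
    """Instrument handover time in seconds for one table of a setup."""
    params.validate()
    specs = {s.table_id: s for s in derive_rotation_specs(layout, turn_direction=turn_direction)}
    if table_id not in specs:
        raise KeyError(f"iht: layout {layout.id!r} has no instrument table {table_id!r}")
    s = specs[table_id]
    return (
        (s.alpha + s.beta + s.gamma) / params.rotation_speed
        + _pass_distance(layout, params) / params.arm_speed
        + params.grasp_time
        + params.transfer_time
    )


def total_handover_time(
    layout: LayoutSetup,
    counts: Mapping[str, float],
    params: MotionParams = MotionParams(),
    turn_direction: str | None = None,
) -> SimResult:
    """Count-weighted total handover time with a sequential event log.

    Integer counts produce one event per handover; a fractional remainder
    (counts are usually per-surgery means) is logged as a final partial
    event so that the event log and the total agree exactly.
    """
    table_ids = [t.id for t in layout.instrument_tables]
    per_table = {t: iht(layout, t, params, turn_direction) for t in table_ids}
    for table_id, count in counts.items():
        if table_id not in per_table:
            raise KeyError(f"total_handover_time: unknown table {table_id!r}")
        if count < 0:
            raise ValueError(f"total_handover_time: negative count for {table_id!r}")
    events = []
    clock = 0.0
    for table_id in table_ids:
        count = float(counts.get(table_id, 0.0))
        duration = per_table[table_id]
        whole, frac = int(count), count - int(count)
        for _ in range(whole):
            events.append(HandoverEvent(time=clock, table_id=table_id, duration=duration))
            clock += duration
        if frac > 1e-12:
            events.append(HandoverEvent(time=clock, table_id=table_id, duration=frac * duration))
            clock += frac * duration
    total = float(sum(e.duration for e in events))
    return SimResult(per_table_iht=per_table, total_handover_time=total, event_log=tuple(events))


@dataclass(frozen=True)
class CalibrationResult:
    params: MotionParams
    residuals: dict[str, float]     # per-table (model - measured), seconds
    cost: float                     # sum of squared residuals
    initial_cost: float


def calibrate(
    params_init: MotionParams,
    layout: LayoutSetup,
    measured_iht: Mapping[str, float],
    turn_direction: str | None = None,
) -> CalibrationResult:
    """Fit motion parameters to intraoperatively measured per-table IHTs.

    Least-squares in log-parameter space (positivity by construction) over
    rotation speed, arm speed, grasp and transfer time, started from
    ``params_init``; the fitted residual norm never exceeds the initial
    one.  Requires at least two tables with distinct rotation geometry --
    with identical angles everywhere the system carries no information
    about the rotation speed.
    """
    params_init.validate()
    specs = {s.table_id: s for s in derive_rotation_specs(layout, turn_direction=turn_direction)}
    unknown = set(measured_iht) - set(specs)
    if unknown:
        raise KeyError(f"calibrate: measurements for unknown tables {sorted(unknown)}")
    if len(measured_iht) < 2:
        raise ValueError("calibrate: need measurements for at least two tables")
    table_ids = sorted(measured_iht)
    angles = np.array([specs[t].alpha + specs[t].beta + specs[t].gamma for t in table_ids])
    if np.ptp(angles) < 1e-9:
        raise ValueError("calibrate: degenerate system -- all tables at identical rotation geometry")
    measured = np.array([measured_iht[t] for t in table_ids])
    sn = layout.agent("SN").position
    su = layout.agent("SU").position
    d_raw = math.hypot(su[0] - sn[0], su[1] - sn[1])

    def model(theta: np.ndarray) -> np.ndarray:
        omega, v, grasp, transfer = np.exp(theta)
        d = min(d_raw, params_init.arm_reach)
        return angles / omega + d / v + grasp + transfer

    x0 = np.log(
        [
            params_init.rotation_speed,
            params_init.arm_speed,
            params_init.grasp_time,
            params_init.transfer_time,
        ]
    )
    initial_cost = float(np.sum((model(x0) - measured) ** 2))
    sol = least_squares(
        lambda th: model(th) - measured,
        x0,
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=2000,
    )
    omega, v, grasp, transfer = np.exp(sol.x)
    fitted = replace(
        params_init,
        rotation_speed=float(omega),
        arm_speed=float(v),
        grasp_time=float(grasp),
        transfer_time=float(transfer),
    )
    resid = model(sol.x) - measured
    return CalibrationResult(
        params=fitted,
        residuals={t: float(r) for t, r in zip(table_ids, resid)},
        cost=float(np.sum(resid**2)),
        initial_cost=initial_cost,
    )


def compare_sim_measured(
    sim: Mapping[str, float], measured: Mapping[str, float]
) -> dict[str, float]:
    """Absolute per-table difference |sim - measured|, rounded to 2 decimals."""
    if set(sim) != set(measured):
        raise KeyError(
            f"compare_sim_measured: table ids differ "
            f"(sim {sorted(sim)}, measured {sorted(measured)})"
        )
    return {t: round(abs(sim[t] - measured[t]), 2) for t in sim}
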