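"""End-to-end setup comparison: the full analysis pipeline and its report.

Mirrors the shape of the clinical study: enumerate the scenario models
(each setup in its left- and right-side variant), simulate per-table
instrument handover times, count-weighted total handover times, the
rotational-movement score and the circulator travel distance, summarise
IBCT per setup, run pairwise two-tailed t-tests between setups, and --
when intraoperative measurements are supplied -- report the per-table
simulation-vs-measurement deltas.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import circulator, handover, synthetic, trm
from .geometry import Finding, LayoutSetup, lint_layout
from .stats import SampleSummary, TestResult, rank_setups, summarize, t_test_two_tailed
from .synthetic import SurgeryLog

__all__ = [
    "ScenarioMetrics",
    "ComparisonReport",
    "run_pipeline",
    "logs_to_csv",
    "logs_from_csv",
]

LOG_CSV_COLUMNS = ["surgery_id", "setup_id", "side", "table_or_dest", "kind", "count_or_value"]


@dataclass(frozen=True)
class ScenarioMetrics:
    """Simulated metrics for one setup x side model."""

    setup_id: str
    side: str
    per_table_iht: dict[str, float]
    total_handover_time: float
    trm_total: float
    travel_total: float
    travel_per_destination: dict[str, float]
    lint: list[dict]


@dataclass(frozen=True)
class ComparisonReport:
    procedure: str
    inventory: list[tuple[str, str]]  # (setup_id, side) scenario models
    scenarios: list[ScenarioMetrics]
    ibct_summaries: dict[str, SampleSummary]
    pairwise_ibct_tests: dict[str, TestResult]
    deltas: dict[str, dict[str, float]]
    rankings: dict[str, list[str]]

    @property
    def n_models(self) -> int:
        return len(self.inventory)

    def to_dict(self) -> dict:
        return {
            "procedure": self.procedure,
            "n_models": self.n_models,
            "inventory": [list(pair) for pair in self.inventory],
            "scenarios": [asdict(s) for s in self.scenarios],
            "ibct_summaries": {k: asdict(v) for k, v in self.ibct_summaries.items()},
            "pairwise_ibct_tests": {k: asdict(v) for k, v in self.pairwise_ibct_tests.items()},
            "deltas": {k: dict(v) for k, v in self.deltas.items()},
            "rankings": {k: list(v) for k, v in self.rankings.items()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary_table(self) -> pd.DataFrame:
        """One row per scenario model with the headline metrics."""
        rows = []
        for s in self.scenarios:
            rows.append(
                {
                    "setup": s.setup_id,
                    "side": s.side,
                    "total_handover_s": round(s.total_handover_time, 1),
                    "trm_deg": round(s.trm_total, 1),
                    "travel_m": round(s.travel_total, 1),
                    "ibct_min": (
                        round(self.ibct_summaries[s.setup_id].mean, 1)
                        if s.setup_id in self.ibct_summaries
                        else None
                    ),
                }
            )
        return pd.DataFrame(rows)


def _mean_counts(logs: Sequence[SurgeryLog], kind: str) -> dict[str, float]:
    keys = sorted({k for log in logs for k in getattr(log, kind)})
    n = len(logs)
    return {k: sum(getattr(log, kind).get(k, 0) for log in logs) / n for k in keys}


def run_pipeline(
    layouts: Sequence[LayoutSetup],
    cohorts: Mapping[str, Sequence[SurgeryLog]] | None = None,
    params: handover.MotionParams = handover.MotionParams(),
    measured_iht: Mapping[str, Mapping[str, float]] | None = None,
    output_dir=None,
) -> ComparisonReport:
    """Run the full comparison over a set of scenario models.

    ``layouts`` lists every setup x side model (a setup appearing with both
    sides yields two models, as in the simulation study).  ``cohorts`` maps
    setup ids to surgery logs (recorded or synthetic); when absent, the
    published per-setup presets provide handover and trip counts.  IBCT
    t-tests require cohorts and at least two setups.
    """
    if not layouts:
        raise ValueError("run_pipeline: need at least one layout")
    procedures = {lay.procedure for lay in layouts}
    if len(procedures) > 1:
        raise ValueError(f"run_pipeline: mixed procedures in one comparison: {sorted(procedures)}")
    procedure = procedures.pop()
    cohorts = dict(cohorts or {})

    inventory = [(lay.id, lay.side) for lay in layouts]
    setup_ids = list(dict.fromkeys(lay.id for lay in layouts))

    scenarios = []
    for lay in layouts:
        logs = cohorts.get(lay.id)
        if logs:
            counts = _mean_counts(logs, "handover_counts")
            trip_counts = _mean_counts(logs, "trip_counts")
        else:
            preset = synthetic.preset_config(lay.id, n_surgeries=1, seed=0)
            counts = {k: m for k, (m, _) in (preset.handover_count_params or {}).items()}
            trip_counts = {k: m for k, (m, _) in (preset.trip_params or {}).items()}
        counts = {k: v for k, v in counts.items() if any(t.id == k for t in lay.instrument_tables)}
        sim = handover.total_handover_time(lay, counts, params)
        trm_result = trm.trm_setup(trm.derive_rotation_specs(lay))
        travel = circulator.total_travel_distance(lay, circulator.TripProfile(counts=trip_counts))
        scenarios.append(
            ScenarioMetrics(
                setup_id=lay.id,
                side=lay.side,
                per_table_iht=sim.per_table_iht,
                total_handover_time=sim.total_handover_time,
                trm_total=trm_result.total,
                travel_total=travel.total_distance,
                travel_per_destination=travel.per_destination,
                lint=[f.to_dict() for f in lint_layout(lay)],
            )
        )

    ibct_summaries: dict[str, SampleSummary] = {}
    for sid in setup_ids:
        logs = cohorts.get(sid)
        if logs and len(logs) >= 2:
            ibct_summaries[sid] = summarize([log.ibct for log in logs])

    pairwise: dict[str, TestResult] = {}
    if len(setup_ids) >= 2:
        for i, a in enumerate(setup_ids):
            for b in setup_ids[i + 1:]:
                if a in ibct_summaries and b in ibct_summaries:
                    pairwise[f"{a} vs {b}"] = t_test_two_tailed(
                        [log.ibct for log in cohorts[a]], [log.ibct for log in cohorts[b]]
                    )

    deltas: dict[str, dict[str, float]] = {}
    if measured_iht:
        for sid, measured in measured_iht.items():
            lay = next((l for l in layouts if l.id == sid), None)
            if lay is None:
                raise KeyError(f"run_pipeline: measurements for unknown setup {sid!r}")
            sim_iht = {t: handover.iht(lay, t, params) for t in measured}
            deltas[sid] = handover.compare_sim_measured(sim_iht, {k: float(v) for k, v in measured.items()})

    def _metric_by_setup(attr: str) -> dict[str, float]:
        by_setup: dict[str, float] = {}
        for s in scenarios:
            by_setup[s.setup_id] = max(by_setup.get(s.setup_id, 0.0), getattr(s, attr))
        return by_setup

    rankings = {
        "trm": rank_setups(_metric_by_setup("trm_total")),
        "total_handover_time": rank_setups(_metric_by_setup("total_handover_time")),
        "travel": rank_setups(_metric_by_setup("travel_total")),
    }

    report = ComparisonReport(
        procedure=procedure,
        inventory=inventory,
        scenarios=scenarios,
        ibct_summaries=ibct_summaries,
        pairwise_ibct_tests=pairwise,
        deltas=deltas,
        rankings=rankings,
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / f"comparison_{procedure}.json")
        report.summary_table().to_csv(out / f"comparison_{procedure}.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# Surgery-log CSV I/O (long format, one row per recorded quantity)


def logs_to_csv(logs: Mapping[str, Sequence[SurgeryLog]], path, side: str = "left") -> None:
    """Write cohorts to the long-format log CSV (``kind`` in handover/trip/ibct)."""
    rows = []
    for setup_id, cohort in logs.items():
        for log in cohort:
            for table, count in log.handover_counts.items():
                rows.append((log.surgery_id, setup_id, side, table, "handover", count))
            for dest, count in log.trip_counts.items():
                rows.append((log.surgery_id, setup_id, side, dest, "trip", count))
            rows.append((log.surgery_id, setup_id, side, "", "ibct", log.ibct))
    pd.DataFrame(rows, columns=LOG_CSV_COLUMNS).to_csv(path, index=False)


def logs_from_csv(path) -> dict[str, list[SurgeryLog]]:
    """Read cohorts back from the long-format log CSV."""
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    missing = set(LOG_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"logs_from_csv: missing columns {sorted(missing)}")
    cohorts: dict[str, list[SurgeryLog]] = {}
    for (setup_id, surgery_id), group in df.groupby(["setup_id", "surgery_id"], sort=False):
        handover_counts: dict[str, int] = {}
        trip_counts: dict[str, int] = {}
        ibct = synthetic.IBCT_FLOOR_MIN
        for _, row in group.iterrows():
            kind = row["kind"]
            if kind == "handover":
                handover_counts[str(row["table_or_dest"])] = int(float(row["count_or_value"]))
            elif kind == "trip":
                trip_counts[str(row["table_or_dest"])] = int(float(row["count_or_value"]))
            elif kind == "ibct":
                ibct = float(row["count_or_value"])
            else:
                raise ValueError(f"logs_from_csv: unknown kind {kind!r}")
        cohorts.setdefault(str(setup_id), []).append(
            SurgeryLog(
                surgery_id=str(surgery_id),
                handover_counts=handover_counts,
                trip_counts=trip_counts,
                ibct=ibct,
            )
        )
    return cohorts
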