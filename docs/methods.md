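# Methods

This note records the models implemented in `orsim`, the assumptions
behind them, and the design choices made where the published material
left the design open.

## Geometry and coordinates

Layouts are planar (top view), in meters, origin at the room's south-west
corner. The default room is 6.5 m × 6.5 m. The OR table is room-fixed
with its long axis horizontal; the patient's head lies at the east end,
next to the anesthesia workstation and the anesthesia-room door (AR).
Room-fixed equipment (supply racks R1/R2 along the north wall, the
anesthesia workstation, a solution stand on the west wall) and the named
destinations (R1, R2, ST1, ST2, AR, WP1, WP2, sterile-room door) belong
to the floor plan; furniture (instrument tables) and staff poses belong
to the setup.

**Mirroring.** The contralateral variant of a setup reflects furniture
centers and staff positions across the OR-table long axis and negates
facing y-components and table-angle signs; the room does not move. The
operation is an involution, and because reflection preserves unsigned
angles and pairwise distances among the mirrored entities, every
rotation- and handover-time quantity is mirror-invariant by construction.
Travel distances are not, which is the point: left/right asymmetries
arise purely from the interaction of the mirrored furniture with the
fixed room.

**Fixtures are reconstructions.** The source layouts were published as
schematic drawings without coordinates. The bundled fixtures are
authored to scale such that each setup's documented qualitative
properties hold under computation: the initial TKA setup's tables sit at
0°/45°/90°/180° from the nurse; in the left-side TKA 2 an instrument
table crowds workplace 2 shut (the planner approaches it to the nearest
free spot, and all destinations remain reachable); in the right-side
THA 3 the table cluster and the solution stand jointly close the west
passage so the circulator must round the OR table. Absolute distances
(as opposed to orderings and blocked/free relations) are therefore
reconstruction-dependent and should not be read as measurements. One
known divergence: in this reconstruction the left-side THA 3 travel
total is close to, but not below, the initial THA setups' — per-setup
travel orderings are sensitive to centimeter-scale choices the drawings
do not constrain. `scripts/make_fixtures.py` regenerates all fixture
files and their diagnostics.

**Table angles.** Each instrument table carries a `table_angle`: its
angular position relative to the scrub nurse's neutral facing, stored
clockwise-positive in [0, 360). Fixtures set it from the authored
geometry, snapped to 5° (the conventional 0°/45°/90°/180° labels). The
nurse's neutral facing is her working direction: along her instrument
row for the classic side-by-side setups (TKA 1/4, THA 1), directly
towards the surgeon for the face-to-face designs (TKA 2/3, THA 2/3).

## Total Rotational Movement

Per table `TRM = i·α + j·β + k·γ` with movement counts i, j, k ∈ {0, 1, 2}
and the default (2, 2, 2): each rotation is performed towards the target
and back once per handover cycle. α is taken from the table angle, folded
to the unsigned rotation magnitude in [0, 180] by default; β and γ are
the nurse→surgeon and surgeon→nurse angles computed from the poses. A
`turn_direction` parameter ("right"/"left") instead charges the full
clockwise or counter-clockwise rotation, modelling a nurse with a
preferred turning side; the default shorter-rotation convention is
mirror-invariant and is what the setup comparison uses.

The published per-setup TRM totals could not be re-derived exactly —
they depend on per-table angles and on which movements had counts below
2, neither of which was published. The reconstruction therefore targets
the *ordering* (the redesigned Setup 3 attains the minimum for both
procedures, with ≥ 160° margin here), not the printed totals.

## Handover-time model

The handover decomposition (rotate–grasp–rotate–pass–rotate–transfer)

    IHT = (α + β + γ)/ω + min(d, reach)/v + t_grasp + t_transfer

is this package's own motion model; the original study used a commercial
simulation engine whose internals are not published. Defaults: torso
rotation speed ω = 180°/s, arm speed v = 1.0 m/s, grasp 0.3 s, transfer
0.2 s, arm reach 0.8 m — round numbers in the range of natural adult
movement, chosen once. The model reproduces the measured monotone
ordering of per-table handover times in every fixture (larger table
angle ⇒ longer handover) and is calibratable: `calibrate` fits the four
motion constants to measured per-table IHTs by trust-region least
squares in log-parameter space (positivity by construction), started
from and never worse than the supplied initial parameters. The rotation
speed is identified by the spread of table angles (hence the degenerate
error when all tables share one angle); the three additive constants are
only jointly identified from per-table data, which is harmless for
prediction. Events are scheduled sequentially on a monotone clock —
handovers never overlap in practice. Handover counts may be fractional
(per-surgery means); a fractional remainder is logged as a partial event
so event-log and total agree exactly, and totals are then expected
values.

## Circulator travel

Round trips from a fixed origin (WP1) to each destination, counts
multiplied in — the published data are per-destination trip counts, not
tour sequences, so no tour optimisation is attempted. Path lengths come
from a deterministic 8-connected grid A* (octile heuristic, diagonal
cost √2, no corner cutting, ties broken by heuristic then cell index):
cell size 0.10 m, footprints and obstacles inflated by the 0.30 m agent
radius with mitre joins, so rectangles inflate to rectangles and
corridor widths stay exact. A cell is blocked only if its interior
overlaps the inflated region — two solids that merely touch leave a
passable seam, matching the physical reading of the inflation as the
walkable-center criterion. Grid path lengths are within the octile bound
(≤ ~8.3 %) of true Euclidean shortest paths and are validated against an
exhaustive uniform-cost search.

Destinations whose exact point rasterizes shut (the nurse inside her U
of tables, a crowded workplace) are approached to the nearest *reachable*
free cell within 1.5 m; a destination with no such cell raises an
unreachable error by default (a skip policy that reports it instead is
selectable). ST1 lies beyond the sterile-room door; a fixed 4 m corridor
allowance per leg (configurable) stands in for the undrawn corridor.

## Statistics

Setup comparisons use mean ± sample SD (n−1) summaries and a two-tailed
two-sample t-test. Welch's test is the default — the compared cohorts
have unequal sizes and no reason to share a variance — with Student's
pooled variant selectable. Degenerate zero-variance inputs follow a
documented convention (equal means ⇒ p = 1, unequal ⇒ p = 0). Because
the underlying per-surgery recordings are not public, exact published
p-values are not a reproduction target; the tests are validated against
an independently coded textbook formula instead.

## Synthetic surgery logs

The generator emulates the *published summaries*, which is all that is
public: per-table handover counts, per-destination trip counts and IBCT,
each as mean ± SD for a given setup. Counts are drawn as
`round(max(0, Normal(m, sd)))`. Flooring a normal at zero inflates its
mean — negligibly for high counts, but by several standard errors of the
mean for the low-count presets (e.g. 2.7 ± 2.3 handovers, 0.3 ± 0.8) —
so the latent location `m` is calibrated per preset (analytic expectation
of the floored-and-rounded draw, solved by bisection) such that the
drawn count's expectation equals the published mean exactly. The
published SD serves as the latent spread; for low-count presets the
realised SD is necessarily below the printed one, since a non-negative
count with that mean cannot carry that spread. The THA trip preset for
ST1 (printed 0.3 ± 6.6, an SD twenty times a non-negative mean) is kept
verbatim but flagged as a suspected misprint and excluded from
spread checks. IBCT is a normal floored at 10 min; all published IBCT
means sit > 2.9 SD above the floor, so the floor shifts means by under
0.02 min and needs no correction. One seeded RNG stream per cohort makes
cohorts byte-reproducible.

What passing tests show — and don't. Cohorts of n = 5000 recover every
published mean within three standard errors, which validates the
pipeline's bookkeeping, not the clinical data-generating process: real
handover counts are overdispersed, correlated with procedure duration,
and not normal. Conclusions about real theatres still require recorded
logs, which the same pipeline accepts via the log CSV format.

## Problem sizes and numerics

Acceptance-style checks use cohorts of 5000 surgeries (sampling error on
a mean ≈ SD/70, comfortably inside a 3-SE band), 100 random 20×20 grids
for planner/oracle equivalence, and the 14 bundled fixtures for the
geometric invariants. Calibration tolerances are set to machine level
(ftol = xtol = 1e-15) so exact-recovery round trips close to < 1e-6 s.
Lint thresholds: surgeon reach 1.0 m, path clearance 1.0 m, OR-table
proximity 2.5 m, behind-the-surgeon 90° + 5° tolerance; findings are
pass/warn with the measured value, never hard errors, since the
requirements are design guidance rather than invariants.

## Known limitations

- Fixture coordinates are reconstructions; absolute TRM totals, handover
  seconds and travel meters are not comparable to the original study's
  engine outputs, only orderings and invariances are.
- The motion model is stationary (no fatigue, no learning) and agents do
  not avoid each other, only furniture.
- Round-trip travel ignores trip chaining and task batching, so totals
  are upper bounds under the recorded trip counts.
- The generator draws fields independently; it cannot exhibit the
  count–duration correlation real surgeries have.
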