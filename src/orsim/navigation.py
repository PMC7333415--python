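"""Obstacle-aware shortest paths on a rasterized floor plan.

The planner is a deterministic 8-connected grid A* with the octile
heuristic: straight moves cost one cell, diagonal moves sqrt(2) cells, and
diagonals may not cut corners (both orthogonal neighbours of a diagonal
step must be free).  Obstacles and furniture footprints are inflated by
the agent radius before rasterization, so the point agent plans for a
walker of finite width.  Output is bit-for-bit reproducible: ties in the
open list are broken by heuristic value and then by cell index.

Path lengths on this graph are guaranteed within the octile bound (at
most ~8.3% above) of the true Euclidean shortest path in free space.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass

import numpy as np
from shapely import prepared
from shapely.geometry import box
from shapely.ops import unary_union

from .geometry import LayoutSetup, Point

__all__ = [
    "NavGrid",
    "Path",
    "UnreachableError",
    "rasterize",
    "shortest_path",
    "approach_point",
    "DEFAULT_CELL_SIZE",
    "DEFAULT_AGENT_RADIUS",
]

DEFAULT_CELL_SIZE = 0.10     # m
DEFAULT_AGENT_RADIUS = 0.30  # m

_SQRT2 = math.sqrt(2.0)
# 8-neighbourhood: (di, dj, cost in cells)
_MOVES = (
    (0, 1, 1.0), (0, -1, 1.0), (1, 0, 1.0), (-1, 0, 1.0),
    (1, 1, _SQRT2), (1, -1, _SQRT2), (-1, 1, _SQRT2), (-1, -1, _SQRT2),
)


class UnreachableError(RuntimeError):
    """No collision-free path exists to the requested goal."""


@dataclass(frozen=True)
class NavGrid:
    """Occupancy lattice over the room; ``True`` cells are blocked."""

    cell_size: float
    occupancy: np.ndarray  # bool, shape (ny, nx); [j, i] = row j (y), col i (x)
    origin: Point = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    def cell_of(self, pt: Point) -> tuple[int, int]:
        i = int((pt[0] - self.origin[0]) / self.cell_size)
        j = int((pt[1] - self.origin[1]) / self.cell_size)
        ny, nx = self.occupancy.shape
        return (min(max(j, 0), ny - 1), min(max(i, 0), nx - 1))

    def center_of(self, cell: tuple[int, int]) -> Point:
        j, i = cell
        return (
            self.origin[0] + (i + 0.5) * self.cell_size,
            self.origin[1] + (j + 0.5) * self.cell_size,
        )

    def blocked(self, pt: Point) -> bool:
        j, i = self.cell_of(pt)
        return bool(self.occupancy[j, i])


def rasterize(
    layout: LayoutSetup,
    cell_size: float = DEFAULT_CELL_SIZE,
    agent_radius: float = DEFAULT_AGENT_RADIUS,
) -> NavGrid:
    """Rasterize a layout into an occupancy grid.

    Cells intersecting any plan obstacle or furniture footprint inflated by
    ``agent_radius`` are blocked.  Staff are not treated as obstacles (they
    step aside for the circulator; tables do not).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if agent_radius < 0:
        raise ValueError("agent_radius must be non-negative")
    if cell_size > max(agent_radius, DEFAULT_CELL_SIZE) * 2.5:
        warnings.warn(
            f"cell_size {cell_size} m is coarse relative to the agent radius; "
            "narrow passages may rasterize shut",
            stacklevel=2,
        )
    nx = math.ceil(layout.plan.width / cell_size)
    ny = math.ceil(layout.plan.height / cell_size)
    occupancy = np.zeros((ny, nx), dtype=bool)

    solids = [o.polygon for o in layout.plan.obstacles] + [f.polygon for f in layout.furniture]
    if solids:
        union = unary_union(solids)
        # Mitre join: rectangular footprints inflate to rectangles (a box
        # Minkowski sum), keeping corridor widths exact and auditable.
        inflated = union.buffer(agent_radius, join_style="mitre") if agent_radius > 0 else union
        prep = prepared.prep(inflated)
        eps = 1e-9  # block on interior overlap only; a shared boundary is passable
        xmin, ymin, xmax, ymax = inflated.bounds
        i_lo = max(0, int(xmin / cell_size) - 1)
        i_hi = min(nx - 1, int(xmax / cell_size) + 1)
        j_lo = max(0, int(ymin / cell_size) - 1)
        j_hi = min(ny - 1, int(ymax / cell_size) + 1)
        for j in range(j_lo, j_hi + 1):
            y0 = j * cell_size
            for i in range(i_lo, i_hi + 1):
                x0 = i * cell_size
                cell = box(x0 + eps, y0 + eps, x0 + cell_size - eps, y0 + cell_size - eps)
                if prep.intersects(cell):
                    occupancy[j, i] = True
    return NavGrid(cell_size=cell_size, occupancy=occupancy)


@dataclass(frozen=True)
class Path:
    """An 8-connected grid path; length is the sum of the move costs."""

    waypoints: tuple[Point, ...]
    length: float


def _octile(a: tuple[int, int], b: tuple[int, int]) -> float:
    dj = abs(a[0] - b[0])
    di = abs(a[1] - b[1])
    return (max(di, dj) - min(di, dj)) + _SQRT2 * min(di, dj)


def shortest_path(grid: NavGrid, start: Point, goal: Point) -> Path:
    """Minimal-length 8-connected path between two free points.

    Raises :class:`UnreachableError` when the goal cannot be reached and
    ``ValueError`` when either endpoint lies in a blocked cell.
    """
    occ = grid.occupancy
    ny, nx = occ.shape
    s = grid.cell_of(start)
    g = grid.cell_of(goal)
    if occ[s]:
        raise ValueError(f"shortest_path: start point {start} lies in a blocked cell")
    if occ[g]:
        raise ValueError(f"shortest_path: goal point {goal} lies in a blocked cell")

    # A* with deterministic tie-breaking: (f, h, cell) ordering.
    dist = {s: 0.0}
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    h0 = _octile(s, g)
    open_heap: list[tuple[float, float, tuple[int, int]]] = [(h0, h0, s)]
    closed: set[tuple[int, int]] = set()
    while open_heap:
        f, h, cell = heapq.heappop(open_heap)
        if cell in closed:
            continue
        if cell == g:
            break
        closed.add(cell)
        dj_, di_ = cell
        d_here = dist[cell]
        for dj, di, cost in _MOVES:
            nj, ni = dj_ + dj, di_ + di
            if not (0 <= nj < ny and 0 <= ni < nx) or occ[nj, ni]:
                continue
            if dj != 0 and di != 0 and (occ[dj_ + dj, di_] or occ[dj_, di_ + di]):
                continue  # no corner cutting
            nd = d_here + cost
            nb = (nj, ni)
            if nb not in dist or nd < dist[nb] - 1e-12:
                dist[nb] = nd
                parent[nb] = cell
                nh = _octile(nb, g)
                heapq.heappush(open_heap, (nd + nh, nh, nb))
    else:
        raise UnreachableError(f"no path to goal {goal} from {start}")
    if g not in dist:
        raise UnreachableError(f"no path to goal {goal} from {start}")

    cells = [g]
    while cells[-1] != s:
        cells.append(parent[cells[-1]])
    cells.reverse()
    return Path(
        waypoints=tuple(grid.center_of(c) for c in cells),
        length=dist[g] * grid.cell_size,
    )


def distance_map(grid: NavGrid, start: Point) -> np.ndarray:
    """Single-source shortest-path distances (meters) to every cell.

    Dijkstra over the same 8-connected move set as :func:`shortest_path`;
    unreachable cells get ``inf``.  Useful when one origin serves many
    goals (the circulator's working place).
    """
    occ = grid.occupancy
    ny, nx = occ.shape
    s = grid.cell_of(start)
    if occ[s]:
        raise ValueError(f"distance_map: start point {start} lies in a blocked cell")
    dist = np.full((ny, nx), math.inf)
    dist[s] = 0.0
    heap: list[tuple[float, tuple[int, int]]] = [(0.0, s)]
    while heap:
        d, (j, i) = heapq.heappop(heap)
        if d > dist[j, i] + 1e-12:
            continue
        for dj, di, cost in _MOVES:
            njj, nii = j + dj, i + di
            if not (0 <= njj < ny and 0 <= nii < nx) or occ[njj, nii]:
                continue
            if dj != 0 and di != 0 and (occ[j + dj, i] or occ[j, i + di]):
                continue
            nd = d + cost
            if nd < dist[njj, nii] - 1e-12:
                dist[njj, nii] = nd
                heapq.heappush(heap, (nd, (njj, nii)))
    return dist * grid.cell_size


def reachable_distance(
    grid: NavGrid, dist: np.ndarray, pt: Point, max_offset: float = 1.5
) -> float:
    """Walking distance to the closest reachable spot near ``pt``.

    If the cell under ``pt`` is free and reached, that cell's distance is
    returned.  Otherwise the nearest *reachable* free cell within
    ``max_offset`` meters of ``pt`` stands in (approach-point policy for
    goals crowded or enclosed by furniture).  Raises
    :class:`UnreachableError` when no reachable cell is that close.
    """
    j0, i0 = grid.cell_of(pt)
    if math.isfinite(dist[j0, i0]):
        return float(dist[j0, i0])
    ny, nx = grid.occupancy.shape
    r_cells = int(math.ceil(max_offset / grid.cell_size))
    best: tuple[float, tuple[int, int]] | None = None
    for j in range(max(0, j0 - r_cells), min(ny, j0 + r_cells + 1)):
        for i in range(max(0, i0 - r_cells), min(nx, i0 + r_cells + 1)):
            if not math.isfinite(dist[j, i]):
                continue
            c = grid.center_of((j, i))
            d = math.hypot(c[0] - pt[0], c[1] - pt[1])
            if d <= max_offset and (best is None or (d, (j, i)) < best):
                best = (d, (j, i))
    if best is None:
        raise UnreachableError(f"no reachable cell within {max_offset} m of {pt}")
    return float(dist[best[1]])


def approach_point(grid: NavGrid, pt: Point, max_offset: float = 1.5) -> Point:
    """Return ``pt`` itself if free, else the nearest free cell center.

    Walkable approximation for goals that sit flush against furniture (a
    scrub nurse inside a U of tables, a workplace crowded by a table): the
    circulator walks to the closest reachable spot within ``max_offset``
    meters.  Raises :class:`UnreachableError` if no free cell is that close.
    """
    if not grid.blocked(pt):
        return pt
    occ = grid.occupancy
    ny, nx = occ.shape
    j0, i0 = grid.cell_of(pt)
    r_cells = int(math.ceil(max_offset / grid.cell_size))
    best: tuple[float, tuple[int, int]] | None = None
    for j in range(max(0, j0 - r_cells), min(ny, j0 + r_cells + 1)):
        for i in range(max(0, i0 - r_cells), min(nx, i0 + r_cells + 1)):
            if occ[j, i]:
                continue
            c = grid.center_of((j, i))
            d = math.hypot(c[0] - pt[0], c[1] - pt[1])
            if d <= max_offset and (best is None or (d, (j, i)) < best):
                best = (d, (j, i))
    if best is None:
        raise UnreachableError(f"no free cell within {max_offset} m of {pt}")
    return grid.center_of(best[1])
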