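"""Barrier-aware least-cost distances over water.

Distances are geodesic shortest paths on the water mask with 8-connectivity
(diagonal steps cost cell_size * sqrt(2)), so shorelines act as barriers to
water movement.  This mirrors the behaviour of GIS cost-distance tools on a
uniform cost surface.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import BayGrid

_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def path_distance(
    water_mask: np.ndarray,
    sources: list[tuple[int, int]],
    cell_size: float,
) -> np.ndarray:
    """Shortest over-water distance (m) from every cell to the nearest source.

    Returns an array shaped like ``water_mask`` with 0 at source cells,
    ``inf`` on water unreachable from any source, and ``nan`` on land.

    Raises
    ------
    ValueError
        If ``sources`` is empty or any source lies on land.
    """
    water_mask = np.asarray(water_mask, dtype=bool)
    if len(sources) == 0:
        raise ValueError("at least one source cell is required")
    for rc in sources:
        r, c = rc
        if not (0 <= r < water_mask.shape[0] and 0 <= c < water_mask.shape[1]):
            raise ValueError(f"source {rc} outside the grid")
        if not water_mask[r, c]:
            raise ValueError(f"source {rc} lies on land")

    n_rows, n_cols = water_mask.shape
    node_id = np.full(water_mask.shape, -1, dtype=np.int64)
    rr, cc = np.nonzero(water_mask)
    node_id[rr, cc] = np.arange(rr.size)

    row_idx, col_idx, weights = [], [], []
    diag = cell_size * math.sqrt(2.0)
    for dr, dc in _OFFSETS:
        r0 = max(0, -dr)
        r1 = n_rows - max(0, dr)
        c0 = max(0, -dc)
        c1 = n_cols - max(0, dc)
        a = water_mask[r0:r1, c0:c1]
        b = water_mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        both = a & b
        src = node_id[r0:r1, c0:c1][both]
        dst = node_id[r0 + dr : r1 + dr, c0 + dc : c1 + dc][both]
        row_idx.append(src)
        col_idx.append(dst)
        w = diag if dr != 0 and dc != 0 else cell_size
        weights.append(np.full(src.size, w))

    n = rr.size
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(row_idx), np.concatenate(col_idx))),
        shape=(n, n),
    ).tocsr()

    source_nodes = np.array([node_id[r, c] for r, c in sources])
    dist = dijkstra(graph, directed=False, indices=source_nodes, min_only=True)

    out = np.full(water_mask.shape, np.nan)
    out[rr, cc] = dist
    return out


def ocean_sources(
    depth: np.ndarray, water_mask: np.ndarray, cutoff: float = 30.0
) -> list[tuple[int, int]]:
    """Water cells at or beyond the deep-water cutoff (inclusive).

    The open ocean is taken to be everything seaward of the ``cutoff`` depth
    contour; a cell at exactly the cutoff qualifies.
    """
    water_mask = np.asarray(water_mask, dtype=bool)
    depth = np.asarray(depth, dtype=float)
    deep = water_mask & (depth >= cutoff)
    cells = list(zip(*np.nonzero(deep)))
    if not cells:
        raise ValueError(f"no water cell reaches the {cutoff} m open-ocean cutoff")
    return [(int(r), int(c)) for r, c in cells]


def snap_to_water(
    water_mask: np.ndarray, cell: tuple[int, int], max_radius: int = 2
) -> tuple[int, int]:
    """Snap a (row, col) point to the nearest water cell within ``max_radius``.

    Vector river-mouth coordinates rarely land exactly on a water cell after
    rasterisation; snapping makes that adjustment explicit and bounded.
    """
    water_mask = np.asarray(water_mask, dtype=bool)
    r0, c0 = cell
    if 0 <= r0 < water_mask.shape[0] and 0 <= c0 < water_mask.shape[1]:
        if water_mask[r0, c0]:
            return (int(r0), int(c0))
    best = None
    best_d = np.inf
    for r in range(r0 - max_radius, r0 + max_radius + 1):
        for c in range(c0 - max_radius, c0 + max_radius + 1):
            if 0 <= r < water_mask.shape[0] and 0 <= c < water_mask.shape[1]:
                if water_mask[r, c]:
                    d = math.hypot(r - r0, c - c0)
                    if d < best_d:
                        best, best_d = (r, c), d
    if best is None:
        raise ValueError(f"no water cell within {max_radius} cells of {cell}")
    return best


def add_distances(grid: BayGrid, ocean_cutoff: float = 30.0) -> BayGrid:
    """Fill ``d_river`` and ``d_ocean`` on a grid (computed once; time-invariant)."""
    if not grid.river_mouths:
        raise ValueError("grid has no river mouths")
    mouths = [snap_to_water(grid.water_mask, m) for m in grid.river_mouths]
    grid.river_mouths = mouths
    grid.d_river = path_distance(grid.water_mask, mouths, grid.cell_size)
    ocean = ocean_sources(grid.depth, grid.water_mask, cutoff=ocean_cutoff)
    grid.d_ocean = path_distance(grid.water_mask, ocean, grid.cell_size)
    return grid
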