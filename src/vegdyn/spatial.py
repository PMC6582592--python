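"""Raster neighbourhood utilities at 100 m grain.

Two neighbourhood tiers feed the transition predictors:

* tier 1 — the 8 adjacent cells;
* tier 2 — cells whose centre lies within 300 m of the focal cell centre,
  excluding the focal cell and tier 1 (20 cells on a 100 m grid).

Out-of-bounds and inactive cells contribute zero weight but stay in the
denominator, so shares shrink towards zero near the landscape edge.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

CELL_SIZE = 100.0
EDGE_DISTANCE_CAP = 1000.0

#: tier-1 offsets: the 8-neighbourhood
TIER1_OFFSETS: tuple[tuple[int, int], ...] = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)

#: tier-2 offsets: centre distance <= 3 cells, excluding focal and tier 1
TIER2_OFFSETS: tuple[tuple[int, int], ...] = tuple(
    (dr, dc)
    for dr in range(-3, 4)
    for dc in range(-3, 4)
    if dr * dr + dc * dc <= 9 and max(abs(dr), abs(dc)) > 1
)

assert len(TIER1_OFFSETS) == 8
assert len(TIER2_OFFSETS) == 20


def _shifted(grid: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """View of ``grid`` shifted by (dr, dc) with zero fill outside bounds."""
    rows, cols = grid.shape[:2]
    out = np.zeros_like(grid)
    r0, r1 = max(dr, 0), min(rows + dr, rows)
    c0, c1 = max(dc, 0), min(cols + dc, cols)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = grid[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def species_weight_grid(
    state_grid: np.ndarray, active: np.ndarray, weight_matrix: np.ndarray
) -> np.ndarray:
    """Per-cell species weights, zero on inactive cells. Shape (rows, cols, pool)."""
    w = weight_matrix[state_grid]
    w = np.where(active[..., None], w, 0.0)
    return w


def tier_share_grids(
    state_grid: np.ndarray, active: np.ndarray, weight_matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Tier-1 and tier-2 species share grids for every cell.

    Returns two (rows, cols, pool) arrays; shares are means over the fixed
    tier denominators (8 and 20), so missing neighbours dilute the share.
    """
    w = species_weight_grid(state_grid, active, weight_matrix)
    tier1 = np.zeros_like(w)
    for dr, dc in TIER1_OFFSETS:
        tier1 += _shifted(w, -dr, -dc)
    tier2 = np.zeros_like(w)
    for dr, dc in TIER2_OFFSETS:
        tier2 += _shifted(w, -dr, -dc)
    return tier1 / len(TIER1_OFFSETS), tier2 / len(TIER2_OFFSETS)


def tier_shares_at(
    state_grid: np.ndarray,
    active: np.ndarray,
    weight_matrix: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Tier shares for selected cells only. Shapes (n, pool)."""
    w = species_weight_grid(state_grid, active, weight_matrix)
    nr, nc = state_grid.shape
    pool = weight_matrix.shape[1]
    t1 = np.zeros((len(rows), pool))
    t2 = np.zeros((len(rows), pool))
    for acc, offsets in ((t1, TIER1_OFFSETS), (t2, TIER2_OFFSETS)):
        for dr, dc in offsets:
            rr = rows + dr
            cc = cols + dc
            ok = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
            if ok.any():
                acc[ok] += w[rr[ok], cc[ok]]
    return t1 / len(TIER1_OFFSETS), t2 / len(TIER2_OFFSETS)


def distance_to_edge_grid(
    active: np.ndarray,
    cell_size: float = CELL_SIZE,
    cap: float = EDGE_DISTANCE_CAP,
) -> np.ndarray:
    """Chebyshev distance (m) from each cell to the nearest inactive or
    out-of-bounds cell, capped. Inactive cells get distance 0."""
    padded = np.zeros((active.shape[0] + 2, active.shape[1] + 2), dtype=np.uint8)
    padded[1:-1, 1:-1] = active.astype(np.uint8)
    dist = ndimage.distance_transform_cdt(padded, metric="chessboard")[1:-1, 1:-1]
    return np.minimum(dist.astype(float) * cell_size, cap)
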