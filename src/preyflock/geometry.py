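"""Periodic-domain geometry: minimum-image displacements and neighbour search.

All pairwise geometry in the simulator goes through the minimum-image
convention on a square periodic domain of side ``L``; wrapped displacement
components lie in ``[-L/2, L/2)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "minimum_image",
    "wrap_positions",
    "pairwise_displacements",
    "neighbour_pairs_bruteforce",
    "neighbour_pairs_celllist",
]


def minimum_image(dx: np.ndarray, L: float) -> np.ndarray:
    """Wrap displacement components into ``[-L/2, L/2)``."""
    return np.asarray(dx) - L * np.floor(np.asarray(dx) / L + 0.5)


def wrap_positions(x: np.ndarray, L: float) -> np.ndarray:
    """Wrap absolute positions into ``[0, L)``."""
    return np.asarray(x) - L * np.floor(np.asarray(x) / L)


def pairwise_displacements(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    """Minimum-image displacements ``b[j] - a[i]`` with shape (len(a), len(b), 2)."""
    return minimum_image(b[np.newaxis, :, :] - a[:, np.newaxis, :], L)


def neighbour_pairs_bruteforce(positions: np.ndarray, radius: float, L: float) -> np.ndarray:
    """All unordered pairs (i < j) with minimum-image distance <= radius.

    O(N^2) reference; returns an (n_pairs, 2) int array sorted lexicographically.
    """
    n = len(positions)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    d = pairwise_displacements(positions, positions, L)
    dist2 = np.einsum("ijk,ijk->ij", d, d)
    iu, ju = np.triu_indices(n, k=1)
    keep = dist2[iu, ju] <= radius * radius
    return np.column_stack([iu[keep], ju[keep]]).astype(np.int64)


def neighbour_pairs_celllist(positions: np.ndarray, radius: float, L: float) -> np.ndarray:
    """Cell-list neighbour search, exact and equal to the brute-force pair set.

    Requires ``radius < L/2``. Cells have side >= radius so only the 3x3
    neighbourhood of each cell needs scanning (with periodic wrapping).
    """
    if not radius < L / 2:
        raise ValueError(f"cell-list search requires radius < L/2, got {radius} >= {L / 2}")
    n = len(positions)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    pos = wrap_positions(np.asarray(positions, dtype=np.float64), L)
    n_cells = max(int(L / radius), 1)
    if n_cells < 3:
        # too few cells for a distinct 3x3 stencil: fall back to brute force
        return neighbour_pairs_bruteforce(pos, radius, L)
    cell_side = L / n_cells
    cx = np.minimum((pos[:, 0] / cell_side).astype(np.int64), n_cells - 1)
    cy = np.minimum((pos[:, 1] / cell_side).astype(np.int64), n_cells - 1)
    buckets: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        buckets.setdefault((int(cx[i]), int(cy[i])), []).append(i)
    r2 = radius * radius
    out: list[tuple[int, int]] = []
    for (bx, by), members in buckets.items():
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                key = ((bx + ox) % n_cells, (by + oy) % n_cells)
                others = buckets.get(key)
                if others is None:
                    continue
                for i in members:
                    for j in others:
                        if j <= i:
                            continue
                        d = minimum_image(pos[j] - pos[i], L)
                        if d[0] * d[0] + d[1] * d[1] <= r2:
                            out.append((i, j))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.array(sorted(set(out)), dtype=np.int64)
    return pairs
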