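"""Hilbert space-filling-curve embedding of a 1D variable sequence into a 2D
grid, plus the naive row-stacking baseline.

A tabular feature vector has no spatial structure a convolution can exploit;
placing consecutive variables along a Hilbert traversal of a 2^p x 2^p grid
guarantees that adjacent input indices occupy grid cells at Manhattan
distance 1, so local convolution kernels see locally coherent groups of
variables.  The naive baseline (row-major reshape) breaks this adjacency at
every row boundary.

Orientation convention: the curve starts at cell (0, 0) and for order 1
visits (0,0), (1,0), (1,1), (0,1) — i.e. the first move is down the first
column.  Coordinates are (row, col).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class HilbertMap:
    """Bijection between curve positions 0..4^p-1 and cells of a 2^p grid."""

    order: int
    coords: tuple[tuple[int, int], ...]
    n_used: int = 0
    pad_value: float = 0.0

    @property
    def side(self) -> int:
        return 2**self.order

    @property
    def n_cells(self) -> int:
        return 4**self.order

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "order": self.order,
                    "coords": [list(c) for c in self.coords],
                    "n_used": self.n_used,
                    "pad_value": self.pad_value,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HilbertMap":
        d = json.loads(Path(path).read_text())
        return cls(
            order=d["order"],
            coords=tuple(tuple(c) for c in d["coords"]),
            n_used=d["n_used"],
            pad_value=d["pad_value"],
        )


def _position_to_cell(order: int, d: int) -> tuple[int, int]:
    """Standard iterative Hilbert index-to-cell conversion (bit-reversal with
    quadrant rotation)."""
    x = y = 0
    t = d
    s = 1
    side = 2**order
    while s < side:
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        if ry == 0:
            if rx == 1:
                x = s - 1 - x
                y = s - 1 - y
            x, y = y, x
        x += s * rx
        y += s * ry
        t //= 4
        s *= 2
    return y, x  # (row, col)


def hilbert_coords(order: int) -> HilbertMap:
    """Canonical Hilbert traversal of the 2^order x 2^order grid."""
    if order < 1:
        raise ValueError("order must be >= 1")
    coords = tuple(_position_to_cell(order, d) for d in range(4**order))
    return HilbertMap(order=order, coords=coords)


def order_for(n_variables: int) -> int:
    """Smallest curve order p with 4^p >= n_variables."""
    if n_variables < 1:
        raise ValueError("need at least one variable")
    p = 1
    while 4**p < n_variables:
        p += 1
    return p


def embed_vector(x: np.ndarray, hmap: HilbertMap) -> np.ndarray:
    """Place x[i] at the i-th curve cell; unused cells take pad_value."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1D")
    if len(x) > hmap.n_cells:
        raise ValueError(f"vector of length {len(x)} exceeds {hmap.n_cells} grid cells")
    grid = np.full((hmap.side, hmap.side), hmap.pad_value, dtype=float)
    for i, v in enumerate(x):
        r, c = hmap.coords[i]
        grid[r, c] = v
    return grid


def embed_matrix(X: np.ndarray, hmap: HilbertMap) -> np.ndarray:
    """Vectorised embedding of an (n, m) matrix into (n, side, side) grids."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if m > hmap.n_cells:
        raise ValueError("too many variables for the grid")
    grids = np.full((n, hmap.side, hmap.side), hmap.pad_value, dtype=float)
    rows = np.array([hmap.coords[i][0] for i in range(m)])
    cols = np.array([hmap.coords[i][1] for i in range(m)])
    grids[:, rows, cols] = X
    return grids


def unembed_vector(grid: np.ndarray, hmap: HilbertMap, n_used: int) -> np.ndarray:
    """Inverse of embed_vector on the used cells."""
    return np.array([grid[r, c] for r, c in hmap.coords[:n_used]])


def embed_naive(x: np.ndarray, side: int) -> np.ndarray:
    """Row-major reshape baseline with tail padding (pad value 0)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1D")
    if len(x) > side * side:
        raise ValueError("vector longer than grid")
    out = np.zeros(side * side, dtype=float)
    out[: len(x)] = x
    return out.reshape(side, side)


def unembed_naive(grid: np.ndarray, n_used: int) -> np.ndarray:
    return grid.reshape(-1)[:n_used]


def adjacent_pair_count(coords, n_used: int) -> int:
    """Number of consecutive input indices whose cells are grid-adjacent
    (Manhattan distance 1); the locality measure Hilbert maximises."""
    count = 0
    for i in range(n_used - 1):
        (r1, c1), (r2, c2) = coords[i], coords[i + 1]
        if abs(r1 - r2) + abs(c1 - c2) == 1:
            count += 1
    return count


def naive_coords(side: int) -> tuple[tuple[int, int], ...]:
    """Cell-visit order of the row-major baseline, for adjacency comparison."""
    return tuple((i // side, i % side) for i in range(side * side))
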