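"""Chaos game representation (CGR) and its frequency matrix (FCGR).

The chaos game places the four bases at the corners of the unit square --
A = (0,0), T = (1,0), G = (1,1), C = (0,1) -- and maps a DNA sequence to a
point cloud by the iterated midpoint rule

    P_i = 0.5 * (P_{i-1} + corner(s_i)),   P_0 = (0.5, 0.5).

Dividing the square into a 2^K x 2^K grid and counting points per cell gives
the frequency chaos game representation.  For every point with index i >= K
the containing cell is determined exactly by the K most recent bases, so the
FCGR is an arrangement of the overlapping k-mer counts of the sequence; this
equivalence is the module's primary correctness oracle.

Cell indices are computed with integer arithmetic directly from the base
bits rather than by flooring float coordinates: the exact coordinates are
dyadic rationals whose low-order bits fall below double precision for long
sequences, and rounding can land a float coordinate exactly on a grid line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

#: x-corner bit per base (right half of the square: T and G).
_XBIT = {"A": 0, "C": 0, "T": 1, "G": 1}
#: y-corner bit per base (top half of the square: C and G).
_YBIT = {"A": 0, "T": 0, "C": 1, "G": 1}

_CORNERS = {"A": (0.0, 0.0), "T": (1.0, 0.0), "G": (1.0, 1.0), "C": (0.0, 1.0)}

_BASES = "ACGT"


def _check_seq(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)!r}; alphabet is A/C/G/T")


@dataclass(frozen=True)
class CGRTrajectory:
    """Ordered CGR points, one per nucleotide, all strictly inside (0,1)^2."""

    points: tuple[tuple[float, float], ...]

    @property
    def L(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FCGRMatrix:
    """A 2^K x 2^K grid of CGR point counts (row 0 = top = C/G side)."""

    K: int
    counts: np.ndarray
    include_transient: bool = False

    def __post_init__(self) -> None:
        side = 2 ** self.K
        if self.counts.shape != (side, side):
            raise ValueError(f"counts must be {side}x{side} for K={self.K}")
        if (self.counts < 0).any():
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def cgr_trajectory(seq: str) -> CGRTrajectory:
    """Iterate the midpoint map from P_0 = (0.5, 0.5), one point per base."""
    _check_seq(seq)
    x, y = 0.5, 0.5
    pts = []
    for base in seq:
        cx, cy = _CORNERS[base]
        x = 0.5 * (x + cx)
        y = 0.5 * (y + cy)
        pts.append((x, y))
    return CGRTrajectory(points=tuple(pts))


def kmer_cell_index(kmer: str) -> tuple[int, int]:
    """Grid cell (row, col) holding every CGR point whose recent k-mer is ``kmer``.

    With kmer ``s_1 .. s_K`` (``s_K`` most recent), the column collects one
    bit per base, most recent base highest:  col = sum_j X(s_j) * 2^(j-1);
    the y-index is the same with the Y bits, and row = 2^K - 1 - y_index so
    that row 0 is the top of the image (C/G side).  Bijective over the 4^K
    k-mers.
    """
    _check_seq(kmer)
    K = len(kmer)
    col = 0
    yidx = 0
    for j, base in enumerate(kmer):  # j = 0 is s_1 (oldest) -> bit j
        col |= _XBIT[base] << j
        yidx |= _YBIT[base] << j
    return (2**K - 1 - yidx, col)


def cell_kmer(row: int, col: int, K: int) -> str:
    """Inverse of :func:`kmer_cell_index`: the k-mer owning grid cell (row, col)."""
    side = 2**K
    if not (0 <= row < side and 0 <= col < side):
        raise ValueError(f"cell ({row},{col}) outside {side}x{side} grid")
    yidx = side - 1 - row
    bases = []
    for j in range(K):  # bit j -> s_{j+1}
        xb = (col >> j) & 1
        yb = (yidx >> j) & 1
        bases.append({(0, 0): "A", (1, 0): "T", (0, 1): "C", (1, 1): "G"}[(xb, yb)])
    return "".join(bases)


def fcgr_counts(seq: str, K: int, include_transient: bool = False) -> FCGRMatrix:
    """Count CGR points per cell of the 2^K x 2^K grid.

    With ``include_transient=False`` (default) only points with index
    i >= K are binned; the result equals the overlapping k-mer counts and
    totals L - K + 1.  With ``include_transient=True`` the first K - 1
    points are also binned -- strict chaos-game counting over all L points --
    using half-open cells [m * 2^-K, (m+1) * 2^-K) on each axis.
    """
    _check_seq(seq)
    if K < 1:
        raise ValueError("K must be >= 1")
    L = len(seq)
    if L < K:
        raise ValueError(f"sequence length {L} < K={K}")
    side = 2**K
    counts = np.zeros((side, side), dtype=np.int64)
    xbits = [_XBIT[b] for b in seq]
    ybits = [_YBIT[b] for b in seq]
    mask = side - 1
    col = 0
    yidx = 0
    for i in range(L):
        # rolling K-bit window; most recent base in the high bit
        col = ((col >> 1) | (xbits[i] << (K - 1))) & mask
        yidx = ((yidx >> 1) | (ybits[i] << (K - 1))) & mask
        if i >= K - 1:
            counts[side - 1 - yidx, col] += 1
        elif include_transient:
            # Exact cell of the transient point P_{i+1}: its x-coordinate is
            # sum_j X(s_j) 2^{-(i-j+1)} + 2^{-(i+2)}, whose floor at 2^-K
            # resolution is the window bits shifted up plus the centre offset.
            n = i + 1  # prefix length consumed so far
            px = 0
            py = 0
            for j in range(n):
                px |= xbits[j] << (K - n + j)
                py |= ybits[j] << (K - n + j)
            px += 1 << (K - n - 1)
            py += 1 << (K - n - 1)
            counts[side - 1 - py, px] += 1
    return FCGRMatrix(K=K, counts=counts, include_transient=include_transient)


def fcgr_vector(m: FCGRMatrix) -> np.ndarray:
    """Row-major flattening of the count grid, normalized to sum to 1."""
    total = m.total
    if total == 0:
        raise ValueError("all-zero FCGR matrix cannot be normalized")
    return m.counts.flatten().astype(float) / total


def fcgr_feature_names(K: int) -> list[str]:
    """K-mer labels for the row-major cells of :func:`fcgr_vector`."""
    side = 2**K
    return [f"fcgr{K}_{cell_kmer(r, c, K)}" for r in range(side) for c in range(side)]


def fcgr_image(m: FCGRMatrix, side: int = 64) -> np.ndarray:
    """Render the count grid as an 8-bit grayscale image of shape (side, side).

    Darker means more points: pixel = round(255 * (1 - count / max_count)),
    so the fullest cell is black (0) and empty cells are white (255).  Each
    grid cell is replicated into a (side / 2^K)-pixel square block.  An
    all-zero matrix renders all white.
    """
    grid = 2**m.K
    if side % grid != 0:
        raise ValueError(f"image side {side} is not a multiple of 2^K = {grid}")
    cmax = m.counts.max()
    if cmax == 0:
        cell_pix = np.full((grid, grid), 255, dtype=np.uint8)
    else:
        cell_pix = np.rint(255.0 * (1.0 - m.counts / cmax)).astype(np.uint8)
    block = side // grid
    return np.kron(cell_pix, np.ones((block, block), dtype=np.uint8))


def combine_k(
    seq: str,
    Ks: Sequence[int],
    mode: Literal["vector", "image_stack"] = "vector",
    side: int = 64,
    include_transient: bool = False,
) -> np.ndarray:
    """Multi-K FCGR features: concatenated vectors or a stacked image channel per K.

    Vector mode returns a 1-D array of length sum(4^K); image mode returns an
    array of shape (len(Ks), side, side) with one grayscale channel per K.
    """
    if not Ks:
        raise ValueError("Ks must be non-empty")
    mats = [fcgr_counts(seq, K, include_transient=include_transient) for K in Ks]
    if mode == "vector":
        return np.concatenate([fcgr_vector(m) for m in mats])
    if mode == "image_stack":
        return np.stack([fcgr_image(m, side=side) for m in mats])
    raise ValueError(f"unknown mode {mode!r}")
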