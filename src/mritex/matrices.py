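"""Gray-level texture matrices: GLCM, GLRLM, GLSZM and the multi-level GLSZM.

All four tabulate the spatial arrangement of quantized gray levels inside
a region of interest:

* **GLCM** (co-occurrence): how often a pair of levels (j, k) occurs at a
  fixed pixel offset, with both ends inside the mask.  Normalized to a
  joint probability table L(j, k) whose marginals give the means and
  standard deviations used by the correlation feature.
* **GLRLM** (run length): counts of maximal collinear runs of one level,
  by level and run length, along a set of directions.  Runs are broken by
  the mask boundary.
* **GLSZM** (size zone): counts of connected zones of one level, by level
  and zone size; direction-free.
* **MGLSZM**: GLSZMs computed at several quantization depths, so zone
  statistics are observed across gray-level resolutions.

Indexing convention: gray levels are 1-based (1..L); array index [j-1]
holds level j.  Run lengths and zone sizes are likewise 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import DegenerateMatrixError
from .quantize import QuantizedROI, quantize

__all__ = [
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "SizeZoneMatrix",
    "MultiZoneMatrix",
    "glcm",
    "glrlm",
    "glszm",
    "mglszm",
    "DEFAULT_OFFSETS",
    "DEFAULT_DIRECTIONS",
    "DEFAULT_MGLSZM_LEVELS",
]

#: Distance-1 offsets at 0°, 45°, 90°, 135° (image row/col convention).
DEFAULT_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
DEFAULT_DIRECTIONS: Tuple[Tuple[int, int], ...] = DEFAULT_OFFSETS
DEFAULT_MGLSZM_LEVELS: Tuple[int, ...] = (4, 8, 16, 32)


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalized gray-level co-occurrence table with its raw counts."""

    counts: np.ndarray  # L x L pair counts accumulated over offsets
    offsets: Tuple[Tuple[int, int], ...]
    symmetric: bool

    @property
    def levels(self) -> int:
        return self.counts.shape[0]

    @property
    def P(self) -> np.ndarray:
        """Joint probability table; sums to 1."""
        return self.counts / self.counts.sum()

    @property
    def p_y(self) -> np.ndarray:
        """Row marginal distribution (first pixel of each pair)."""
        return self.P.sum(axis=1)

    @property
    def p_z(self) -> np.ndarray:
        """Column marginal distribution (second pixel of each pair)."""
        return self.P.sum(axis=0)

    @property
    def mean_y(self) -> float:
        return float(np.sum(self._levels_axis() * self.p_y))

    @property
    def mean_z(self) -> float:
        return float(np.sum(self._levels_axis() * self.p_z))

    @property
    def std_y(self) -> float:
        lv = self._levels_axis()
        return float(np.sqrt(np.sum((lv - self.mean_y) ** 2 * self.p_y)))

    @property
    def std_z(self) -> float:
        lv = self._levels_axis()
        return float(np.sqrt(np.sum((lv - self.mean_z) ** 2 * self.p_z)))

    def _levels_axis(self) -> np.ndarray:
        return np.arange(1, self.levels + 1, dtype=np.float64)

    def to_csv(self, path) -> None:
        _table_to_csv(self.P, path)


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts R(j, r): maximal runs of level j with length r."""

    counts: np.ndarray  # L x Rmax integer counts, pooled over directions
    directions: Tuple[Tuple[int, int], ...]

    @property
    def levels(self) -> int:
        return self.counts.shape[0]

    @property
    def max_run_length(self) -> int:
        return self.counts.shape[1]

    @property
    def n_runs(self) -> int:
        """Total run count (the normalization constant)."""
        return int(self.counts.sum())

    @property
    def P(self) -> np.ndarray:
        return self.counts / self.n_runs

    def to_csv(self, path) -> None:
        _table_to_csv(self.counts, path)


@dataclass(frozen=True)
class SizeZoneMatrix:
    """Zone counts Z(j, s): connected zones of level j with size s pixels."""

    counts: np.ndarray  # L x Smax integer counts
    connectivity: int  # 4 or 8

    @property
    def levels(self) -> int:
        return self.counts.shape[0]

    @property
    def max_zone_size(self) -> int:
        return self.counts.shape[1]

    @property
    def n_zones(self) -> int:
        return int(self.counts.sum())

    @property
    def P(self) -> np.ndarray:
        return self.counts / self.n_zones

    def to_csv(self, path) -> None:
        _table_to_csv(self.counts, path)


@dataclass(frozen=True)
class MultiZoneMatrix:
    """Size-zone matrices keyed by quantization level."""

    members: Dict[int, SizeZoneMatrix]

    @property
    def level_set(self) -> Tuple[int, ...]:
        return tuple(sorted(self.members))


def _table_to_csv(table: np.ndarray, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        table,
        index=np.arange(1, table.shape[0] + 1),
        columns=np.arange(1, table.shape[1] + 1),
    )
    df.to_csv(path, index_label="gray_level")


def glcm(
    roi: QuantizedROI,
    offsets: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> CooccurrenceMatrix:
    """Co-occurrence matrix pooled over ``offsets``.

    A pair is counted when both the pixel and the offset neighbour lie
    inside the mask.  With ``symmetric`` each pair is counted in both
    orders, making the table symmetric.  Raises
    :class:`DegenerateMatrixError` when no offset yields a valid pair.
    """
    offsets = tuple((int(dr), int(dc)) for dr, dc in offsets)
    if any(off == (0, 0) for off in offsets):
        raise ValueError("offsets must be nonzero")
    L = roi.levels
    grid, mask = roi.grid, roi.mask
    h, w = grid.shape
    counts = np.zeros((L, L), dtype=np.float64)
    for dr, dc in offsets:
        # overlap window of the grid with itself shifted by (dr, dc)
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = grid[r0:r1, c0:c1]
        b = grid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if not valid.any():
            continue
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    if counts.sum() == 0:
        raise DegenerateMatrixError("no valid pixel pair for any offset")
    if symmetric:
        counts = counts + counts.T
    return CooccurrenceMatrix(counts=counts, offsets=offsets, symmetric=symmetric)


def _mask_lines(
    grid: np.ndarray, mask: np.ndarray, direction: Tuple[int, int]
) -> Iterable[Tuple[np.ndarray, np.ndarray]]:
    """Yield (values, in_mask) 1-D slices of the grid along a direction.

    Opposite directions trace the same line families, so only the
    direction's axis matters for run extraction.
    """
    dr, dc = direction
    if dr == 0 and dc != 0:  # horizontal
        for r in range(grid.shape[0]):
            yield grid[r], mask[r]
    elif dc == 0 and dr != 0:  # vertical
        for c in range(grid.shape[1]):
            yield grid[:, c], mask[:, c]
    elif dr * dc > 0:  # main-diagonal family (down-right)
        h, w = grid.shape
        for k in range(-(h - 1), w):
            yield np.diagonal(grid, k), np.diagonal(mask, k)
    else:  # anti-diagonal family (down-left)
        g, m = np.fliplr(grid), np.fliplr(mask)
        h, w = grid.shape
        for k in range(-(h - 1), w):
            yield np.diagonal(g, k), np.diagonal(m, k)


def _runs_in_line(values: np.ndarray, in_mask: np.ndarray) -> Iterable[Tuple[int, int]]:
    """Maximal (level, length) runs of a line, broken at mask boundaries."""
    level, length = 0, 0
    for v, ok in zip(values, in_mask):
        if not ok:
            if length:
                yield level, length
            level, length = 0, 0
        elif v == level:
            length += 1
        else:
            if length:
                yield level, length
            level, length = int(v), 1
    if length:
        yield level, length


def glrlm(
    roi: QuantizedROI, directions: Sequence[Tuple[int, int]] = DEFAULT_DIRECTIONS
) -> RunLengthMatrix:
    """Run-length matrix pooled over ``directions``.

    Along each direction every in-mask pixel belongs to exactly one
    maximal run, so the pixel-count identity
    sum_j sum_r r * R(j, r) = m * n_directions holds.
    """
    directions = tuple((int(dr), int(dc)) for dr, dc in directions)
    if not directions:
        raise ValueError("directions must be nonempty")
    L = roi.levels
    max_len = max(roi.grid.shape)
    counts = np.zeros((L, max_len), dtype=np.int64)
    for d in directions:
        if d == (0, 0):
            raise ValueError("directions must be nonzero")
        for values, in_mask in _mask_lines(roi.grid, roi.mask, d):
            for level, length in _runs_in_line(values, in_mask):
                counts[level - 1, length - 1] += 1
    # trim trailing all-zero run-length columns
    nonzero = np.nonzero(counts.sum(axis=0))[0]
    rmax = int(nonzero[-1]) + 1 if nonzero.size else 1
    return RunLengthMatrix(counts=counts[:, :rmax], directions=directions)


_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def glszm(roi: QuantizedROI, connectivity: int = 8) -> SizeZoneMatrix:
    """Size-zone matrix: connected-component zones per gray level.

    Every in-mask pixel belongs to exactly one zone, so
    sum_j sum_s s * Z(j, s) = m.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCTS[connectivity]
    L = roi.levels
    sizes_per_level: List[np.ndarray] = []
    smax = 1
    for level in range(1, L + 1):
        labeled, n = ndimage.label(roi.grid == level, structure=struct)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
            sizes = sizes.astype(np.int64)
            smax = max(smax, int(sizes.max()))
        else:
            sizes = np.zeros(0, dtype=np.int64)
        sizes_per_level.append(sizes)
    counts = np.zeros((L, smax), dtype=np.int64)
    for level, sizes in enumerate(sizes_per_level):
        for s in sizes:
            counts[level, s - 1] += 1
    return SizeZoneMatrix(counts=counts, connectivity=connectivity)


def mglszm(
    image: np.ndarray,
    mask: np.ndarray,
    level_set: Sequence[int] = DEFAULT_MGLSZM_LEVELS,
    connectivity: int = 8,
) -> MultiZoneMatrix:
    """Size-zone matrices of the same ROI at several quantization depths."""
    level_set = tuple(int(L) for L in level_set)
    if not level_set:
        raise ValueError("level_set must be nonempty")
    if any(L < 2 for L in level_set):
        raise ValueError("every quantization level must be >= 2")
    members = {
        L: glszm(quantize(image, mask, L), connectivity=connectivity) for L in level_set
    }
    return MultiZoneMatrix(members=members)
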