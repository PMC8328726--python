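"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit Python loops, direct
summation, BFS flood fill — and shares no code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def glcm_counts_oracle(grid, mask, offsets, symmetric, levels=None):
    """Pair enumeration: count (j, k) at each offset, both ends in-mask."""
    L = int(levels if levels is not None else grid[mask].max())
    h, w = grid.shape
    counts = np.zeros((L, L))
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    counts[grid[r, c] - 1, grid[r2, c2] - 1] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def glrlm_counts_oracle(grid, mask, directions, levels, max_len):
    """Run scanning: walk every maximal same-level run along each direction."""
    h, w = grid.shape
    counts = np.zeros((levels, max_len), dtype=int)
    for dr, dc in directions:
        # canonical orientation so each line family is scanned once
        if (dr, dc) < (0, 0) or (dr == 0 and dc < 0) or (dc == 0 and dr < 0):
            dr, dc = -dr, -dc
        for r in range(h):
            for c in range(w):
                pr, pc = r - dr, c - dc
                prev_same = (
                    0 <= pr < h
                    and 0 <= pc < w
                    and mask[pr, pc]
                    and mask[r, c]
                    and grid[pr, pc] == grid[r, c]
                )
                if not mask[r, c] or prev_same:
                    continue  # not the start of a run
                length = 0
                rr, cc = r, c
                while 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and grid[rr, cc] == grid[r, c]:
                    length += 1
                    rr, cc = rr + dr, cc + dc
                counts[grid[r, c] - 1, length - 1] += 1
    return counts


def glszm_counts_oracle(grid, mask, connectivity, levels, max_size):
    """Flood fill: BFS connected zones of equal level inside the mask."""
    h, w = grid.shape
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros((h, w), dtype=bool)
    counts = np.zeros((levels, max_size), dtype=int)
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            level = grid[r, c]
            size = 0
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                cr, cc = queue.popleft()
                size += 1
                for dr, dc in neigh:
                    nr, nc = cr + dr, cc + dc
                    if (
                        0 <= nr < h
                        and 0 <= nc < w
                        and mask[nr, nc]
                        and not seen[nr, nc]
                        and grid[nr, nc] == level
                    ):
                        seen[nr, nc] = True
                        queue.append((nr, nc))
            counts[level - 1, size - 1] += 1
    return counts


def first_order_oracle(values):
    """Direct summation of the four intensity statistics."""
    values = list(map(float, values))
    m = len(values)
    mean = sum(values) / m
    m2 = sum((v - mean) ** 2 for v in values) / m
    out = {"j_mean": mean, "j_variance": m2, "j_std": math.sqrt(m2)}
    if m2 > 0:
        m3 = sum((v - mean) ** 3 for v in values) / m
        m4 = sum((v - mean) ** 4 for v in values) / m
        out["j_skewness"] = m3 / m2**1.5
        out["j_kurtosis"] = m4 / m2**2 - 3.0
    else:
        out["j_skewness"] = float("nan")
        out["j_kurtosis"] = float("nan")
    return out


def glcm_features_oracle(P, log_base=2.0):
    """Direct double-sum evaluation of contrast, correlation, entropy."""
    L = P.shape[0]
    contrast = sum(
        (j - k) ** 2 * P[j - 1, k - 1] for j in range(1, L + 1) for k in range(1, L + 1)
    )
    p_y = [sum(P[j - 1, k - 1] for k in range(1, L + 1)) for j in range(1, L + 1)]
    p_z = [sum(P[j - 1, k - 1] for j in range(1, L + 1)) for k in range(1, L + 1)]
    phi_y = sum(j * p_y[j - 1] for j in range(1, L + 1))
    phi_z = sum(k * p_z[k - 1] for k in range(1, L + 1))
    lam_y = math.sqrt(sum((j - phi_y) ** 2 * p_y[j - 1] for j in range(1, L + 1)))
    lam_z = math.sqrt(sum((k - phi_z) ** 2 * p_z[k - 1] for k in range(1, L + 1)))
    cross = sum(j * k * P[j - 1, k - 1] for j in range(1, L + 1) for k in range(1, L + 1))
    corr = (cross - phi_y * phi_z) / (lam_y * lam_z) if lam_y * lam_z > 0 else float("nan")
    entropy = -sum(
        P[j - 1, k - 1] * math.log(P[j - 1, k - 1], log_base)
        for j in range(1, L + 1)
        for k in range(1, L + 1)
        if P[j - 1, k - 1] > 0
    )
    return {"t_contrast": contrast, "t_correlation": corr, "t_entropy": entropy}


def auc_oracle(scores, labels):
    """All-pairs counting: P(pos > neg) with ties worth 1/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_quantized_roi(rng, max_side=16, max_levels=8):
    """A random small quantized grid + mask with at least one valid pair."""
    from mritex.quantize import QuantizedROI

    while True:
        h = int(rng.integers(2, max_side + 1))
        w = int(rng.integers(2, max_side + 1))
        levels = int(rng.integers(2, max_levels + 1))
        mask = rng.random((h, w)) < 0.8
        if mask.sum() < 4:
            continue
        grid = np.zeros((h, w), dtype=np.int64)
        grid[mask] = rng.integers(1, levels + 1, size=int(mask.sum()))
        raw = grid[mask].astype(float)
        roi = QuantizedROI(levels=levels, grid=grid, mask=mask, raw_values=raw)
        # need one horizontally/vertically adjacent in-mask pair
        if (mask[:, 1:] & mask[:, :-1]).any() or (mask[1:] & mask[:-1]).any():
            return roi
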