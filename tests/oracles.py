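"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: dense 2D
convolution instead of separable 1D passes, BFS flood fill instead of
scipy labelling, and full enumeration of rank assignments for the
rank-sum test.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb

import numpy as np


def dense_smooth(image: np.ndarray, kernel_px: int) -> np.ndarray:
    """Dense 2D binomial convolution with symmetric (reflect) padding."""
    taps = np.array([1.0])
    for _ in range(kernel_px - 1):
        taps = np.convolve(taps, [1.0, 1.0])
    taps /= taps.sum()
    kernel = np.outer(taps, taps)
    k = kernel_px // 2
    padded = np.pad(image, k, mode="symmetric")
    out = np.zeros_like(image, dtype=float)
    for dy in range(kernel_px):
        for dx in range(kernel_px):
            out += kernel[dy, dx] * padded[
                dy : dy + image.shape[0], dx : dx + image.shape[1]
            ]
    return out


def bfs_components(mask: np.ndarray, min_area: int = 1) -> list[np.ndarray]:
    """8-connected components of a boolean mask by breadth-first search."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            comp = np.zeros_like(mask)
            queue = deque([(sy, sx)])
            seen[sy, sx] = True
            while queue:
                y, x = queue.popleft()
                comp[y, x] = True
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            queue.append((ny, nx))
            if comp.sum() >= min_area:
                comps.append(comp)
    return comps


def lamp1_oracle(
    stack,
    exclude_permeable: bool,
    kernel_px: int = 5,
    thresholds: dict | None = None,
    min_nucleus_area_px: int = 5,
    nucleus_denominator: str = "fitc",
    background_subtract: bool = True,
) -> tuple[float, int, float]:
    """Pixel-arithmetic re-derivation of the per-cell LAMP-1 pipeline.

    ``thresholds`` carries the threshold values the pipeline recorded in its
    gating provenance (threshold selection itself is configuration, the
    algebra is what is being checked). Returns (total, cell_count,
    per_cell).
    """
    thresholds = thresholds or {}
    fitc = dense_smooth(np.asarray(stack["FITC"], float), kernel_px)
    cy3 = dense_smooth(np.asarray(stack["Cy3"], float), kernel_px)
    fitc_mask = fitc > thresholds["fitc"]
    combined = fitc_mask.copy()
    if exclude_permeable:
        cy5 = dense_smooth(np.asarray(stack["Cy5"], float), kernel_px)
        if thresholds.get("cy5") is not None:
            combined &= ~(cy5 > thresholds["cy5"])
    background = 0.0
    if background_subtract:
        outside = cy3[~fitc_mask]
        background = float(np.median(outside)) if outside.size else 0.0
    total = max(float(np.sum(cy3[combined] - background)), 0.0)
    dapi = dense_smooth(np.asarray(stack["DAPI"], float), kernel_px)
    nuc_mask = dapi > thresholds["dapi"]
    comps = bfs_components(nuc_mask, min_area=min_nucleus_area_px)
    if nucleus_denominator == "fitc":
        count = sum(1 for c in comps if (c & fitc_mask).any())
    else:
        count = len(comps)
    return total, count, total / count if count else float("nan")


def ranksum_exact_oracle(a, b) -> float:
    """Two-sided exact rank-sum p by full enumeration, written from scratch.

    Midranks computed by sorting; statistic W = rank sum of sample a; the
    p-value counts assignments with |W' - mu| >= |W - mu|.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n, n_a = len(pooled), len(a)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    w = sum(ranks[:n_a])
    mu = n_a * (n + 1) / 2.0
    obs = abs(w - mu) - 1e-9
    hits = sum(
        1
        for idx in combinations(range(n), n_a)
        if abs(sum(ranks[i] for i in idx) - mu) >= obs
    )
    return hits / comb(n, n_a)
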