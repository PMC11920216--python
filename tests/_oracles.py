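"""Independent brute-force oracles used by the test suite.

Pure-Python pixel enumeration for square-union geometry (no numpy labeling,
no image pathway) and O(n^2) statistics (pairwise Mann-Whitney count,
exhaustive Youden scan, grouped jackknife variance).  Kept deliberately
naive: correctness over speed.
"""

from __future__ import annotations

import math
from collections import deque

NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
NEIGHBOURS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def union_pixels(squares: list[tuple[int, int, int]]) -> set[tuple[int, int]]:
    """All pixels covered by axis-aligned squares given as (row, col, side)."""
    pixels: set[tuple[int, int]] = set()
    for row, col, side in squares:
        for r in range(row, row + side):
            for c in range(col, col + side):
                pixels.add((r, c))
    return pixels


def clusters_8(pixels: set[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """Connected components of a pixel set under 8-connectivity (BFS)."""
    remaining = set(pixels)
    out = []
    while remaining:
        seed = next(iter(remaining))
        comp = {seed}
        remaining.remove(seed)
        queue = deque([seed])
        while queue:
            r, c = queue.popleft()
            for dr, dc in NEIGHBOURS_8:
                nb = (r + dr, c + dc)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        out.append(comp)
    return out


def edge_count_perimeter(component: set[tuple[int, int]]) -> int:
    """Pixel edges separating the component from everything else."""
    per = 0
    for r, c in component:
        for dr, dc in NEIGHBOURS_4:
            if (r + dr, c + dc) not in component:
                per += 1
    return per


def enumerate_parameters(
    squares: list[tuple[int, int, int]], center_xy: tuple[float, float]
) -> tuple[float, float, float]:
    """(SA, SP, ACD) by exhaustive enumeration, fully independent of the package."""
    pixels = union_pixels(squares)
    if not pixels:
        return 0.0, 0.0, 0.0
    comps = clusters_8(pixels)
    cx, cy = center_xy
    sa = float(len(pixels))
    sp = 0.0
    weighted = 0.0
    total = 0.0
    for comp in comps:
        sp += edge_count_perimeter(comp)
        rows = [p[0] for p in comp]
        cols = [p[1] for p in comp]
        mr = sum(rows) / len(comp)
        mc = sum(cols) / len(comp)
        dist = math.hypot(mc - cx, mr - cy)
        weighted += len(comp) * dist
        total += len(comp)
    return sa, sp, weighted / total


def mann_whitney_auc(pos_scores, neg_scores) -> float:
    """AUC by counting all positive/negative pairs (ties worth 1/2)."""
    wins = 0.0
    for x in pos_scores:
        for y in neg_scores:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def brute_force_youden(scores, labels, positive=1):
    """Best (threshold, J) by scanning every candidate threshold with loops."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    distinct = sorted(set(scores))
    candidates = [float("-inf")]
    candidates += [(a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])]
    candidates += [float("inf")]
    best_thr, best_j = None, -2.0
    for thr in candidates:
        sens = sum(1 for s in pos if s > thr) / len(pos)
        spec = sum(1 for s in neg if s <= thr) / len(neg)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_thr, best_j = thr, j
    return best_thr, best_j


def jackknife_delta_auc_variance(scores_a, scores_b, labels, positive=1) -> float:
    """Grouped leave-one-out jackknife variance of AUC_a - AUC_b."""
    n = len(labels)

    def delta(idx):
        pa = [scores_a[i] for i in idx if labels[i] == positive]
        na = [scores_a[i] for i in idx if labels[i] != positive]
        pb = [scores_b[i] for i in idx if labels[i] == positive]
        nb = [scores_b[i] for i in idx if labels[i] != positive]
        return mann_whitney_auc(pa, na) - mann_whitney_auc(pb, nb)

    var = 0.0
    for lab_is_pos in (True, False):
        grp = [i for i in range(n) if (labels[i] == positive) == lab_is_pos]
        m = len(grp)
        loo = [delta([j for j in range(n) if j != i]) for i in grp]
        mean = sum(loo) / m
        var += (m - 1) / m * sum((v - mean) ** 2 for v in loo)
    return var
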