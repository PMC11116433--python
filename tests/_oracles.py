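"""Independent reference implementations used only to check the package.

Each oracle computes its quantity straight from the definition (pairwise
containment, pixel enumeration, cluster-average recomputation) without
sharing code paths with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def level_oracle(intervals: list[tuple[int, int]]) -> list[int]:
    """Longest strict-containment chain, from the O(n^2) definition.

    level(T) = 1 + max over strict containers C of level(C), via memoized
    recursion on the explicit containment relation.
    """
    n = len(intervals)
    s = np.array([iv[0] for iv in intervals])
    e = np.array([iv[1] for iv in intervals])
    contains = (
        (s[:, None] <= s[None, :])
        & (e[:, None] >= e[None, :])
        & ((s[:, None] != s[None, :]) | (e[:, None] != e[None, :]))
    )  # contains[c, t]: c strictly contains t
    memo: dict[int, int] = {}

    def level(t: int) -> int:
        if t not in memo:
            memo[t] = 0  # cycle guard; containment is acyclic
            parents = np.flatnonzero(contains[:, t])
            memo[t] = 1 + max((level(p) for p in parents), default=0)
        return memo[t]

    return [level(t) for t in range(n)]


def union_length_oracle(intervals: list[tuple[int, int]]) -> int:
    """Union length by marking individual units on a dense line."""
    if not intervals:
        return 0
    hi = max(e for _, e in intervals)
    covered = np.zeros(hi, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    return int(covered.sum())


def raster_oracle(intervals_levels, n_bins: int, resolution: int) -> np.ndarray:
    """Pixel-by-pixel enumeration: 20 x max level of a domain containing
    both bins."""
    out = np.zeros((n_bins, n_bins), dtype=np.int64)
    for i in range(n_bins):
        for j in range(n_bins):
            best = 0
            for s, e, lvl in intervals_levels:
                sb, eb = s // resolution, e // resolution
                if sb <= i < eb and sb <= j < eb:
                    best = max(best, lvl)
            out[i, j] = 20 * best
    return out


def upgma_oracle(d: np.ndarray):
    """Average linkage recomputed from the original distances at every step.

    Clusters are leaf sets; at each step the pair with the smallest mean
    pairwise leaf distance merges (ties to the lexicographically smallest
    sorted leaf pair).  Returns (merge partitions, heights).
    """
    n = d.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    merges = []
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                dist = np.mean([d[i, j] for i in ca for j in cb])
                key = (dist, min(ca | cb), sorted(ca | cb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        heights.append(float(np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])))
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges, heights


def body_resample_oracle(values: np.ndarray, n_out: int) -> np.ndarray:
    """Length-weighted resampling by explicit sub-unit integration."""
    n_src = len(values)
    fine = np.repeat(np.asarray(values, dtype=float), n_out)  # n_src*n_out units
    return fine.reshape(n_out, n_src).mean(axis=1)
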