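"""Similarity metrics between TAD hierarchies, and caller clustering.

Hier_SSIM compares two hierarchies as images.  Each hierarchy is first
rasterized onto a matrix the size of the Hi-C heatmap: pixel (i, j) holds
20 times the level of the innermost domain containing both bins i and j
(0 where no domain covers the pair).  An 8-Mb window then slides along the
diagonal, the structural similarity index (SSIM) is computed on each pair
of windows, and the mean over windows is Hier_SSIM.  The factor 20 spreads
adjacent levels far apart on the intensity scale so that SSIM's contrast
and structure terms respond to level disagreements and not only to domain
footprints.

The overlap ratio treats each hierarchy as a coding tree — the set of
distinct domain intervals at all levels — and scores the Dice overlap of
the two node sets under an endpoint tolerance.

Average-linkage (UPGMA) clustering on 1 - similarity groups callers whose
hierarchies resemble each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import ParameterError, ResolutionError, ShapeError, SymmetryError
from .hierarchy import TadHierarchy

#: Pixel intensity per hierarchy level in the raster.
LEVEL_MULTIPLIER = 20
#: Diagonal sliding-window size for Hier_SSIM, in bp.
DEFAULT_WINDOW_BP = 8_000_000


@dataclass
class LevelRaster:
    """Square symmetric image of a hierarchy: pixel = 20 x innermost level."""

    values: np.ndarray
    resolution: int
    multiplier: int = LEVEL_MULTIPLIER

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError(f"raster must be square, got {v.shape}")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SsimParams:
    """SSIM stabilisation constants and patch geometry.

    ``data_range`` (L) is the nominal dynamic range of the images;
    C1 = (K1 L)^2 and C2 = (K2 L)^2 guard the luminance and
    contrast/structure terms against division by near-zero moments.
    """

    data_range: float
    k1: float = 0.01
    k2: float = 0.03
    local_patch_side: int = 7

    def __post_init__(self):
        if self.local_patch_side % 2 == 0 or self.local_patch_side < 3:
            raise ParameterError("local_patch_side must be odd and >= 3")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2


def rasterize_hierarchy(h: TadHierarchy, n_bins: int | None = None) -> LevelRaster:
    """Map a levelled hierarchy onto a heatmap-sized matrix.

    Pixel (i, j) = multiplier x max{level(T) : T contains bins i and j},
    or 0 when no domain contains both.  The innermost (highest-level)
    common domain wins, so nested structure shows as nested brighter
    squares on the diagonal.
    """
    if n_bins is None:
        n_bins = h.n_bins
    elif h.chrom_length is not None and n_bins != h.n_bins:
        raise ShapeError(
            f"n_bins {n_bins} inconsistent with chrom_length/resolution "
            f"({h.n_bins} bins)"
        )
    raster = np.zeros((n_bins, n_bins), dtype=np.int64)
    res = h.resolution
    for r in sorted(h.records, key=lambda r: r.level or 0):
        if r.level is None:
            raise ParameterError("levels are unset; run assign_tad_levels first")
        sb, eb = r.start // res, r.end // res
        if eb > n_bins:
            raise ShapeError(f"record [{r.start}, {r.end}) exceeds raster extent")
        block = raster[sb:eb, sb:eb]
        np.maximum(block, LEVEL_MULTIPLIER * r.level, out=block)
    return LevelRaster(values=raster, resolution=res)


def ssim_window(
    x: np.ndarray, y: np.ndarray, params: SsimParams
) -> float:
    """Mean SSIM over all fully interior local patches of two images.

    Patches are uniform (unweighted) squares of side ``local_patch_side``;
    per-patch means, variances and covariance use sample statistics.
    Identical inputs score exactly 1 irrespective of the data range.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch {x.shape} vs {y.shape}")
    if np.array_equal(x, y):
        return 1.0
    if params.data_range <= 0:
        raise ParameterError("data_range must be positive for distinct inputs")
    w = params.local_patch_side
    if min(x.shape) < w:
        raise ShapeError(f"images of shape {x.shape} smaller than patch side {w}")
    np_pix = w * w
    cov_norm = np_pix / (np_pix - 1)  # sample (co)variance
    filt = lambda a: uniform_filter(a, size=w)
    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1, c2 = params.c1, params.c2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    pad = (w - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def hier_ssim(
    a: LevelRaster,
    b: LevelRaster,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bins: int | None = None,
    data_range: float | None = None,
    params: SsimParams | None = None,
) -> float:
    """Mean SSIM over diagonal windows of two level rasters.

    Windows are the W x W diagonal blocks starting at bins 0, step,
    2*step, ... where W = window_bp / resolution; a trailing block shorter
    than W is dropped.  The data range defaults to ``multiplier x`` the
    maximum level observed in either raster (falling back to one level's
    worth when both rasters are empty), and can be pinned with
    ``data_range`` for cross-comparison reproducibility.
    """
    if a.values.shape != b.values.shape:
        raise ShapeError(
            f"raster shapes differ: {a.values.shape} vs {b.values.shape}"
        )
    if a.resolution != b.resolution:
        raise ResolutionError("rasters have different resolutions")
    if window_bp % a.resolution:
        raise ParameterError(
            f"window {window_bp} bp is not a multiple of resolution {a.resolution}"
        )
    w_bins = window_bp // a.resolution
    n = a.n_bins
    if n < w_bins:
        raise ParameterError(
            f"raster of {n} bins shorter than one {w_bins}-bin window"
        )
    if step_bins is None:
        step_bins = w_bins
    if step_bins <= 0:
        raise ParameterError("step_bins must be positive")
    if data_range is None:
        observed = max(float(a.values.max()), float(b.values.max()))
        data_range = observed if observed > 0 else float(a.multiplier)
    p = params or SsimParams(data_range=data_range)
    scores = []
    for start in range(0, n - w_bins + 1, step_bins):
        sl = slice(start, start + w_bins)
        scores.append(ssim_window(a.values[sl, sl], b.values[sl, sl], p))
    return float(np.mean(scores))


def _coding_tree_nodes(h: TadHierarchy) -> list[tuple[int, int]]:
    res = h.resolution
    return sorted({(r.start // res, r.end // res) for r in h.records})


def overlap_ratio(
    a: TadHierarchy, b: TadHierarchy, match_tolerance_bins: int = 0
) -> float:
    """Dice overlap of the two coding trees' node sets.

    Nodes are the distinct (start, end) intervals at all levels, in bins.
    An A-node matches a B-node when both endpoints differ by at most the
    tolerance; matching is greedy one-to-one by smallest total endpoint
    distance.  OR = 2 |matches| / (|A| + |B|); two empty trees count as
    fully overlapping.
    """
    if a.resolution != b.resolution:
        raise ResolutionError(
            f"resolutions differ: {a.resolution} vs {b.resolution}"
        )
    if match_tolerance_bins < 0:
        raise ParameterError("tolerance must be nonnegative")
    na, nb = _coding_tree_nodes(a), _coding_tree_nodes(b)
    if not na and not nb:
        return 1.0
    if not na or not nb:
        return 0.0
    tol = match_tolerance_bins
    candidates = []
    for i, (sa, ea) in enumerate(na):
        for j, (sb, eb) in enumerate(nb):
            ds, de = abs(sa - sb), abs(ea - eb)
            if ds <= tol and de <= tol:
                candidates.append((ds + de, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = 0
    for _, i, j in candidates:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            matches += 1
    return 2.0 * matches / (len(na) + len(nb))


@dataclass
class SimilarityMatrix:
    """Caller x caller pairwise similarities with unit diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ShapeError("similarity matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9, rtol=0):
            raise SymmetryError("similarity matrix is not symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 1.0)
        self.values = v


def pairwise_similarity(
    hierarchies: dict[str, TadHierarchy],
    metric: str = "hier_ssim",
    **kwargs,
) -> SimilarityMatrix:
    """All-pairs similarity under ``hier_ssim`` (on rasters) or
    ``overlap_ratio``."""
    labels = list(hierarchies)
    n = len(labels)
    vals = np.eye(n)
    if metric == "hier_ssim":
        rasters = {k: rasterize_hierarchy(v) for k, v in hierarchies.items()}
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = hier_ssim(
                    rasters[labels[i]], rasters[labels[j]], **kwargs
                )
    elif metric == "overlap_ratio":
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = overlap_ratio(
                    hierarchies[labels[i]], hierarchies[labels[j]], **kwargs
                )
    else:
        raise ParameterError(f"unknown metric {metric!r}")
    return SimilarityMatrix(labels=labels, values=vals)


@dataclass
class Dendrogram:
    """UPGMA merge tree in scipy linkage form.

    ``linkage`` rows are (cluster_a, cluster_b, height, size); leaves are
    0..n-1 and merge k creates cluster n+k.
    """

    labels: list[str]
    linkage: np.ndarray = field(repr=False)

    def newick(self) -> str:
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (ia, ib, h, _) in enumerate(self.linkage):
            ia, ib = int(ia), int(ib)
            la = h - height[ia]
            lb = h - height[ib]
            node[n + k] = f"({node[ia]}:{la:g},{node[ib]}:{lb:g})"
            height[n + k] = h
        return node[n + len(self.linkage) - 1] + ";"


def average_linkage_cluster(s: SimilarityMatrix) -> Dendrogram:
    """Agglomerative clustering on distance 1 - similarity with unweighted
    average linkage (UPGMA).

    At each step the pair of clusters with the smallest average pairwise
    distance merges; ties break toward the pair whose smallest original
    leaf indices come first, making the merge order deterministic.
    """
    n = len(s.labels)
    if n < 2:
        raise ParameterError("need at least two items to cluster")
    d = 1.0 - s.values
    # active cluster id -> (size, smallest leaf, member leaf for distance rows)
    size = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for (i, j), dij in dist.items():
            key = (dij, min(rep[i], rep[j]), max(rep[i], rep[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = dist[(i, j)]
        linkage[step] = (i, j, h, size[i] + size[j])
        new = next_id
        next_id += 1
        for k in active - {i, j}:
            a = dist[(min(i, k), max(i, k))]
            b = dist[(min(j, k), max(j, k))]
            dist[(k, new)] = (size[i] * a + size[j] * b) / (size[i] + size[j])
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        active -= {i, j}
        active.add(new)
        size[new] = size[i] + size[j]
        rep[new] = min(rep[i], rep[j])
    return Dendrogram(labels=list(s.labels), linkage=linkage)
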