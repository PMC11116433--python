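"""Synthetic nested-TAD fixtures: ground-truth hierarchies, block-enriched
contact maps, and controlled perturbations.

The generator emulates the "domains within domains" organisation of
chromatin: level-1 TADs tile most of a chromosome, each may recursively
split into non-overlapping child subTADs, and the contact map shows each
domain as a block of enriched contacts on top of a power-law distance
decay.  Expected counts are

    mu(i, j) = A * (|i - j| + 1) ** (-alpha) * beta ** depth(i, j)

where ``depth(i, j)`` counts the domains containing both bins, so
enrichment compounds multiplicatively with nesting; observed counts are
Poisson draws, symmetrized.  Defaults give a 24-Mb chromosome at 10-kb
bins with three levels of structure — deep enough for level-recovery and
similarity-degradation experiments, small enough to simulate in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .hierarchy import (
    DEFAULT_MAX_TAD_BP,
    DEFAULT_MIN_TAD_BP,
    TadHierarchy,
    TadRecord,
    assign_tad_levels,
    validate_hierarchy,
)
from .matrix import ContactMatrix


@dataclass
class SimParams:
    """Knobs of the nested-TAD simulator.

    ``split_probability`` is the chance a domain at any level spawns
    children (until ``max_depth``); ``child_range`` the inclusive range of
    child counts per split; ``gap_fraction`` the chance of a gap between
    consecutive level-1 TADs; ``decay_exponent`` (alpha) the power-law
    distance decay; ``enrichment`` (beta) the per-level contact boost,
    > 1 for detectable structure; ``background`` (A) the count scale at
    distance 0 outside any domain.
    """

    chrom_length: int = 24_000_000
    resolution: int = 10_000
    max_depth: int = 3
    split_probability: float = 0.7
    child_range: tuple[int, int] = (2, 4)
    gap_fraction: float = 0.1
    decay_exponent: float = 1.0
    enrichment: float = 1.6
    background: float = 10.0
    min_tad_bp: int = DEFAULT_MIN_TAD_BP
    max_tad_bp: int = DEFAULT_MAX_TAD_BP
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ParameterError("max_depth must be >= 1")
        if not 0 <= self.split_probability <= 1:
            raise ParameterError("split_probability must be in [0, 1]")
        if not 0 <= self.gap_fraction <= 1:
            raise ParameterError("gap_fraction must be in [0, 1]")
        if self.enrichment <= 1:
            raise ParameterError("enrichment must exceed 1 for visible structure")


#: Minimum child size in bins; below this a split is not attempted.
_MIN_CHILD_BINS = 3


def _split_segment(
    rng: np.random.Generator,
    sb: int,
    eb: int,
    depth: int,
    p: SimParams,
    out: list[tuple[int, int, int]],
) -> None:
    out.append((sb, eb, depth))
    if depth >= p.max_depth:
        return
    if rng.random() >= p.split_probability:
        return
    n_bins = eb - sb
    kmax = min(p.child_range[1], n_bins // _MIN_CHILD_BINS)
    if kmax < max(2, p.child_range[0]):
        return
    k = int(rng.integers(max(2, p.child_range[0]), kmax + 1))
    # cut points giving k contiguous children of >= _MIN_CHILD_BINS bins
    inner = rng.choice(
        np.arange(1, n_bins // _MIN_CHILD_BINS), size=k - 1, replace=False
    )
    cuts = np.sort(inner) * _MIN_CHILD_BINS
    slack = n_bins - (n_bins // _MIN_CHILD_BINS) * _MIN_CHILD_BINS
    edges = [0, *cuts.tolist(), n_bins - slack] if slack else [0, *cuts.tolist(), n_bins]
    for a, b in zip(edges[:-1], edges[1:]):
        _split_segment(rng, sb + a, sb + b, depth + 1, p, out)


def simulate_hierarchy(p: SimParams) -> TadHierarchy:
    """Draw a ground-truth nested hierarchy.

    Level-1 TADs tile the chromosome with log-uniform sizes in
    [min_tad_bp, max_tad_bp] separated by occasional gaps; each domain
    recursively splits into non-overlapping children strictly inside it.
    The recorded levels equal what :func:`assign_tad_levels` recomputes
    from the bare intervals.
    """
    if p.chrom_length % p.resolution:
        raise ParameterError("resolution must divide chrom_length")
    rng = np.random.default_rng(p.seed)
    res = p.resolution
    n_bins = p.chrom_length // res
    min_bins = max(_MIN_CHILD_BINS, p.min_tad_bp // res)
    max_bins = max(min_bins, p.max_tad_bp // res)
    segments: list[tuple[int, int, int]] = []
    pos = 0
    while pos < n_bins:
        if rng.random() < p.gap_fraction:
            pos += int(rng.integers(1, 6))
        size = int(
            np.round(
                np.exp(rng.uniform(np.log(min_bins), np.log(max_bins)))
            )
        )
        size = min(size, n_bins - pos)
        if size < min_bins:
            break
        _split_segment(rng, pos, pos + size, 1, p, segments)
        pos += size
    records = [
        TadRecord(start=sb * res, end=eb * res, level=depth)
        for sb, eb, depth in segments
    ]
    h = TadHierarchy(
        chrom="chrSim", resolution=res, chrom_length=p.chrom_length,
        records=records,
    )
    return validate_hierarchy(h)


def domain_depth_matrix(h: TadHierarchy, n_bins: int | None = None) -> np.ndarray:
    """depth(i, j): number of domains containing both bins i and j."""
    if n_bins is None:
        n_bins = h.n_bins
    depth = np.zeros((n_bins, n_bins), dtype=np.int64)
    res = h.resolution
    for r in h.records:
        sb, eb = r.start // res, r.end // res
        depth[sb:eb, sb:eb] += 1
    return depth


def simulate_contact_matrix(h: TadHierarchy, p: SimParams) -> ContactMatrix:
    """Poisson contact map with power-law decay and block enrichment.

    mu(i, j) = background * (|i-j| + 1)^(-decay_exponent)
               * enrichment^depth(i, j); the upper triangle is drawn once
    and mirrored so the output is exactly symmetric and integer.
    """
    rng = np.random.default_rng(p.seed)
    n = h.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    mu = p.background * (dist + 1.0) ** (-p.decay_exponent)
    mu *= p.enrichment ** domain_depth_matrix(h, n)
    iu, ju = np.triu_indices(n)
    draws = rng.poisson(mu[iu, ju])
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu, ju] = draws
    counts[ju, iu] = draws
    return ContactMatrix(matrix=counts, resolution=h.resolution, chrom=h.chrom,
                         chrom_length=h.chrom_length)


def perturb_hierarchy(
    h: TadHierarchy,
    shift_bins: int = 0,
    drop_prob: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> TadHierarchy:
    """Corrupt a hierarchy for robustness experiments.

    Each record's start and end are independently shifted by a uniform
    integer in [-shift_bins, +shift_bins] bins (clamped to keep the
    interval at least one bin long and on the chromosome), and each record
    is dropped with probability ``drop_prob``.  Levels are re-assigned on
    the survivors.
    """
    if shift_bins < 0 or not 0 <= drop_prob <= 1:
        raise ParameterError("shift_bins >= 0 and drop_prob in [0, 1] required")
    rng = np.random.default_rng(seed)
    res = h.resolution
    n_bins = h.n_bins if h.chrom_length is not None else None
    kept: list[TadRecord] = []
    for r in h.records:
        if drop_prob and rng.random() < drop_prob:
            continue
        sb, eb = r.start // res, r.end // res
        if shift_bins:
            sb = sb + int(rng.integers(-shift_bins, shift_bins + 1))
            eb = eb + int(rng.integers(-shift_bins, shift_bins + 1))
        sb = max(sb, 0)
        if n_bins is not None:
            eb = min(eb, n_bins)
        eb = max(eb, sb + 1)
        if n_bins is not None and eb > n_bins:
            eb = n_bins
            sb = min(sb, eb - 1)
        kept.append(TadRecord(start=sb * res, end=eb * res, chrom=r.chrom))
    out = validate_hierarchy(replace(h, records=kept))
    return assign_tad_levels(out)
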