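"""Canonical model for hierarchical TAD calls.

A *TAD hierarchy* is a set of genomic intervals ("domains") on one chromosome
at a fixed bin resolution.  Domains may nest: a level-1 TAD is one contained
in no larger TAD, and the level increases by one for each additional layer of
strict containment.  A *boundary* is a position where domains start or end;
its level is the larger of the number of domains starting there and the
number ending there, so a position shared by several nested domains on one
side gets a correspondingly high level.

Coordinates are 0-based half-open base pairs snapped to the resolution grid,
which makes bin conversion exact: ``bin = coordinate // resolution``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import BoundsError, GridError, IntervalError, ParameterError

#: Default size filter: domains shorter than 30 kb or longer than 2 Mb are
#: outside the scale at which TADs are defined and are removed.
DEFAULT_MIN_TAD_BP = 30_000
DEFAULT_MAX_TAD_BP = 2_000_000


@dataclass(frozen=True)
class TadRecord:
    """One domain interval ``[start, end)`` in bp with an optional level."""

    start: int
    end: int
    level: int | None = None
    chrom: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BoundaryRecord:
    """A boundary position with its level (max of #starts, #ends there)."""

    position: int
    level: int
    chrom: str | None = None


@dataclass
class TadHierarchy:
    """A set of (possibly nested) domains on one chromosome.

    Parameters
    ----------
    chrom :
        Chromosome identifier, informational only.
    resolution :
        Bin size in bp; every coordinate must be a multiple of it.
    chrom_length :
        Chromosome length in bp; ``None`` disables bounds checking and
        coverage computation.
    records :
        The domain intervals.
    """

    chrom: str
    resolution: int
    chrom_length: int | None = None
    records: list[TadRecord] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        if self.chrom_length is None:
            raise ParameterError("chrom_length is unset")
        return -(-self.chrom_length // self.resolution)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class LevelDistribution:
    """Per-level counts and percentages for domains and boundaries."""

    tad_counts: dict[int, int]
    tad_percentages: dict[int, float]
    boundary_counts: dict[int, int]
    boundary_percentages: dict[int, float]


def _check_record(r: TadRecord, resolution: int, chrom_length: int | None) -> None:
    if r.end <= r.start:
        raise IntervalError(f"interval [{r.start}, {r.end}) has end <= start")
    if r.start < 0:
        raise BoundsError(f"negative start {r.start}")
    if r.start % resolution or r.end % resolution:
        raise GridError(
            f"interval [{r.start}, {r.end}) is off the {resolution}-bp grid"
        )
    if chrom_length is not None and r.end > chrom_length:
        raise BoundsError(
            f"interval [{r.start}, {r.end}) exceeds chromosome length {chrom_length}"
        )


def validate_hierarchy(h: TadHierarchy) -> TadHierarchy:
    """Return a canonical copy: coordinates checked, duplicates removed,
    records sorted by (start ascending, length descending).

    Duplicate ``(start, end)`` pairs keep their first occurrence, so a level
    already attached to the first copy survives.
    """
    if h.resolution <= 0:
        raise ParameterError(f"resolution must be positive, got {h.resolution}")
    seen: dict[tuple[int, int], TadRecord] = {}
    for r in h.records:
        _check_record(r, h.resolution, h.chrom_length)
        seen.setdefault((r.start, r.end), r)
    ordered = sorted(seen.values(), key=lambda r: (r.start, -r.length))
    return replace(h, records=ordered)


def assign_tad_levels(h: TadHierarchy) -> TadHierarchy:
    """Assign every record its nesting level.

    level(T) = 1 + length of the longest chain of records strictly
    containing T.  On a properly nested set this is simply one plus the
    number of containers; on callers that emit partially overlapping
    domains it stays well defined because partial overlaps contribute
    nothing to containment.

    Runs a size-descending dynamic program: a strict container is always
    strictly longer (duplicates are removed beforehand), so processing
    records longest-first means every potential container is already
    levelled when its contents are reached.
    """
    if not h.records:
        return replace(h, records=[])
    starts = np.array([r.start for r in h.records], dtype=np.int64)
    ends = np.array([r.end for r in h.records], dtype=np.int64)
    order = np.lexsort((starts, -(ends - starts)))  # length desc, start asc
    s, e = starts[order], ends[order]
    levels = np.ones(len(s), dtype=np.int64)
    for i in range(1, len(s)):
        contains = (s[:i] <= s[i]) & (e[:i] >= e[i])
        if contains.any():
            levels[i] = 1 + levels[:i][contains].max()
    out = [None] * len(h.records)
    for rank, orig in enumerate(order):
        r = h.records[orig]
        out[orig] = replace(r, level=int(levels[rank]))
    return replace(h, records=sorted(out, key=lambda r: (r.start, -r.length)))


def assign_boundary_levels(h: TadHierarchy) -> list[BoundaryRecord]:
    """One boundary per distinct start/end position.

    The level is the maximum multiplicity of the position in the start
    column versus the end column — a boundary closing three nested domains
    at once is a level-3 boundary even if only one domain starts there.
    """
    starts = Counter(r.start for r in h.records)
    ends = Counter(r.end for r in h.records)
    return [
        BoundaryRecord(position=p, level=max(starts.get(p, 0), ends.get(p, 0)),
                       chrom=h.chrom)
        for p in sorted(set(starts) | set(ends))
    ]


def filter_by_size(
    h: TadHierarchy,
    min_len: int = DEFAULT_MIN_TAD_BP,
    max_len: int = DEFAULT_MAX_TAD_BP,
) -> TadHierarchy:
    """Keep records with min_len <= length <= max_len (inclusive bounds) and
    re-assign levels on the survivors, since removing an outer domain can
    promote its children."""
    if min_len > max_len:
        raise ParameterError(f"min_len {min_len} > max_len {max_len}")
    kept = [r for r in h.records if min_len <= r.length <= max_len]
    return assign_tad_levels(replace(h, records=kept))


def genomic_coverage(h: TadHierarchy) -> float:
    """Fraction of the chromosome covered by the union of all domains.

    Equivalently one minus the total length of the complement segments over
    the chromosome length; nesting does not double-count.
    """
    if not h.chrom_length:
        raise ParameterError("chrom_length must be set and positive")
    covered = 0
    last_end = None
    for r in sorted(h.records, key=lambda r: (r.start, r.end)):
        lo = r.start if last_end is None else max(r.start, last_end)
        if r.end > lo:
            covered += r.end - lo
            last_end = r.end
        elif last_end is None:
            last_end = r.end
    return covered / h.chrom_length


def mean_genomic_coverage(hierarchies: Iterable[TadHierarchy]) -> float:
    """Arithmetic mean of per-sample coverages (multi-cell-type aggregate)."""
    vals = [genomic_coverage(h) for h in hierarchies]
    if not vals:
        raise ParameterError("no hierarchies given")
    return float(np.mean(vals))


def level_distribution(
    h: TadHierarchy, boundaries: Sequence[BoundaryRecord] | None = None
) -> LevelDistribution:
    """Counts and percentages per level for domains and for boundaries."""
    if boundaries is None:
        boundaries = assign_boundary_levels(h)
    tad_counts = Counter(r.level for r in h.records)
    if None in tad_counts:
        raise ParameterError("levels are unset; run assign_tad_levels first")
    b_counts = Counter(b.level for b in boundaries)

    def pct(counts: Counter) -> dict[int, float]:
        total = sum(counts.values())
        return {k: 100.0 * v / total for k, v in sorted(counts.items())} if total else {}

    return LevelDistribution(
        tad_counts=dict(sorted(tad_counts.items())),
        tad_percentages=pct(tad_counts),
        boundary_counts=dict(sorted(b_counts.items())),
        boundary_percentages=pct(b_counts),
    )
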