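"""Readers and writers for the text formats hierarchical TAD callers and
Hi-C pipelines exchange.

TAD callers disagree on almost everything about their output files: bp vs
bin units, 0- vs 1-based bins, an explicit level column vs one file per
level.  :class:`CallDialect` captures those four axes; every input is
normalized to the canonical form (0-based half-open bp, explicit level) on
the way in.  Contact matrices come as 3-column sparse text, either bin
indices ("i j count") or genomic coordinates in the first two columns
("Rao format"), or as whitespace-separated dense matrices.  Signal tracks
are bedGraph, resampled to per-bin values by length-weighted averaging.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    BoundsError,
    ParameterError,
    ParseError,
    ShapeError,
    SymmetryError,
)
from .hierarchy import TadHierarchy, TadRecord
from .matrix import ContactMatrix


@dataclass(frozen=True)
class CallDialect:
    """How a caller's output file encodes intervals.

    ``unit``
        "bp" (genomic coordinates, half-open) or "bin" (bin indices with an
        *inclusive* end bin, the common caller convention).
    ``bin_base``
        First bin index, 0 or 1; only meaningful for the bin unit.
    ``has_level``
        Whether a third/fourth numeric column carries the level.
    ``per_level_files``
        One file per level; the level is the file's rank in the input list,
        not a column.
    """

    unit: str = "bp"
    bin_base: int = 0
    has_level: bool = True
    per_level_files: bool = False

    def __post_init__(self):
        if self.unit not in ("bp", "bin"):
            raise ParameterError(f"unknown unit {self.unit!r}")
        if self.bin_base not in (0, 1):
            raise ParameterError(f"bin_base must be 0 or 1, got {self.bin_base}")
        if self.per_level_files and self.has_level:
            raise ParameterError(
                "per_level_files derives levels from file identity; "
                "has_level must be False"
            )


#: Canonical dialect: bp units, explicit level column.
CANONICAL_DIALECT = CallDialect(unit="bp", bin_base=0, has_level=True)


@dataclass
class SignalTrack:
    """One value per bin for a chromosome; missing data is 0."""

    chrom: str
    resolution: int
    chrom_length: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = -(-self.chrom_length // self.resolution)
        if self.values.shape != (n,):
            raise ShapeError(
                f"track needs {n} bins for chrom_length {self.chrom_length} "
                f"at {self.resolution} bp, got {self.values.shape}"
            )

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def _data_lines(path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split()


def _int_field(tok: str, lineno: int, what: str) -> int:
    try:
        return int(tok)
    except ValueError:
        try:
            f = float(tok)
        except ValueError:
            raise ParseError(f"non-numeric {what} {tok!r}", lineno) from None
        if f != int(f):
            raise ParseError(f"non-integer {what} {tok!r}", lineno) from None
        return int(f)


def read_tad_calls(
    paths: str | Path | Sequence[str | Path],
    dialect: CallDialect = CANONICAL_DIALECT,
    *,
    resolution: int,
    chrom_length: int | None = None,
    chrom: str = "chr",
) -> TadHierarchy:
    """Read one or more TAD-call files into an (unvalidated) hierarchy.

    Numeric columns are ``start end [level]``; an optional leading
    non-numeric column is taken as the chromosome name.  Bin units convert
    via ``start_bp = (start_bin - bin_base) * resolution`` and
    ``end_bp = (end_bin - bin_base + 1) * resolution`` (inclusive end bins).
    For per-level dialects pass the files in level order; level = file rank
    (1-based).  Run :func:`~tadhier.hierarchy.validate_hierarchy` (and
    :func:`~tadhier.hierarchy.assign_tad_levels` if levels are absent) on
    the result.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if dialect.per_level_files and len(paths) < 1:
        raise ParameterError("per-level dialect needs at least one file")
    records: list[TadRecord] = []
    for rank, path in enumerate(paths, 1):
        for lineno, toks in _data_lines(path):
            file_chrom = None
            try:
                float(toks[0])
            except ValueError:
                file_chrom = toks[0]
                toks = toks[1:]
            need = 3 if dialect.has_level else 2
            if len(toks) < need:
                raise ParseError(
                    f"expected at least {need} numeric columns, got {len(toks)}",
                    lineno,
                )
            start = _int_field(toks[0], lineno, "start")
            end = _int_field(toks[1], lineno, "end")
            if dialect.unit == "bin":
                if min(start, end) < dialect.bin_base:
                    raise BoundsError(
                        f"line {lineno}: bin index below bin_base {dialect.bin_base}"
                    )
                start = (start - dialect.bin_base) * resolution
                end = (end - dialect.bin_base + 1) * resolution
            if start < 0 or end < 0:
                raise BoundsError(f"line {lineno}: negative coordinate")
            if dialect.per_level_files:
                level: int | None = rank
            elif dialect.has_level:
                level = _int_field(toks[2], lineno, "level")
            else:
                level = None
            records.append(
                TadRecord(start=start, end=end, level=level,
                          chrom=file_chrom or chrom)
            )
    return TadHierarchy(
        chrom=chrom, resolution=resolution, chrom_length=chrom_length,
        records=records,
    )


def write_tad_calls(h: TadHierarchy, path: str | Path, header: str | None = None) -> None:
    """Write the canonical 4-column file (chrom, start, end, level), sorted
    by (start, length descending); round-trips exactly through
    :func:`read_tad_calls`."""
    ordered = sorted(h.records, key=lambda r: (r.start, -r.length))
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for r in ordered:
            lvl = "" if r.level is None else r.level
            fh.write(f"{r.chrom or h.chrom}\t{r.start}\t{r.end}\t{lvl}\n".replace("\t\n", "\n"))


def write_boundaries(boundaries, resolution: int, path: str | Path,
                     header: str | None = None) -> None:
    """BED3-compatible boundary file: chrom, position, position+resolution,
    level."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for b in boundaries:
            fh.write(f"{b.chrom or 'chr'}\t{b.position}\t{b.position + resolution}\t{b.level}\n")


def read_sparse_contacts(
    path: str | Path,
    dialect: str = "bin_pairs",
    *,
    resolution: int,
    chrom_length: int,
    chrom: str = "chr",
) -> ContactMatrix:
    """Read 3-column sparse text (i, j, count) into a symmetric matrix.

    ``dialect`` is ``"bin_pairs"`` (i, j are bin indices) or
    ``"coordinate_pairs"`` (Rao format: genomic coordinates, mapped to bins
    by floor division).  Duplicate entries are summed; (i, j) and (j, i)
    fold together.
    """
    if dialect not in ("bin_pairs", "coordinate_pairs"):
        raise ParameterError(f"unknown sparse dialect {dialect!r}")
    n = -(-chrom_length // resolution)
    acc = np.zeros((n, n), dtype=float)
    integral = True
    for lineno, toks in _data_lines(path):
        if toks and not toks[0][0].isdigit() and toks[0][0] not in "+-.":
            toks = toks[1:]  # tolerate a leading chrom column
        if len(toks) < 3:
            raise ParseError(f"expected 3 numeric columns, got {len(toks)}", lineno)
        try:
            a, b, c = float(toks[0]), float(toks[1]), float(toks[2])
        except ValueError:
            raise ParseError(f"non-numeric field in {toks[:3]}", lineno) from None
        if c < 0:
            raise ParseError(f"negative count {c}", lineno)
        if dialect == "coordinate_pairs":
            i, j = int(a // resolution), int(b // resolution)
        else:
            if a != int(a) or b != int(b):
                raise ParseError("bin indices must be integers", lineno)
            i, j = int(a), int(b)
        if i < 0 or j < 0 or i >= n or j >= n:
            raise BoundsError(
                f"line {lineno}: bin ({i}, {j}) outside chromosome of {n} bins"
            )
        if i > j:
            i, j = j, i
        acc[i, j] += c
        integral &= c == int(c)
    full = acc + np.triu(acc, 1).T
    if integral:
        full = full.astype(np.int64)
    return ContactMatrix(matrix=full, resolution=resolution, chrom=chrom,
                         chrom_length=chrom_length)


def write_sparse_contacts(
    m: ContactMatrix,
    path: str | Path,
    coordinate: bool = False,
    header: str | None = None,
) -> None:
    """Write nonzero upper-triangle entries as 3-column text; with
    ``coordinate=True`` the first two columns are bin-start coordinates
    (Rao format)."""
    iu, ju = np.nonzero(np.triu(m.matrix))
    scale = m.resolution if coordinate else 1
    is_int = m.is_integer()
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for i, j in zip(iu, ju):
            v = m.matrix[i, j]
            vtxt = str(int(round(v))) if is_int else repr(float(v))
            fh.write(f"{i * scale}\t{j * scale}\t{vtxt}\n")


def read_dense_contacts(
    path: str | Path,
    *,
    resolution: int,
    chrom: str = "chr",
    chrom_length: int | None = None,
) -> ContactMatrix:
    """Read a whitespace-separated square symmetric matrix."""
    try:
        arr = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"could not parse dense matrix: {exc}") from None
    if arr.shape[0] != arr.shape[1]:
        raise ShapeError(f"dense matrix is not square: {arr.shape}")
    if not np.allclose(arr, arr.T, atol=1e-9, rtol=0):
        raise SymmetryError("dense matrix is asymmetric beyond 1e-9")
    arr = (arr + arr.T) / 2.0
    if np.all(arr == np.round(arr)):
        arr = arr.astype(np.int64)
    return ContactMatrix(matrix=arr, resolution=resolution, chrom=chrom,
                         chrom_length=chrom_length)


def write_dense_contacts(m: ContactMatrix, path: str | Path) -> None:
    fmt = "%d" if m.is_integer() else "%.10g"
    np.savetxt(path, m.matrix, fmt=fmt, delimiter="\t")


def read_signal_bedgraph(
    path: str | Path,
    *,
    resolution: int,
    chrom_length: int,
    chrom: str | None = None,
) -> SignalTrack:
    """Bin a 4-column bedGraph (chrom, start, end, value).

    Each bin's value is the length-weighted mean of overlapping bedGraph
    intervals over the full bin width, so uncovered bases dilute toward 0
    and fully uncovered bins are exactly 0.  Overlapping input intervals
    are ambiguous and rejected.
    """
    n = -(-chrom_length // resolution)
    weighted = np.zeros(n)
    seen: list[tuple[int, int]] = []
    track_chrom = chrom
    for lineno, toks in _data_lines(path):
        if len(toks) < 4:
            raise ParseError(f"expected 4 bedGraph columns, got {len(toks)}", lineno)
        c, start, end, val = toks[0], toks[1], toks[2], toks[3]
        if chrom is not None and c != chrom:
            continue
        track_chrom = track_chrom or c
        try:
            s, e, v = int(start), int(end), float(val)
        except ValueError:
            raise ParseError("non-numeric bedGraph field", lineno) from None
        if e <= s or s < 0:
            raise ParseError(f"bad interval [{s}, {e})", lineno)
        if e > chrom_length:
            raise BoundsError(f"line {lineno}: interval end {e} beyond chromosome")
        for ps, pe in seen:
            if s < pe and ps < e:
                raise ParseError(
                    f"interval [{s}, {e}) overlaps earlier [{ps}, {pe})", lineno
                )
        seen.append((s, e))
        first, last = s // resolution, (e - 1) // resolution
        for b in range(first, last + 1):
            lo, hi = max(s, b * resolution), min(e, (b + 1) * resolution)
            weighted[b] += v * (hi - lo)
    widths = np.full(n, resolution, dtype=float)
    widths[-1] = chrom_length - (n - 1) * resolution
    return SignalTrack(chrom=track_chrom or "chr", resolution=resolution,
                       chrom_length=chrom_length, values=weighted / widths)
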