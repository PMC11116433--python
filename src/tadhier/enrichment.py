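"""Aggregate signal profiles around TAD boundaries and across TAD bodies.

These mirror the two standard meta-region summaries: a *reference-point*
profile averages a binned signal track in a fixed window around each
boundary, and a *scale-regions* profile linearly rescales every region body
to a common length before averaging, so domains of different sizes align.
Typical use: CTCF or histone-mark enrichment around boundaries, stratified
by boundary level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .hierarchy import BoundaryRecord, TadRecord
from .io import SignalTrack

#: Common body length (bp) regions are rescaled to in scale-regions mode.
DEFAULT_BODY_BP = 30_000


@dataclass
class ProfileResult:
    """Position-wise mean signal over the regions that contributed.

    ``positions`` are bp offsets relative to the anchor; in scale-regions
    mode the body positions are labelled 0 .. body_bp and flanks extend
    negative / beyond.  ``n_regions + n_skipped`` equals the number of
    regions supplied.
    """

    positions: np.ndarray
    values: np.ndarray
    n_regions: int
    n_skipped: int


def _positions(boundaries) -> list[int]:
    out = []
    for b in boundaries:
        out.append(b.position if isinstance(b, BoundaryRecord) else int(b))
    return out


def reference_point_profile(
    track: SignalTrack,
    boundaries: Sequence[BoundaryRecord] | Sequence[int],
    flank_bp: int = 500_000,
    skip_zeros: bool = False,
) -> ProfileResult:
    """Average the track in [position - flank, position + flank) across
    boundaries.

    Windows running past either chromosome end are dropped (counted as
    skipped); with ``skip_zeros`` all-zero windows are excluded too.
    """
    res = track.resolution
    if flank_bp % res:
        raise ParameterError(f"flank {flank_bp} is not a multiple of {res}")
    f = flank_bp // res
    if f < 1:
        raise ParameterError("flank must span at least one bin")
    rows = []
    skipped = 0
    for pos in _positions(boundaries):
        c = pos // res
        if c - f < 0 or c + f > track.n_bins:
            skipped += 1
            continue
        w = track.values[c - f : c + f]
        if skip_zeros and not w.any():
            skipped += 1
            continue
        rows.append(w)
    offsets = np.arange(-f, f) * res
    if rows:
        mean = np.mean(rows, axis=0)
    else:
        mean = np.zeros(2 * f)
    return ProfileResult(positions=offsets, values=mean,
                         n_regions=len(rows), n_skipped=skipped)


def _resample_body(values: np.ndarray, n_out: int) -> np.ndarray:
    """Length-weighted averaging of source bins onto n_out equal slots."""
    n_src = values.shape[0]
    c = np.concatenate([[0.0], np.cumsum(values)])
    edges = np.linspace(0.0, n_src, n_out + 1)
    integrals = np.interp(edges, np.arange(n_src + 1), c)
    return np.diff(integrals) / (n_src / n_out)


def scale_regions_profile(
    track: SignalTrack,
    regions: Sequence[TadRecord] | Sequence[tuple[int, int]],
    body_bp: int = DEFAULT_BODY_BP,
    flank_bp: int = 0,
    skip_zeros: bool = True,
) -> ProfileResult:
    """Rescale every region body to ``body_bp`` and average position-wise.

    Bodies are resampled by length-weighted averaging of source bins onto
    ``body_bp / resolution`` slots; flanks are taken unscaled.  Regions
    shorter than one bin, regions whose flanks leave the chromosome, and
    (with ``skip_zeros``) all-zero regions are skipped and counted.
    """
    res = track.resolution
    if body_bp % res or body_bp <= 0:
        raise ParameterError(f"body {body_bp} is not a positive multiple of {res}")
    if flank_bp % res:
        raise ParameterError(f"flank {flank_bp} is not a multiple of {res}")
    nb = body_bp // res
    f = flank_bp // res
    rows = []
    skipped = 0
    for reg in regions:
        if isinstance(reg, TadRecord):
            s, e = reg.start, reg.end
        else:
            s, e = int(reg[0]), int(reg[1])
        sb, eb = s // res, -(-e // res)
        if eb - sb < 1:
            skipped += 1
            continue
        if sb - f < 0 or eb + f > track.n_bins:
            skipped += 1
            continue
        body = _resample_body(track.values[sb:eb].astype(float), nb)
        left = track.values[sb - f : sb]
        right = track.values[eb : eb + f]
        row = np.concatenate([left, body, right])
        if skip_zeros and not row.any():
            skipped += 1
            continue
        rows.append(row)
    positions = np.concatenate(
        [
            np.arange(-f, 0) * res,
            np.arange(nb) * res,  # scaled body coordinates, 0 .. body_bp
            body_bp + np.arange(f) * res,
        ]
    )
    if rows:
        mean = np.mean(rows, axis=0)
    else:
        mean = np.zeros(positions.shape[0])
    return ProfileResult(positions=positions, values=mean,
                         n_regions=len(rows), n_skipped=skipped)
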