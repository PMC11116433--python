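"""Contact matrices and the operations a benchmarking pipeline applies to
them before TAD calling: ICE balancing, depth downsampling, bulk mixing, and
pseudo-bulk aggregation of single-cell maps.

A :class:`ContactMatrix` is a symmetric intra-chromosomal matrix of binned
contact counts.  Internally it is stored dense; the *total* of a matrix is
the sum over unordered bin pairs, i.e. the upper triangle with the diagonal
counted once — the number of underlying contacts, which is the quantity
downsampling and mixing conserve.

Downsampling draws exactly ``target_total`` contacts *without replacement*
from the multiset of observed contacts (a multivariate hypergeometric over
the upper-triangle entries), mirroring subsampling of a real read multiset.
A with-replacement multinomial mode is available for model-based work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateInputError,
    ParameterError,
    ShapeError,
    SymmetryError,
)

#: Mixing-ratio grid used for two-population heterogeneity scans: pure
#: samples plus 9:1 through 1:9.
MIXING_RATIO_GRID: tuple[tuple[float, float], ...] = tuple(
    (k / 10, (10 - k) / 10) for k in range(10, -1, -1)
)

_SYMMETRY_TOL = 1e-9


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact counts for one chromosome."""

    matrix: np.ndarray
    resolution: int
    chrom: str = "chr"
    chrom_length: int | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeError(f"contact matrix must be square, got {m.shape}")
        if not np.allclose(m, m.T, atol=_SYMMETRY_TOL, rtol=0):
            raise SymmetryError("contact matrix is not symmetric")
        if (m < 0).any():
            raise ParameterError("contact counts must be nonnegative")
        self.matrix = m
        if self.chrom_length is None:
            self.chrom_length = m.shape[0] * self.resolution

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> float:
        """Sum over unordered bin pairs (diagonal counted once)."""
        return float(np.triu(self.matrix).sum())

    def is_integer(self) -> bool:
        return np.issubdtype(self.matrix.dtype, np.integer) or bool(
            np.all(self.matrix == np.round(self.matrix))
        )

    def copy(self) -> "ContactMatrix":
        return replace(self, matrix=self.matrix.copy())


@dataclass
class BiasVector:
    """Per-bin multiplicative ICE biases; masked bins carry NaN."""

    biases: np.ndarray
    mask: np.ndarray  # True where the bin is excluded

    def __post_init__(self):
        self.biases = np.asarray(self.biases, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class IceResult:
    matrix: ContactMatrix
    biases: BiasVector
    converged: bool
    n_iter: int
    max_marginal_deviation: float


def _triu_entries(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(m.shape[0])
    return iu, ju, m[iu, ju]


def _from_triu(n: int, iu: np.ndarray, ju: np.ndarray, vals: np.ndarray) -> np.ndarray:
    out = np.zeros((n, n), dtype=vals.dtype)
    out[iu, ju] = vals
    out[ju, iu] = vals
    return out


def ice_normalize(
    m: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 100,
    mask_zero_bins: bool = True,
    mask_fraction: float | None = None,
) -> IceResult:
    """Iterative correction: equalize bin marginals by a multiplicative bias.

    Repeatedly divides ``c(i, j)`` by ``b_i * b_j`` with
    ``b_i = marginal_i / mean(unmasked marginals)`` until the maximum
    relative deviation of unmasked marginals from their mean drops below
    ``tol``, then rescales so the total equals the input total.  Bins with
    zero marginal (and optionally the lowest ``mask_fraction`` of nonzero
    bins) are excluded throughout.

    Non-convergence within ``max_iter`` produces a warning, not an error;
    the partially balanced matrix is still returned.
    """
    work = np.array(m.matrix, dtype=float)
    n = work.shape[0]
    marg = work.sum(axis=1)
    mask = np.zeros(n, dtype=bool)
    if mask_zero_bins:
        mask |= marg == 0
    if mask_fraction is not None:
        if not 0 <= mask_fraction < 1:
            raise ParameterError("mask_fraction must be in [0, 1)")
        nonzero = np.flatnonzero(marg > 0)
        k = int(np.floor(mask_fraction * nonzero.size))
        if k:
            mask[nonzero[np.argsort(marg[nonzero])[:k]]] = True
    if mask.all():
        raise DegenerateInputError("every bin is masked; nothing to balance")

    work[mask, :] = 0.0
    work[:, mask] = 0.0
    total_in = np.triu(work).sum()
    cumulative = np.ones(n)
    converged = False
    deviation = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        marg = work.sum(axis=1)
        mean_marg = marg[~mask].mean()
        if mean_marg == 0:
            raise DegenerateInputError("all unmasked contacts vanished")
        deviation = float(np.abs(marg[~mask] / mean_marg - 1.0).max())
        if deviation < tol:
            converged = True
            break
        b = np.ones(n)
        b[~mask] = marg[~mask] / mean_marg
        work /= np.outer(b, b)
        work[mask, :] = 0.0
        work[:, mask] = 0.0
        cumulative *= b
    if not converged:
        warnings.warn(
            f"ICE did not reach tol={tol} in {max_iter} iterations "
            f"(max marginal deviation {deviation:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    total_now = np.triu(work).sum()
    if total_now > 0:
        work *= total_in / total_now
    biases = np.where(mask, np.nan, cumulative)
    out = replace(m, matrix=work)
    return IceResult(out, BiasVector(biases, mask), converged, it, deviation)


def _require_integer(m: ContactMatrix) -> np.ndarray:
    if not m.is_integer():
        raise TypeError("operation requires integer (raw) contact counts")
    return np.round(m.matrix).astype(np.int64)


def downsample_contacts(
    m: ContactMatrix,
    target_total: int,
    seed: int | np.random.Generator,
    replace_draws: bool = False,
) -> ContactMatrix:
    """Subsample a raw matrix to exactly ``target_total`` contacts.

    Without replacement (default) the result follows the multivariate
    hypergeometric law over upper-triangle entries; entry expectations are
    ``fraction * count`` and the total is exact.  ``replace_draws=True``
    switches to multinomial (with-replacement) semantics.
    """
    counts = _require_integer(m)
    iu, ju, vals = _triu_entries(counts)
    total = int(vals.sum())
    if target_total < 0:
        raise ParameterError(f"target_total must be nonnegative, got {target_total}")
    if not replace_draws and target_total > total:
        raise ParameterError(
            f"target_total {target_total} exceeds matrix total {total}"
        )
    rng = np.random.default_rng(seed)
    if replace_draws:
        if total == 0:
            raise ParameterError("cannot resample an empty matrix with replacement")
        p = vals / total
        new_vals = rng.multinomial(target_total, p)
    elif target_total == total:
        new_vals = vals
    elif target_total == 0:
        new_vals = np.zeros_like(vals)
    else:
        new_vals = rng.multivariate_hypergeometric(
            vals, target_total, method="marginals"
        )
    out = _from_triu(counts.shape[0], iu, ju, new_vals.astype(np.int64))
    return replace(m, matrix=out)


def mix_matrices(
    ms: list[ContactMatrix],
    ratios: list[float],
    seed: int | np.random.Generator,
    equalized_total: int | None = None,
) -> ContactMatrix:
    """Mix raw matrices at given ratios after depth equalization.

    Every matrix is first downsampled to a common depth (the minimum total
    by default), then matrix *i* is downsampled again to
    ``round(ratio_i * equalized_total)`` (round half to even) and the
    results are summed entrywise.  The output total is the sum of the
    rounded targets; ICE, if wanted, is applied to the mixed raw matrix
    afterwards.
    """
    if len(ms) != len(ratios) or not ms:
        raise ParameterError("need one ratio per matrix")
    shape = ms[0].matrix.shape
    for m in ms:
        if m.matrix.shape != shape:
            raise ShapeError("all matrices must share a shape")
        if m.resolution != ms[0].resolution:
            raise ParameterError("all matrices must share a resolution")
    if any(r < 0 for r in ratios):
        raise ParameterError("ratios must be nonnegative")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ParameterError(f"ratios must sum to 1, got {sum(ratios)}")
    totals = [int(round(m.total)) for m in ms]
    if equalized_total is None:
        equalized_total = min(totals)
    if equalized_total > min(totals):
        raise ParameterError("equalized_total exceeds the smallest matrix total")
    rng = np.random.default_rng(seed)
    acc = np.zeros(shape, dtype=np.int64)
    for m, r in zip(ms, ratios):
        eq = downsample_contacts(m, equalized_total, rng)
        target = int(np.round(r * equalized_total))  # numpy rounds half to even
        part = downsample_contacts(eq, target, rng)
        acc += np.round(part.matrix).astype(np.int64)
    return replace(ms[0], matrix=acc)


def pseudo_bulk(
    cells: list[ContactMatrix],
    group_sizes: list[int] | None = None,
    *,
    groups: list[list[ContactMatrix]] | None = None,
    ratios: list[float] | None = None,
    n_cells: int | None = None,
    seed: int | np.random.Generator = 0,
) -> ContactMatrix:
    """Sum per-cell matrices into a pseudo-bulk map.

    Two call styles:

    * ``pseudo_bulk(cells, [k])`` — sample ``k`` cells without replacement
      from one pool and sum them.
    * ``pseudo_bulk([], groups=[g1, g2], ratios=[0.5, 0.5], n_cells=10)`` —
      split ``n_cells`` across groups proportionally (largest-remainder
      apportionment, ties to the earlier group), sample within each group
      without replacement, and sum.
    """
    rng = np.random.default_rng(seed)
    if groups is not None:
        if ratios is None or n_cells is None:
            raise ParameterError("groups requires ratios and n_cells")
        if abs(sum(ratios) - 1.0) > 1e-9:
            raise ParameterError("ratios must sum to 1")
        raw = [r * n_cells for r in ratios]
        take = [int(np.floor(x)) for x in raw]
        rem = n_cells - sum(take)
        order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - take[i]), i))
        for i in order[:rem]:
            take[i] += 1
        selected: list[ContactMatrix] = []
        for g, k in zip(groups, take):
            if k > len(g):
                raise ParameterError(f"requested {k} cells from a group of {len(g)}")
            idx = rng.choice(len(g), size=k, replace=False)
            selected.extend(g[i] for i in sorted(idx))
    else:
        if group_sizes is None or len(group_sizes) != 1:
            raise ParameterError("single-pool style takes group_sizes=[k]")
        k = group_sizes[0]
        if k > len(cells):
            raise ParameterError(f"requested {k} cells from a pool of {len(cells)}")
        idx = rng.choice(len(cells), size=k, replace=False)
        selected = [cells[i] for i in sorted(idx)]
    if not selected:
        raise ParameterError("no cells selected")
    shape = selected[0].matrix.shape
    acc = np.zeros(shape, dtype=selected[0].matrix.dtype)
    for c in selected:
        if c.matrix.shape != shape:
            raise ShapeError("all cell matrices must share a shape")
        acc = acc + c.matrix
    return replace(selected[0], matrix=acc)
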