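# Methods

This note records the models, conventions and numerical choices behind
`tadhier`, in the order a benchmarking run encounters them.

## Coordinate and level conventions

All intervals are 0-based, half-open, in base pairs, snapped to the bin
grid, so `bin = coordinate // resolution` is exact and invertible.  Caller
outputs that use bin indices are converted with an *inclusive* end bin
(`end_bp = (end_bin - bin_base + 1) * resolution`), which is the dominant
caller convention; the bin base (0 or 1) is part of the input dialect
because callers do not agree on it and files do not declare it.

A domain's level is one plus the length of the longest chain of domains
strictly containing it.  On a properly nested ("laminar") family this
equals one plus the number of containers — the intuitive nesting depth —
but the chain definition stays well defined when callers emit partially
overlapping domains, which contribute nothing to containment.  Levels are
computed by a size-descending dynamic program: after removing duplicate
intervals, any strict container is strictly longer, so processing
longest-first guarantees containers are levelled before their contents.
The test suite checks this against a memoized brute-force recursion on
the explicit pairwise containment relation.

Boundary level is the larger of the number of domains starting versus
ending at a position: a position closing three nested domains is a
level-3 boundary regardless of what starts there.

The size filter removes domains shorter than 30 kb or longer than 2 Mb
(bounds inclusive: 30 kb and 2 Mb themselves survive), the scale range
within which TADs are defined.  Levels are re-derived on the survivors,
since deleting an outer domain promotes its children.  Filtering is a
separate, explicit step — it is never applied implicitly before
similarity or coverage computations.

Genomic coverage is the union length of all domains over the chromosome
length (equivalently one minus the relative complement length); nesting
never double-counts.  Multi-sample coverage is the arithmetic mean of
per-sample coverages.

## Hier_SSIM

Two design points needed fixing where the procedure is usually left
implicit:

* **Pixel value.**  Pixel (i, j) carries 20 × the level of the
  *innermost* (maximum-level) domain containing both bins.  "The level of
  the pixel" is only single-valued under this reading; it also reproduces
  the familiar nested-squares rendering of hierarchy heatmaps.  The
  multiplier 20 is frozen as `LEVEL_MULTIPLIER`.
* **Windowing.**  W = 8 Mb / resolution bins.  Windows are diagonal
  W×W blocks at bins 0, step, 2·step, …, default step one full window
  (non-overlapping); a trailing block shorter than W is dropped, so
  content past the last full window cannot influence the score.  The
  stride is a parameter because overlapping strides are a legitimate
  variant; the default is the cheapest faithful one.

SSIM itself uses uniform (unweighted) 7×7 patches, sample (co)variances
(the n/(n−1) correction), and averages only patches that lie fully
inside the window — the standard defaults of the common image-quality
implementation, against which the test suite cross-checks to 1e-9.
The stabilisation constants are C1 = (0.01·L)², C2 = (0.03·L)².  The
data range L defaults to 20 × the deepest level observed in *either*
raster, computed jointly so that both arguments are scored on one scale;
it can be pinned explicitly when many pairs must share a range.  Two
identical windows score exactly 1 by construction, which makes the
L = 0 corner (two empty rasters) well defined.

Hier_SSIM is symmetric, equals 1 iff the rasters agree on every full
window, and degrades monotonically in expectation as boundaries are
shifted — the simulator's perturbation operator exists to exercise
exactly that property.

## Overlap ratio

Each hierarchy is reduced to its coding tree's node set: the distinct
(start, end) intervals at all levels, in bins.  An A-node may match a
B-node when both endpoint differences are at most the tolerance (default
0); matching is greedy one-to-one by smallest total endpoint distance
with deterministic index tie-breaks, and OR = 2·|matches|/(|A|+|B|) — a
Dice coefficient on tree nodes.  Two empty trees score 1 (they agree
vacuously).  This is a documented re-implementation of the
coding-tree-intersection idea, not a byte-level clone of any external
binary; increasing the tolerance never lowers OR.

## Clustering

Callers are clustered on distance 1 − similarity with unweighted
average linkage (UPGMA), implemented directly so the tie-break is
explicit: among equally distant pairs, the one whose smallest original
leaf indices sort first merges.  Output is a scipy-format linkage matrix
plus a Newick export.  Tests verify it against both scipy's
average-linkage and a stepwise re-enumeration of cluster mean distances.

## Contact-matrix operations

Matrices are symmetric, intra-chromosomal, dense in memory; the *total*
is the sum over unordered bin pairs with the diagonal counted once —
the number of underlying contacts.

**ICE.**  Iterative correction divides c(i,j) by bᵢbⱼ with
bᵢ = marginalᵢ / mean marginal each round, until the maximum relative
marginal deviation drops below 1e-5 (default) or 100 iterations pass;
non-convergence warns rather than fails.  Only zero-marginal bins are
masked by default (an optional fraction-based low-coverage mask exists).
The result is rescaled to the input total, so balancing redistributes
but never creates or destroys mass.  Balancing is per chromosome;
inter-chromosomal contacts are out of scope throughout.

**Downsampling.**  Real sequencing depth reduction removes reads from a
finite multiset, so the default semantics are without replacement: the
vector of upper-triangle entries is drawn from a multivariate
hypergeometric law, giving an exact output total and per-entry means of
fraction × count.  A with-replacement multinomial mode exists for
model-based resampling.  Every stochastic operation takes a seed and is
bit-reproducible.

**Mixing.**  To mix cell types at a ratio, all matrices are first
downsampled to a common depth (the minimum total by default), then each
to round(ratioᵢ × depth) — round half to even; the sub-contact lost to
rounding is discarded, not redistributed, so totals are exactly the sum
of rounded targets.  Mixing operates on raw counts; ICE is applied to
the mixed matrix afterwards, matching the order normalize-after-mix.
The canonical two-population grid spans pure samples and 9:1 … 1:9.

**Pseudo-bulk.**  Cells are sampled without replacement (within groups,
apportioned by largest remainder with ties to the earlier group) and
summed entrywise.

## Enrichment profiles

Reference-point mode averages the binned track in ±flank around each
boundary; windows leaving the chromosome are dropped and counted.
Scale-regions mode resamples each region body to 30 kb (default) by
length-weighted averaging — target slot j receives the exact integral of
the piecewise-constant source signal over its sub-interval — with flanks
unscaled.  `skip_zeros` defaults off for reference-point and on for
scale-regions.  With skipping off, profiles are linear in the track and
invariant to region order.  The flank has no universal default and is a
required explicit parameter.

## Synthetic data

The simulator emulates the domains-within-domains organisation the
benchmarking machinery is built to measure.  Level-1 TADs tile the
chromosome with log-uniform sizes in [30 kb, 2 Mb], separated by
occasional short gaps (probability 0.1); each domain splits with
probability 0.7 into 2–4 contiguous children of at least 3 bins,
strictly inside the parent, down to depth 3.  Expected contacts are

    μ(i, j) = A · (|i−j| + 1)^(−α) · β^depth(i, j)

with background A = 10 counts, decay α = 1 (the classic power-law
exponent for intra-chromosomal contact frequency), per-level boost
β = 1.6, and depth(i, j) the number of domains containing both bins —
enrichment compounds multiplicatively with nesting, so a level-2 subTAD
sits β² above open chromatin at equal distance.  Observed counts are
independent Poisson draws on the upper triangle, mirrored; Poisson is
the simplest model producing integer raw counts valid for downsampling
and mixing.  The default chromosome is 24 Mb at 10-kb bins — 2400 bins,
exactly three 8-Mb Hier_SSIM windows — which keeps a full
simulate–perturb–compare cycle under a second.

The perturbation operator shifts each record's endpoints independently
by a uniform integer in [−k, +k] bins (clamped to keep at least one bin
and stay on the chromosome) and drops records with a given probability,
then re-derives levels.

What the simulator does *not* emulate: loop anchors and corner peaks,
A/B compartments, coverage biases (GC, mappability), overdispersion
beyond Poisson, and inter-chromosomal structure.  Tests passing on this
generator therefore demonstrate correctness of the metrics and
operations, not caller performance on real Hi-C data.

## Problem sizes and numerical notes

The acceptance-style checks run at the sizes the defaults imply: level
assignment is verified against brute force on a thousand random interval
sets of up to 200 intervals; Hier_SSIM identity/symmetry on a hundred
2400-bin pairs; ICE on two hundred 300-bin Poisson matrices;
downsampling moments over a thousand seeds on a ten-entry toy matrix;
enrichment recovery over fifty seeds.  Equality tie-breaks are
deterministic everywhere (sorting by (start, −length); smallest-label
merges; half-to-even rounding), so every pipeline is a pure function of
inputs and seed.  Degenerate inputs are defined rather than rejected
where a sensible value exists: empty hierarchies have coverage 0, empty
coding trees overlap at 1, identical images score SSIM 1 even at L = 0.
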