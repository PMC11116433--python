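# tadhier

Harmonize hierarchical TAD calls and benchmark how well they agree.

Topologically associating domains (TADs) are megabase-scale blocks of
self-interacting chromatin visible as diagonal squares in Hi-C contact
maps, and they nest: subTADs sit inside TADs, which may sit inside larger
metaTADs.  More than a dozen callers reconstruct this hierarchy, but they
disagree on output format, on what "level" means, and — substantively —
on the domains themselves.  `tadhier` is for computational biologists who
need to compare such outputs quantitatively: it normalizes every caller
dialect to one level scheme, measures similarity between hierarchies,
prepares the contact matrices that callers consume, and simulates nested
ground truth so every step can be validated without external data.

## What it computes

**Level scheme.**  A TAD contained in no larger TAD has level 1; the
level grows by one per layer of strict containment, so

    level(T) = 1 + max length of a chain of domains strictly containing T.

A boundary's level is `max(#domains starting there, #domains ending
there)`.  Domains shorter than 30 kb or longer than 2 Mb can be filtered
out, with levels re-derived on the survivors.

**Hier_SSIM.**  Each hierarchy is drawn onto a heatmap-sized raster where
pixel (i, j) is 20 × the level of the innermost domain containing both
bins i and j.  An 8-Mb window slides along the diagonal, the structural
similarity index

    SSIM(x, y) = mean over 7×7 patches of
                 (2 μx μy + C1)(2 σxy + C2) / ((μx² + μy² + C1)(σx² + σy² + C2))

is evaluated on each pair of windows, and the mean over windows is
Hier_SSIM (1 for identical hierarchies, toward 0 as they diverge).

**Overlap ratio.**  Each hierarchy is a coding tree — the set of distinct
domain intervals at all levels; OR = 2·|matched nodes| / (|A| + |B|),
with an optional endpoint tolerance in bins.

**Supporting machinery.**  ICE matrix balancing, exact-total contact
downsampling (multivariate hypergeometric), depth-equalized mixing of
raw maps at ratios such as 9:1 … 1:9, pseudo-bulk aggregation of
single-cell maps, UPGMA clustering of callers from a similarity matrix,
boundary/body signal-enrichment profiles, and a seeded simulator of
nested hierarchies with Poisson contact maps.

## Worked example

```python
import numpy as np
from tadhier import *

p = SimParams(seed=7)                      # 24 Mb, 10 kb bins, depth 3
truth = simulate_hierarchy(p)
dist = level_distribution(truth)
print("domains:", len(truth.records), "coverage: %.3f" % genomic_coverage(truth))
print("per-level counts:", dist.tad_counts)

noisy = perturb_hierarchy(truth, shift_bins=2, seed=1)
ra, rb = rasterize_hierarchy(truth), rasterize_hierarchy(noisy)
print("Hier_SSIM(truth, truth)  = %.6f" % hier_ssim(ra, ra))
print("Hier_SSIM(truth, noisy)  = %.6f" % hier_ssim(ra, rb))
print("overlap ratio (tol 0)    = %.4f" % overlap_ratio(truth, noisy))
print("overlap ratio (tol 2)    = %.4f" % overlap_ratio(truth, noisy, 2))
```

prints

```
domains: 235 coverage: 0.988
per-level counts: {1: 49, 2: 87, 3: 99}
Hier_SSIM(truth, truth)  = 1.000000
Hier_SSIM(truth, noisy)  = 0.971164
overlap ratio (tol 0)    = 0.0383
overlap ratio (tol 2)    = 0.9830
```

The simulated chromosome carries 235 nested domains covering 98.8% of
its length.  Shifting every boundary by up to 2 bins drops Hier_SSIM
from 1 to 0.97 — the metric degrades smoothly with boundary error.  The
strict overlap ratio collapses to 0.04 because almost no interval
survives a shift exactly, while a 2-bin tolerance restores it to 0.98;
the two metrics probe different notions of agreement.

The same operations are available from the shell:

```sh
tadhier simulate --seed 7 --out-prefix sim
tadhier hier-ssim sim.tads.tsv sim.tads.tsv \
    --resolution 10000 --chrom-length 24000000
tadhier ice sim.contacts.tsv --resolution 10000 \
    --chrom-length 24000000 --out sim.iced.tsv
```

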