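import numpy as np
import pytest

from tadhier import ContactMatrix, TadHierarchy, TadRecord

RES = 10_000


def make_hierarchy(intervals, chrom_length=None, resolution=RES, levels=None):
    if levels is None:
        records = [TadRecord(s, e) for s, e in intervals]
    else:
        records = [TadRecord(s, e, l) for (s, e), l in zip(intervals, levels)]
    return TadHierarchy(chrom="chrT", resolution=resolution,
                        chrom_length=chrom_length, records=records)


def random_intervals(rng, n_max=200, resolution=RES, span_bins=500,
                     max_len_bins=100):
    """Random on-grid interval set (may contain duplicates/overlaps)."""
    n = int(rng.integers(0, n_max + 1))
    starts = rng.integers(0, span_bins, size=n)
    lengths = rng.integers(1, max_len_bins, size=n)
    return [
        (int(s) * resolution, int(s + l) * resolution)
        for s, l in zip(starts, lengths)
    ]


@pytest.fixture
def nested4():
    """The four-domain example: outer TAD split in two, with a sub-subTAD."""
    return make_hierarchy(
        [(0, 100_000), (0, 50_000), (50_000, 100_000), (10_000, 40_000)],
        chrom_length=200_000,
    )


@pytest.fixture
def toy_contacts():
    rng = np.random.default_rng(7)
    m = np.triu(rng.poisson(8, (12, 12)))
    return ContactMatrix(matrix=m + np.triu(m, 1).T, resolution=RES)
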