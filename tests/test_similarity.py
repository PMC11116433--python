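import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from tadhier import (
    LevelRaster,
    SimilarityMatrix,
    SsimParams,
    assign_tad_levels,
    average_linkage_cluster,
    hier_ssim,
    overlap_ratio,
    pairwise_similarity,
    rasterize_hierarchy,
    simulate_hierarchy,
    ssim_window,
    validate_hierarchy,
    SimParams,
)
from tadhier.errors import ParameterError, ResolutionError, ShapeError

from _oracles import raster_oracle, upgma_oracle
from conftest import RES, make_hierarchy, random_intervals


def levelled(intervals, chrom_length):
    return assign_tad_levels(
        validate_hierarchy(make_hierarchy(intervals, chrom_length=chrom_length))
    )


class TestRasterize:
    def test_nested_blocks_take_innermost_level(self):
        h = levelled([(0, 30_000), (0, 20_000)], chrom_length=50_000)
        r = rasterize_hierarchy(h)
        assert r.values[0, 1] == 40  # inside the level-2 child
        assert r.values[0, 2] == 20  # only the level-1 parent spans both
        assert r.values[3, 3] == 0   # outside every domain

    def test_empty_hierarchy_all_zero(self):
        r = rasterize_hierarchy(make_hierarchy([], chrom_length=100_000))
        assert not r.values.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_values_are_multiples_of_twenty_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, n_max=30, span_bins=40, max_len_bins=60)
        h = levelled(ivs, chrom_length=100 * RES)
        r = rasterize_hierarchy(h)
        assert np.array_equal(r.values, r.values.T)
        assert not (r.values % 20).any()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pixel_enumeration_oracle(self, seed):
        rng = np.random.default_rng(50 + seed)
        ivs = random_intervals(rng, n_max=15, span_bins=15, max_len_bins=5)
        h = levelled(ivs, chrom_length=20 * RES)
        got = rasterize_hierarchy(h).values
        want = raster_oracle(
            [(r.start, r.end, r.level) for r in h.records], 20, RES
        )
        assert np.array_equal(got, want)

    def test_inconsistent_n_bins_rejected(self):
        h = levelled([(0, 30_000)], chrom_length=50_000)
        with pytest.raises(ShapeError):
            rasterize_hierarchy(h, n_bins=99)


class TestSsimWindow:
    def test_identical_inputs_score_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, (16, 16)) * 20.0
        assert ssim_window(x, x.copy(), SsimParams(data_range=60)) == 1.0

    def test_constant_images_closed_form(self):
        x = np.zeros((9, 9))
        y = np.full((9, 9), 20.0)
        got = ssim_window(x, y, SsimParams(data_range=20))
        assert got == pytest.approx(0.04 / 400.04, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 60, (20, 20))
        y = rng.uniform(0, 60, (20, 20))
        p = SsimParams(data_range=60)
        assert ssim_window(x, y, p) == pytest.approx(ssim_window(y, x, p))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_skimage_reference(self, seed):
        structural_similarity = pytest.importorskip(
            "skimage.metrics"
        ).structural_similarity
        rng = np.random.default_rng(100 + seed)
        x = rng.integers(0, 4, (40, 40)) * 20.0
        y = rng.integers(0, 4, (40, 40)) * 20.0
        mine = ssim_window(x, y, SsimParams(data_range=60))
        ref = structural_similarity(x, y, win_size=7, data_range=60,
                                    gaussian_weights=False)
        assert mine == pytest.approx(ref, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ssim_window(np.zeros((8, 8)), np.zeros((9, 9)),
                        SsimParams(data_range=20))

    def test_zero_range_with_distinct_inputs_rejected(self):
        with pytest.raises(ParameterError):
            ssim_window(np.zeros((8, 8)), np.ones((8, 8)),
                        SsimParams(data_range=0))


def _raster(values):
    return LevelRaster(values=np.asarray(values), resolution=RES)


class TestHierSsim:
    def test_self_similarity_is_one(self):
        h = simulate_hierarchy(SimParams(seed=1))
        r = rasterize_hierarchy(h)
        assert hier_ssim(r, r) == 1.0

    def test_two_empty_rasters_score_one(self):
        z = _raster(np.zeros((900, 900)))
        assert hier_ssim(z, _raster(np.zeros((900, 900)))) == 1.0

    def test_window_grid_three_windows_at_2400_bins(self):
        # 2400 bins at 10 kb with an 8 Mb window -> windows at 0, 800, 1600
        a = np.zeros((2400, 2400))
        b = np.zeros((2400, 2400))
        b[:800, :800] = 20.0  # only the first window differs
        p = SsimParams(data_range=20)
        per_window = ssim_window(a[:800, :800], b[:800, :800], p)
        got = hier_ssim(_raster(a), _raster(b), data_range=20)
        assert got == pytest.approx((per_window + 1.0 + 1.0) / 3)

    def test_invariant_to_trailing_partial_window(self):
        rng = np.random.default_rng(3)
        base = (rng.integers(0, 3, (1700, 1700)) * 20).astype(float)
        a1, a2 = base.copy(), base.copy()
        a2[1600:, 1600:] += 20.0  # beyond the last full 800-bin window
        b = (rng.integers(0, 3, (1700, 1700)) * 20).astype(float)
        v1 = hier_ssim(_raster(a1), _raster(b), data_range=40)
        v2 = hier_ssim(_raster(a2), _raster(b), data_range=40)
        assert v1 == v2

    def test_insufficient_extent_rejected(self):
        small = _raster(np.zeros((100, 100)))
        with pytest.raises(ParameterError):
            hier_ssim(small, small)

    def test_window_not_multiple_of_resolution_rejected(self):
        r = _raster(np.zeros((900, 900)))
        with pytest.raises(ParameterError):
            hier_ssim(r, r, window_bp=8_000_001)


class TestOverlapRatio:
    def test_self_overlap_is_one(self, nested4):
        h = validate_hierarchy(nested4)
        assert overlap_ratio(h, h) == 1.0

    def test_worked_three_node_example(self):
        a = make_hierarchy([(0, 100_000), (0, 50_000), (50_000, 100_000)])
        b = make_hierarchy([(0, 100_000), (0, 50_000), (40_000, 100_000)])
        assert overlap_ratio(validate_hierarchy(a), validate_hierarchy(b)) == (
            pytest.approx(2 * 2 / (3 + 3))
        )

    def test_disjoint_node_sets_score_zero(self):
        a = validate_hierarchy(make_hierarchy([(0, 50_000)]))
        b = validate_hierarchy(make_hierarchy([(100_000, 200_000)]))
        assert overlap_ratio(a, b) == 0.0

    def test_both_empty_defined_as_one(self):
        assert overlap_ratio(make_hierarchy([]), make_hierarchy([])) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = validate_hierarchy(make_hierarchy(random_intervals(rng, 30)))
        b = validate_hierarchy(make_hierarchy(random_intervals(rng, 30)))
        v = overlap_ratio(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(overlap_ratio(b, a))

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_tolerance(self, seed):
        rng = np.random.default_rng(10 + seed)
        a = validate_hierarchy(make_hierarchy(random_intervals(rng, 25)))
        b = validate_hierarchy(make_hierarchy(random_intervals(rng, 25)))
        vals = [overlap_ratio(a, b, t) for t in (0, 1, 2, 5)]
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))

    def test_mismatched_resolutions_rejected(self):
        a = validate_hierarchy(make_hierarchy([(0, 50_000)]))
        b = validate_hierarchy(make_hierarchy([(0, 50_000)], resolution=5_000))
        with pytest.raises(ResolutionError):
            overlap_ratio(a, b)


class TestAverageLinkage:
    def test_hand_computed_three_item_tree(self):
        sim = 1 - np.array([[0, .1, .4], [.1, 0, .5], [.4, .5, 0]])
        np.fill_diagonal(sim, 1.0)
        dend = average_linkage_cluster(SimilarityMatrix(["A", "B", "C"], sim))
        assert dend.linkage[0][:3].tolist() == [0, 1, pytest.approx(0.1)]
        assert dend.linkage[1][2] == pytest.approx(0.45)

    def test_all_equal_distances_merge_at_same_height(self):
        sim = np.full((4, 4), 0.7)
        np.fill_diagonal(sim, 1.0)
        dend = average_linkage_cluster(
            SimilarityMatrix(list("WXYZ"), sim)
        )
        assert np.allclose(dend.linkage[:, 2], 0.3)

    def test_two_items_merge_at_their_distance(self):
        sim = np.array([[1.0, 0.2], [0.2, 1.0]])
        dend = average_linkage_cluster(SimilarityMatrix(["A", "B"], sim))
        assert dend.linkage.shape == (1, 4)
        assert dend.linkage[0, 2] == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        s = rng.uniform(0, 1, (n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        sm = SimilarityMatrix([f"c{i}" for i in range(n)], s)
        mine = average_linkage_cluster(sm).linkage
        ref = linkage(squareform(1 - sm.values, checks=False), method="average")
        assert np.allclose(mine[:, 2], ref[:, 2])
        assert np.allclose(mine[:, 3], ref[:, 3])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 6))
        s = rng.uniform(0, 1, (n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        sm = SimilarityMatrix([f"c{i}" for i in range(n)], s)
        dend = average_linkage_cluster(sm)
        merges, heights = upgma_oracle(1 - sm.values)
        assert np.allclose(dend.linkage[:, 2], heights)
        # reconstruct member sets from the linkage and compare partitions
        members = {i: {i} for i in range(n)}
        for k, row in enumerate(dend.linkage):
            members[n + k] = members[int(row[0])] | members[int(row[1])]
            assert members[n + k] == set(merges[k])

    def test_newick_contains_all_labels(self):
        sim = np.array([[1, .9, .2], [.9, 1, .3], [.2, .3, 1]])
        dend = average_linkage_cluster(
            SimilarityMatrix(["ca", "cb", "cc"], sim)
        )
        nwk = dend.newick()
        assert nwk.endswith(";") and all(l in nwk for l in ("ca", "cb", "cc"))


class TestPairwiseSimilarity:
    def test_hier_ssim_matrix_has_unit_diagonal(self):
        hs = {
            f"s{i}": simulate_hierarchy(
                SimParams(chrom_length=9_000_000, seed=i)
            )
            for i in range(3)
        }
        sm = pairwise_similarity(hs, metric="hier_ssim")
        assert np.allclose(np.diag(sm.values), 1.0)
        assert np.allclose(sm.values, sm.values.T)

    def test_overlap_ratio_metric(self, nested4):
        h = validate_hierarchy(nested4)
        sm = pairwise_similarity({"a": h, "b": h}, metric="overlap_ratio")
        assert sm.values[0, 1] == 1.0
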