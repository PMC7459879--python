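"""Block partitioning, MST weights and the two-pass segmenter."""

import itertools

import numpy as np
import pytest

from dermoseg.graphseg import (
    PixelBlock,
    SegmentationConfig,
    build_block_graph,
    dynamic_threshold,
    mst_weight,
    partition_blocks,
    segment,
    segment_iteration1,
    segment_iteration2,
)

# the 16 spanning trees of the complete graph on 4 vertices
ALL_EDGES = list(itertools.combinations(range(4), 2))
SPANNING_TREES = [
    t
    for t in itertools.combinations(ALL_EDGES, 3)
    if len({v for e in t for v in e}) == 4
]


def brute_force_mst(w: np.ndarray) -> float:
    """Exhaustive minimum over all 16 spanning trees (independent oracle)."""
    return min(sum(w[i, j] for i, j in tree) for tree in SPANNING_TREES)


class TestPartition:
    def test_exact_tiling_counts(self):
        img = np.zeros((8, 8), np.uint8)
        assert len(partition_blocks(img)) == 4
        img = np.zeros((64, 64), np.uint8)
        assert len(partition_blocks(img)) == 256

    def test_remainder_blocks_zero_padded(self):
        img = np.full((10, 10), 7, np.uint8)
        blocks = partition_blocks(img)
        assert len(blocks) == 9
        corner = [b for b in blocks if (b.top_row, b.left_col) == (8, 8)][0]
        assert corner.values[0, 0] == 7 and corner.values[3, 3] == 0

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            partition_blocks(np.zeros((3, 8), np.uint8))


class TestBlockGraph:
    def test_constant_block_gives_constant_edges(self):
        g = build_block_graph(PixelBlock(0, 0, np.full((4, 4), 9, np.uint8)))
        off = g.weights[~np.eye(4, dtype=bool)]
        assert (off == 9).all()

    def test_multi_edge_collapses_to_minimum(self):
        v = np.full((4, 4), 50, np.uint8)
        v[0, 1], v[1, 0] = 5, 9
        g = build_block_graph(PixelBlock(0, 0, v))
        assert g.weights[0, 1] == 5 and g.weights[1, 0] == 5

    def test_diagonal_is_discarded(self):
        v = np.full((4, 4), 50, np.uint8)
        g1 = build_block_graph(PixelBlock(0, 0, v))
        v2 = v.copy()
        np.fill_diagonal(v2, 201)
        g2 = build_block_graph(PixelBlock(0, 0, v2))
        assert (g1.weights == g2.weights).all()


class TestMST:
    def test_uniform_graph(self):
        g = build_block_graph(PixelBlock(0, 0, np.full((4, 4), 10, np.uint8)))
        w, edges = mst_weight(g)
        assert w == 30 and len(edges) == 3

    def test_path_shaped_optimum(self):
        v = np.full((4, 4), 100, np.uint8)
        for i, j in ((0, 1), (1, 2), (2, 3)):
            v[i, j] = v[j, i] = 1
        w, edges = mst_weight(build_block_graph(PixelBlock(0, 0, v)))
        assert w == 3
        assert sorted(edges) == [(0, 1), (1, 2), (2, 3)]

    def test_tree_spans_all_vertices(self, rng):
        for _ in range(50):
            v = rng.integers(0, 256, (4, 4), dtype=np.uint8)
            g = build_block_graph(PixelBlock(0, 0, v))
            w, edges = mst_weight(g)
            assert len(edges) == 3
            assert {v for e in edges for v in e} == {0, 1, 2, 3}

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(500):
            v = rng.integers(0, 256, (4, 4), dtype=np.uint8)
            g = build_block_graph(PixelBlock(0, 0, v))
            w, _ = mst_weight(g)
            assert w == brute_force_mst(g.weights)


class TestIteration1:
    def test_bright_uniform_image_empty(self):
        img = np.full((8, 8), 200, np.uint8)
        mask, _ = segment_iteration1(img, SegmentationConfig(threshold=100))
        assert not mask.pixels.any()

    def test_dark_uniform_image_full(self):
        img = np.full((8, 8), 10, np.uint8)
        mask, w = segment_iteration1(img, SegmentationConfig(threshold=100))
        assert mask.pixels.all()
        assert (w == 30).all()

    def test_single_dark_block_selected(self):
        img = np.full((8, 8), 250, np.uint8)
        img[4:8, 0:4] = 5
        mask, w = segment_iteration1(img, SegmentationConfig(threshold=100))
        assert mask.blocks.tolist() == [[False, False], [True, False]]
        assert w[1, 0] == 15 and w[0, 0] == 750
        assert mask.pixels[4:8, 0:4].all() and mask.pixels.sum() == 16


class TestDynamicThreshold:
    def test_median_max_midpoint(self):
        fz, d = dynamic_threshold([1, 2, 3, 4, 5])
        assert (fz.alpha, fz.beta, d) == (3, 5, 4)

    def test_equal_weights(self):
        _, d = dynamic_threshold([7.0, 7.0, 7.0])
        assert d == 7.0

    def test_even_length_median_convention(self):
        fz, d = dynamic_threshold([2, 4, 6, 8])
        assert fz.alpha == 5 and fz.beta == 8 and d == 6.5

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            dynamic_threshold([])


class TestIteration2:
    def _mask1(self, weights):
        img = np.zeros((4, 4 * len(weights)), np.uint8)
        mask, _ = segment_iteration1(img, SegmentationConfig(threshold=1e9))
        return mask

    def test_weights_partitioned_by_d(self):
        w = np.array([[10.0, 20.0, 30.0, 40.0, 50.0]])
        mask1 = self._mask1(w[0])
        _, d = dynamic_threshold(w[mask1.blocks])
        assert d == 40.0
        mask2 = segment_iteration2(mask1, w, d)
        assert mask2.blocks.tolist() == [[True, True, True, True, False]]

    def test_equal_weights_unchanged(self):
        w = np.array([[5.0, 5.0, 5.0]])
        mask1 = self._mask1(w[0])
        _, d = dynamic_threshold(w[mask1.blocks])
        mask2 = segment_iteration2(mask1, w, d)
        assert (mask2.blocks == mask1.blocks).all()

    def test_empty_mask_stays_empty(self):
        img = np.full((8, 8), 200, np.uint8)
        mask1, w = segment_iteration1(img, SegmentationConfig(threshold=10))
        mask2 = segment_iteration2(mask1, w, 1e9)
        assert not mask2.pixels.any()

    def test_refinement_is_subset_on_random_images(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
            out = segment(img)
            assert not (out.mask2.pixels & ~out.mask1.pixels).any()
            if out.D is not None:
                sel = out.weights[out.mask1.blocks]
                assert np.median(sel) <= out.D <= sel.max()
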