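"""Two-pass graph-based lesion segmentation on 4x4 pixel blocks.

Pass I ("iteration I"): every 4x4 grayscale block is read as the
adjacency matrix of a complete 4-vertex graph — diagonal entries are
self-loops and discarded, and the two off-diagonal entries for a vertex
pair are a multi-edge collapsed to their minimum.  A spanning tree is
grown greedily from vertex 0 (always picking the cheapest edge leaving
the connected set, which yields the global minimum spanning tree on 4
vertices); the block weight W is the sum of its 3 tree edges.  Blocks
with W <= T are selected; dark homogeneous (lesion) blocks have small W.

Pass II ("iteration II"): the weights of the selected blocks define an
L-type fuzzy number with alpha = median weight and beta = maximum
weight; its defuzzified value D = (alpha + beta)/2 is a dynamic
threshold below T, and only blocks with W <= D survive.  The second
pass therefore always refines (is a subset of) the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fuzzy import LFuzzyNumber, defuzzify
from .raster import validate_image

__all__ = [
    "PixelBlock",
    "BlockGraph",
    "SegmentationConfig",
    "BlockMask",
    "partition_blocks",
    "build_block_graph",
    "mst_weight",
    "block_weights",
    "segment_iteration1",
    "dynamic_threshold",
    "segment_iteration2",
    "segment",
    "SegmentationOutcome",
]


@dataclass(frozen=True)
class PixelBlock:
    """One block-size x block-size tile of a grayscale image."""

    top_row: int
    left_col: int
    values: np.ndarray  # (k, k) uint8

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"block values must be square, got {v.shape}")
        if v.min() < 0 or v.max() > 255:
            raise ValueError("block values must lie in [0, 255]")


@dataclass(frozen=True)
class BlockGraph:
    """Complete weighted graph on k vertices; ``weights[i, j]`` = e(i, j).

    Symmetric, zero diagonal (self-loops already discarded).
    """

    weights: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]


@dataclass
class SegmentationConfig:
    """Tunables of the two-pass segmenter.

    ``threshold`` is the pass-I cutoff T; ``None`` means the scale-free
    default T = mean of all block weights of the image.
    """

    threshold: float | None = None
    block_size: int = 4

    def __post_init__(self) -> None:
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold T must be >= 0")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")


@dataclass
class BlockMask:
    """Pixel mask that exactly tiles a set of selected blocks.

    ``blocks`` is the block-level selection grid; ``pixels`` the
    congruent pixel mask with image-edge (padding) pixels excluded.
    """

    pixels: np.ndarray  # (H, W) bool
    blocks: np.ndarray  # (nbr, nbc) bool
    block_size: int
    provenance: list[tuple[int, int]] = field(default_factory=list)


def partition_blocks(gray: np.ndarray, block_size: int = 4) -> list[PixelBlock]:
    """Tile a grayscale image into non-overlapping blocks in raster order.

    Right/bottom remainders are zero-padded to full blocks.
    """
    gray = validate_image(gray)
    if gray.ndim != 2:
        raise ValueError("partition_blocks requires a single-channel image")
    h, w = gray.shape
    if h < block_size or w < block_size:
        raise ValueError(
            f"image {gray.shape} smaller than one {block_size}x{block_size} block"
        )
    blocks = []
    for r in range(0, h, block_size):
        for c in range(0, w, block_size):
            tile = gray[r : r + block_size, c : c + block_size]
            if tile.shape != (block_size, block_size):
                padded = np.zeros((block_size, block_size), dtype=np.uint8)
                padded[: tile.shape[0], : tile.shape[1]] = tile
                tile = padded
            blocks.append(PixelBlock(r, c, tile))
    return blocks


def build_block_graph(b: PixelBlock) -> BlockGraph:
    """Read a block's value grid as an adjacency matrix.

    Row i / column j = directed edge i -> j; self-loops (diagonal) are
    discarded and the (i, j)/(j, i) multi-edge is collapsed to the
    minimum of the two entries.
    """
    v = np.asarray(b.values, dtype=np.float64)
    w = np.minimum(v, v.T)
    np.fill_diagonal(w, 0.0)
    return BlockGraph(weights=w)


def mst_weight(g: BlockGraph) -> tuple[float, list[tuple[int, int]]]:
    """Greedy spanning-tree growth from vertex 0; returns (W, tree edges).

    At each step the minimum-weight edge from the connected set that
    creates no circuit is added (ties broken on the lexicographically
    smallest vertex pair), until all vertices are covered.  On a
    complete graph this greedy growth is Prim's algorithm, so W is the
    global minimum spanning-tree weight.
    """
    n = g.n_vertices
    w = g.weights
    in_tree = {0}
    edges: list[tuple[int, int]] = []
    total = 0.0
    while len(in_tree) < n:
        best: tuple[float, int, int] | None = None
        for i in sorted(in_tree):
            for j in range(n):
                if j in in_tree:
                    continue
                cand = (w[i, j], min(i, j), max(i, j))
                if best is None or cand < best:
                    best = cand
        assert best is not None
        total += best[0]
        edges.append((best[1], best[2]))
        in_tree.add(best[1])
        in_tree.add(best[2])
    return total, edges


def block_weights(gray: np.ndarray, block_size: int = 4) -> np.ndarray:
    """Per-block MST weight grid of shape (ceil(H/k), ceil(W/k))."""
    gray = validate_image(gray)
    h, w = gray.shape
    nbr = -(-h // block_size)
    nbc = -(-w // block_size)
    grid = np.zeros((nbr, nbc), dtype=np.float64)
    for blk in partition_blocks(gray, block_size):
        W, _ = mst_weight(build_block_graph(blk))
        grid[blk.top_row // block_size, blk.left_col // block_size] = W
    return grid


def _blocks_to_pixels(
    blocks: np.ndarray, shape: tuple[int, int], block_size: int
) -> np.ndarray:
    pixels = np.kron(blocks, np.ones((block_size, block_size), dtype=bool))
    return pixels[: shape[0], : shape[1]]


def segment_iteration1(
    gray: np.ndarray, cfg: SegmentationConfig | None = None
) -> tuple[BlockMask, np.ndarray]:
    """Pass I: select blocks with W <= T; returns (mask, per-block W grid)."""
    cfg = cfg or SegmentationConfig()
    gray = validate_image(gray)
    weights = block_weights(gray, cfg.block_size)
    t = cfg.threshold if cfg.threshold is not None else float(weights.mean())
    selected = weights <= t
    rows, cols = np.nonzero(selected)
    mask = BlockMask(
        pixels=_blocks_to_pixels(selected, gray.shape, cfg.block_size),
        blocks=selected,
        block_size=cfg.block_size,
        provenance=[
            (int(r) * cfg.block_size, int(c) * cfg.block_size)
            for r, c in zip(rows, cols)
        ],
    )
    return mask, weights


def dynamic_threshold(weights_selected) -> tuple[LFuzzyNumber, float]:
    """Fuzzy dynamic threshold from the selected-block weights.

    alpha = median weight, beta = maximum weight; D = (alpha + beta)/2.
    Even-length medians use the mean-of-middle-two convention.
    """
    w = np.asarray(list(weights_selected), dtype=np.float64)
    if w.size == 0:
        raise ValueError("iteration I selected no blocks; cannot form a threshold")
    alpha = float(np.median(w))
    beta = float(w.max())
    fz = LFuzzyNumber(alpha=alpha, beta=beta)
    return fz, defuzzify(fz)


def segment_iteration2(mask1: BlockMask, weights: np.ndarray, d: float) -> BlockMask:
    """Pass II: keep only pass-I blocks with W <= D (a subset of pass I)."""
    selected = mask1.blocks & (weights <= d)
    rows, cols = np.nonzero(selected)
    k = mask1.block_size
    return BlockMask(
        pixels=_blocks_to_pixels(selected, mask1.pixels.shape, k),
        blocks=selected,
        block_size=k,
        provenance=[(int(r) * k, int(c) * k) for r, c in zip(rows, cols)],
    )


@dataclass
class SegmentationOutcome:
    """Both passes of the segmenter plus the resolved thresholds."""

    mask1: BlockMask
    mask2: BlockMask
    weights: np.ndarray
    T: float
    fuzzy: LFuzzyNumber | None
    D: float | None


def segment(
    gray: np.ndarray, cfg: SegmentationConfig | None = None, single_pass: bool = False
) -> SegmentationOutcome:
    """Run both segmentation passes; pass II is skipped when nothing is
    selected in pass I or ``single_pass`` is set."""
    cfg = cfg or SegmentationConfig()
    mask1, weights = segment_iteration1(gray, cfg)
    t = cfg.threshold if cfg.threshold is not None else float(weights.mean())
    if single_pass or not mask1.blocks.any():
        return SegmentationOutcome(mask1, mask1, weights, t, None, None)
    fz, d = dynamic_threshold(weights[mask1.blocks])
    mask2 = segment_iteration2(mask1, weights, d)
    return SegmentationOutcome(mask1, mask2, weights, t, fz, d)
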