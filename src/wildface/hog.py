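"""Gradient-orientation-histogram (HOG) features shared by detector and embedder.

Thin wrapper over :func:`skimage.feature.hog` that keeps the block grid
(rather than a flat vector) so a sliding window can be scored directly on
the grid of an image pyramid level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import hog as _skimage_hog

__all__ = ["HogParams", "extract_hog", "window_feature_length", "window_features"]

CELLS_PER_BLOCK = 2  # 2x2-cell blocks throughout


@dataclass(frozen=True)
class HogParams:
    """Cell/block/orientation layout of the descriptor.

    ``window_cells`` is the sliding-window extent in cells; the physical
    window is ``window_cells * cell_size`` pixels.
    """

    cell_size: int = 8
    n_orientations: int = 9
    block_norm: str = "L2-Hys"
    window_cells: tuple[int, int] = (6, 6)  # (rows, cols)

    @property
    def window_px(self) -> tuple[int, int]:
        return (self.window_cells[0] * self.cell_size, self.window_cells[1] * self.cell_size)


def extract_hog(image: np.ndarray, params: HogParams) -> np.ndarray:
    """Block-normalized orientation histograms on the cell grid.

    Returns an array of shape ``(n_blocks_r, n_blocks_c, 2, 2,
    n_orientations)``; every normalized block has L2 norm <= 1 (up to
    floating error), and a constant image yields all zeros.
    """
    h, w = image.shape
    if h < params.cell_size or w < params.cell_size:
        raise ValueError(
            f"image {w}x{h} is smaller than one {params.cell_size}px cell"
        )
    return _skimage_hog(
        image,
        orientations=params.n_orientations,
        pixels_per_cell=(params.cell_size, params.cell_size),
        cells_per_block=(CELLS_PER_BLOCK, CELLS_PER_BLOCK),
        block_norm=params.block_norm,
        feature_vector=False,
    )


def window_feature_length(params: HogParams) -> int:
    br = params.window_cells[0] - CELLS_PER_BLOCK + 1
    bc = params.window_cells[1] - CELLS_PER_BLOCK + 1
    return br * bc * CELLS_PER_BLOCK * CELLS_PER_BLOCK * params.n_orientations


def window_features(grid: np.ndarray, params: HogParams) -> np.ndarray:
    """All window feature vectors of a HOG grid.

    Returns shape ``(n_window_rows, n_window_cols, F)`` where the window at
    position (i, j) starts at cell (i, j) of the level image.
    """
    br = params.window_cells[0] - CELLS_PER_BLOCK + 1
    bc = params.window_cells[1] - CELLS_PER_BLOCK + 1
    nbr, nbc = grid.shape[:2]
    if nbr < br or nbc < bc:
        return np.zeros((0, 0, window_feature_length(params)))
    view = np.lib.stride_tricks.sliding_window_view(grid, (br, bc), axis=(0, 1))
    # view: (nwr, nwc, 2, 2, orient, br, bc) -> move window block dims forward
    view = np.moveaxis(view, (5, 6), (2, 3))
    nwr, nwc = view.shape[:2]
    return view.reshape(nwr, nwc, -1)
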