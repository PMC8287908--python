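"""Conversion between spot coordinate lists and grid-cell tensors.

The image is tiled into ``cell_size`` x ``cell_size`` cells.  Each cell
carries three values: the probability that it contains a spot, and the
spot's within-cell (row, col) offsets normalized to [0, 1).  The
coordinate convention is (row, col) with the origin at the top-left and
the center of pixel (i, j) at exactly (i, j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridTensor", "encode_coordinates", "decode_grid"]


@dataclass
class GridTensor:
    """A (H/cs, W/cs, 3) grid: channel 0 spot probability, 1-2 offsets."""

    cells: np.ndarray
    cell_size: int

    def __post_init__(self):
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 3 or self.cells.shape[-1] != 3:
            raise ValueError("cells must have shape (h, w, 3)")

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.cells.shape[0] * self.cell_size,
                self.cells.shape[1] * self.cell_size)


def _check_cell_size(cell_size: int) -> None:
    if cell_size < 1 or (cell_size & (cell_size - 1)):
        raise ValueError(f"cell_size must be a power of two >= 1, got {cell_size}")


def encode_coordinates(coords, image_shape: tuple[int, int],
                       cell_size: int = 4) -> GridTensor:
    """Encode sub-pixel spot coordinates into a grid-cell target tensor.

    Each spot sets p=1 in its cell and stores its fractional position
    within the cell.  A cell can represent only one spot: on collision the
    spot closest to the cell center wins, remaining ties broken by
    row-major coordinate order.

    Parameters
    ----------
    coords : array-like of shape (n, 2)
        Sub-pixel (row, col) positions, inside the image.
    image_shape : (height, width)
        Must be divisible by ``cell_size``.
    cell_size : int
        Power-of-two side length of one grid-cell in pixels.
    """
    _check_cell_size(cell_size)
    h, w = int(image_shape[0]), int(image_shape[1])
    if h % cell_size or w % cell_size:
        raise ValueError(
            f"image shape ({h},{w}) not divisible by cell_size {cell_size}"
        )
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
    cells = np.zeros((h // cell_size, w // cell_size, 3), dtype=np.float64)
    if coords.size == 0:
        return GridTensor(cells, cell_size)
    if (coords < 0).any() or (coords[:, 0] >= h).any() or (coords[:, 1] >= w).any():
        raise ValueError("coordinates out of image bounds")

    # stable tie-break: process in row-major coordinate order, keep the
    # first spot for a cell unless a later one is strictly closer to the
    # cell center (offset 0.5, 0.5)
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    best: dict[tuple[int, int], float] = {}
    for idx in order:
        r, c = coords[idx]
        ci, cj = int(r // cell_size), int(c // cell_size)
        off_r = (r - ci * cell_size) / cell_size
        off_c = (c - cj * cell_size) / cell_size
        d2 = (off_r - 0.5) ** 2 + (off_c - 0.5) ** 2
        key = (ci, cj)
        if key in best and d2 >= best[key]:
            continue
        best[key] = d2
        cells[ci, cj] = (1.0, off_r, off_c)
    return GridTensor(cells, cell_size)


def decode_grid(grid, cell_size: int | None = None,
                prob_threshold: float = 0.5) -> np.ndarray:
    """Decode a grid tensor back into sub-pixel (row, col) coordinates.

    Every cell whose probability is >= ``prob_threshold`` emits one
    coordinate ``cell_index * cs + offset * cs``, in row-major cell order.

    ``grid`` may be a :class:`GridTensor` or a raw (h, w, 3) array with
    ``cell_size`` given explicitly.
    """
    if isinstance(grid, GridTensor):
        cells, cs = grid.cells, grid.cell_size
    else:
        if cell_size is None:
            raise ValueError("cell_size required when passing a raw array")
        cells, cs = np.asarray(grid), cell_size
    _check_cell_size(cs)
    if not 0.0 <= prob_threshold <= 1.0:
        raise ValueError("prob_threshold must be in [0, 1]")
    if cells.ndim != 3 or cells.shape[-1] != 3:
        raise ValueError("grid must have shape (h, w, 3)")
    ci, cj = np.nonzero(cells[..., 0] >= prob_threshold)
    rows = ci * cs + cells[ci, cj, 1] * cs
    cols = cj * cs + cells[ci, cj, 2] * cs
    return np.column_stack([rows, cols]).astype(np.float64)
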