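"""Probe grid geometry for the visually guided saccade task.

Probes flash one at a time on a rectangular lattice of candidate locations
covering the fixation points (FP1, FP2) and the neuron's receptive field
before (RF1) and after (RF2) the saccade.  Cells are addressed by a flat
0-based, column-major index: ``cell = col * n_rows + row``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProbeGrid"]


@dataclass(frozen=True)
class ProbeGrid:
    """Rectangular lattice of probe locations.

    Parameters
    ----------
    n_cols, n_rows : int
        Grid dimensions (the task uses 9 x 9).
    spacing_x, spacing_y : float
        Center-to-center probe spacing in degrees of visual angle.
    rf1_index, rf2_index : int
        Flat cell indices of the pre- and post-saccadic receptive-field
        centers.  Must differ.
    fp1_index, fp2_index : int
        Flat cell indices of the central fixation point and the saccade
        target.
    """

    n_cols: int = 9
    n_rows: int = 9
    spacing_x: float = 5.0
    spacing_y: float = 5.0
    rf1_index: int = 22   # col 2, row 4 on the default 9x9 grid
    rf2_index: int = 58   # col 6, row 4
    fp1_index: int = 40   # center cell
    fp2_index: int = 76   # col 8, row 4

    def __post_init__(self) -> None:
        n = self.n_cells
        for name in ("rf1_index", "rf2_index", "fp1_index", "fp2_index"):
            idx = getattr(self, name)
            if not 0 <= idx < n:
                raise ValueError(f"{name}={idx} outside grid of {n} cells")
        if self.rf1_index == self.rf2_index:
            raise ValueError("rf1_index and rf2_index must differ")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def control_indices(self) -> np.ndarray:
        """Cells outside the RF1 and RF2 neighborhoods (candidate controls)."""
        excluded = set(self.neighborhood(self.rf1_index)) | set(
            self.neighborhood(self.rf2_index)
        )
        return np.array(
            [c for c in range(self.n_cells) if c not in excluded], dtype=np.intp
        )

    def cell(self, col: int, row: int) -> int:
        """Flat index of (col, row)."""
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise ValueError(f"({col}, {row}) outside {self.n_cols}x{self.n_rows} grid")
        return col * self.n_rows + row

    def col_row(self, cell: int) -> tuple[int, int]:
        """Inverse of :meth:`cell`."""
        if not 0 <= cell < self.n_cells:
            raise ValueError(f"cell {cell} outside grid")
        return cell // self.n_rows, cell % self.n_rows

    def coordinates(self, cell: int) -> tuple[float, float]:
        """Visual-field coordinates (dva) of a cell, grid-centered."""
        col, row = self.col_row(cell)
        x = (col - (self.n_cols - 1) / 2) * self.spacing_x
        y = (row - (self.n_rows - 1) / 2) * self.spacing_y
        return x, y

    def is_interior(self, cell: int) -> bool:
        col, row = self.col_row(cell)
        return 0 < col < self.n_cols - 1 and 0 < row < self.n_rows - 1

    def neighborhood(self, cell: int, include_center: bool = True) -> np.ndarray:
        """Flat indices of the (up to) 3x3 block of cells around ``cell``.

        Edge cells return a clipped neighborhood.  Row-major within the
        block, deterministic order.
        """
        col, row = self.col_row(cell)
        out = []
        for dc in (-1, 0, 1):
            for dr in (-1, 0, 1):
                if not include_center and dc == 0 and dr == 0:
                    continue
                c, r = col + dc, row + dr
                if 0 <= c < self.n_cols and 0 <= r < self.n_rows:
                    out.append(self.cell(c, r))
        return np.array(out, dtype=np.intp)

    def neighbors(self, cell: int) -> np.ndarray:
        """The 8 surrounding cells (errors if the cell is not interior)."""
        if not self.is_interior(cell):
            raise ValueError(
                f"cell {cell} is on the grid edge; 8-neighborhood undefined"
            )
        return self.neighborhood(cell, include_center=False)
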