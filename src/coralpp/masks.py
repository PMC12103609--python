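"""Substrate category masks.

The study classifies the seabed inside each quadrat into three substrate
categories: elevated boulders, flat rock, and debris-filled gulleys. A
:class:`CategoryMask` stores that classification on a regular grid aligned
with the observation window (row 0 = bottom of the window, matching the
y-up coordinate convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Window

#: Canonical substrate categories, in code order.
CATEGORIES = ("boulder", "flat", "gulley")


@dataclass(frozen=True)
class CategoryMask:
    """Piecewise-constant substrate classification of a window.

    ``grid`` holds integer category codes (indices into ``categories``),
    shape (n_rows, n_cols); cell (0, 0) is the lower-left corner cell.
    """

    grid: np.ndarray
    window: Window
    categories: tuple = CATEGORIES

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if grid.min(initial=0) < 0 or (grid.size and grid.max() >= len(self.categories)):
            raise ValueError("mask grid contains codes outside the category list")
        object.__setattr__(self, "grid", grid.astype(np.int16))

    @property
    def cell_height(self) -> float:
        return self.window.height / self.grid.shape[0]

    @property
    def cell_width(self) -> float:
        return self.window.width / self.grid.shape[1]

    @property
    def cell_area(self) -> float:
        return self.cell_width * self.cell_height

    def category_areas(self) -> dict:
        """Area (cm^2) covered by each category; sums to the window area."""
        counts = np.bincount(self.grid.ravel(), minlength=len(self.categories))
        return {c: counts[i] * self.cell_area for i, c in enumerate(self.categories)}

    def category_at(self, x, y) -> np.ndarray:
        """Category code of the cell containing each point (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.clip((x / self.cell_width).astype(int), 0, self.grid.shape[1] - 1)
        row = np.clip((y / self.cell_height).astype(int), 0, self.grid.shape[0] - 1)
        return self.grid[row, col]

    def intensity_map(self, per_category: dict) -> np.ndarray:
        """Cell-wise intensity surface from per-category intensities."""
        lam = np.zeros(len(self.categories))
        for i, c in enumerate(self.categories):
            lam[i] = per_category.get(c, 0.0)
        return lam[self.grid]


def uniform_mask(window: Window, category: str = "flat", cell_size: float = 0.5) -> CategoryMask:
    """A mask assigning the whole window to a single category."""
    nrows = max(1, int(round(window.height / cell_size)))
    ncols = max(1, int(round(window.width / cell_size)))
    code = CATEGORIES.index(category)
    return CategoryMask(np.full((nrows, ncols), code), window)
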