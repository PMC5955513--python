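"""Square-cell tessellation of the study extent and point-in-cell counts.

Cells are half-open intervals ``[lower, upper)`` in both x and y, except
that points landing exactly on the grid's top/right outer boundary are
assigned to the last cell, so no point on the hull of the extent is lost.
Row index 0 is the southernmost row (smallest y).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import ProjectedPoints

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned grid of square cells.

    ``x_min, y_min`` are the coordinates of the lower-left corner in
    metres; the grid spans ``n_cols`` x ``n_rows`` cells of ``cell_size``
    metres.
    """

    x_min: float
    y_min: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Centroid coordinate arrays ``(cx[n_cols], cy[n_rows])``."""
        cx = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        cy = self.y_min + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return cx, cy

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map coordinates to ``(row, col, inside)`` arrays.

        Half-open cells; the extreme top/right boundary is closed.  The
        ``inside`` mask flags points within the grid extent; row/col for
        outside points are clipped and should be ignored.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        col = np.floor((x - self.x_min) / self.cell_size).astype(int)
        row = np.floor((y - self.y_min) / self.cell_size).astype(int)
        inside = ((x >= self.x_min) & (x <= self.x_max)
                  & (y >= self.y_min) & (y <= self.y_max))
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col, inside

    def cell_polygon(self, row: int, col: int) -> list[list[float]]:
        """Closed ring of the cell's corners (counter-clockwise)."""
        x0 = self.x_min + col * self.cell_size
        y0 = self.y_min + row * self.cell_size
        s = self.cell_size
        return [[x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s], [x0, y0]]


@dataclass
class CellCounts:
    """Per-cell event counts on a :class:`GridSpec`.

    ``counts`` has shape ``(n_rows, n_cols)``; ``n_dropped`` counts points
    that fell outside the grid extent.
    """

    grid: GridSpec
    counts: np.ndarray
    n_dropped: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def cell_size_from_extent(longest_side: float, divisor: int = 100,
                          round_to: float = 10) -> float:
    """Cell size rule: longest side of the study area over ``divisor``,
    rounded to the nearest ``round_to`` metres (half rounds up, so a
    42,750 m side gives 430 m cells)."""
    if longest_side <= 0 or divisor <= 0 or round_to <= 0:
        raise ValueError("longest_side, divisor and round_to must be positive")
    raw = longest_side / divisor
    return float(np.floor(raw / round_to + 0.5) * round_to)


def make_grid(points: ProjectedPoints, cell_size: float) -> GridSpec:
    """Minimal grid of ``cell_size`` cells covering the points' bounding box.

    The origin is the bounding-box minimum corner; column/row counts are
    ceiling divisions of the spans (at least 1).
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    if points.n == 0:
        raise ValueError("cannot build a grid from an empty point set")
    x_min, y_min = float(points.x.min()), float(points.y.min())
    span_x = float(points.x.max()) - x_min
    span_y = float(points.y.max()) - y_min
    n_cols = max(1, int(np.ceil(span_x / cell_size - 1e-12)))
    n_rows = max(1, int(np.ceil(span_y / cell_size - 1e-12)))
    return GridSpec(x_min=x_min, y_min=y_min, cell_size=cell_size,
                    n_cols=n_cols, n_rows=n_rows)


def bin_points(points: ProjectedPoints, grid: GridSpec) -> CellCounts:
    """Count points per grid cell (half-open cells, top/right edge closed).

    Points outside the grid extent are dropped with a logged count; the
    counts of covered points are conserved exactly.
    """
    row, col, inside = grid.cell_index(points.x, points.y)
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=np.int64)
    np.add.at(counts, (row[inside], col[inside]), 1)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("bin_points: %d points outside the grid extent dropped",
                       n_dropped)
    return CellCounts(grid=grid, counts=counts, n_dropped=n_dropped)


def counts_to_csv(cells: CellCounts, path) -> None:
    """Write per-cell counts as CSV columns row, col, count."""
    rows, cols = np.nonzero(np.ones_like(cells.counts))
    pd.DataFrame({"row": rows, "col": cols,
                  "count": cells.counts[rows, cols]}).to_csv(path, index=False)


def counts_to_geojson(cells: CellCounts, path, attributes: dict | None = None) -> None:
    """Write cells as GeoJSON polygons (planar coordinates) with a ``count``
    property; ``attributes`` may add extra per-cell arrays keyed by name."""
    attributes = attributes or {}
    feats = []
    for r in range(cells.grid.n_rows):
        for c in range(cells.grid.n_cols):
            props = {"row": r, "col": c, "count": int(cells.counts[r, c])}
            for name, arr in attributes.items():
                v = arr[r, c]
                props[name] = v.item() if hasattr(v, "item") else v
            feats.append({"type": "Feature",
                          "geometry": {"type": "Polygon",
                                       "coordinates": [cells.grid.cell_polygon(r, c)]},
                          "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
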