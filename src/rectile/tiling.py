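"""Rectangular tile grid with neighbor-pooled training samples.

The study extent is partitioned into equal-area rectangular tiles
(default 3 rows x 5 columns = 15 tiles, row-major ids from the top-left).
Each tile's classifier is trained on the samples falling in the tile itself
plus its queen-contiguous (8-neighbor) tiles, which localizes the training
distribution while keeping per-tile sample counts workable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from .errors import ExtentError, ParameterError
from .raster import CLASSES, SamplePoint


@dataclass(frozen=True)
class TileGrid:
    """Equal-area rectangular partition of a map extent.

    Tile cells are half-open on their east and south edges except that the
    last column/row is closed, so the tiles partition the extent exactly.
    """

    extent: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    n_rows: int = 3
    n_cols: int = 5

    def __post_init__(self) -> None:
        x_min, y_min, x_max, y_max = self.extent
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParameterError("grid dimensions must be >= 1")
        if x_max <= x_min or y_max <= y_min:
            raise ParameterError("degenerate extent")

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def tile_width(self) -> float:
        return (self.extent[2] - self.extent[0]) / self.n_cols

    @property
    def tile_height(self) -> float:
        return (self.extent[3] - self.extent[1]) / self.n_rows

    def tile_bounds(self, tile_id: int) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of one tile."""
        self._check_id(tile_id)
        r, c = divmod(tile_id, self.n_cols)
        x_min = self.extent[0] + c * self.tile_width
        y_max = self.extent[3] - r * self.tile_height
        return (x_min, y_max - self.tile_height, x_min + self.tile_width, y_max)

    def _check_id(self, tile_id: int) -> None:
        if not 0 <= tile_id < self.n_tiles:
            raise ParameterError(
                f"tile id {tile_id} outside 0..{self.n_tiles - 1}"
            )


def make_grid(
    extent: tuple[float, float, float, float], n_rows: int = 3, n_cols: int = 5
) -> TileGrid:
    """Equal-width, equal-height tile grid over an extent."""
    return TileGrid(tuple(extent), n_rows, n_cols)


def tile_of_point(grid: TileGrid, x: float, y: float) -> int:
    """Row-major id of the tile containing a point.

    Interior tile edges resolve by the half-open rule (a point on a vertical
    edge belongs to the tile on its right, on a horizontal edge to the tile
    below); the extent's own boundary is inclusive.
    """
    x_min, y_min, x_max, y_max = grid.extent
    if not (x_min <= x <= x_max and y_min <= y <= y_max):
        raise ExtentError(f"point ({x}, {y}) outside grid extent")
    c = min(int((x - x_min) / grid.tile_width), grid.n_cols - 1)
    r = min(int((y_max - y) / grid.tile_height), grid.n_rows - 1)
    return r * grid.n_cols + c


def neighbors(grid: TileGrid, tile_id: int) -> set[int]:
    """Queen-contiguity neighborhood of a tile, including the tile itself."""
    grid._check_id(tile_id)
    r, c = divmod(tile_id, grid.n_cols)
    out = set()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                out.add(rr * grid.n_cols + cc)
    return out


def pooled_training(
    grid: TileGrid,
    tile_id: int,
    samples: Sequence[SamplePoint],
    per_class_floor: int = 0,
    per_class_cap: int | None = None,
    seed: int = 0,
    fallback_global: bool = False,
) -> list[SamplePoint]:
    """Training samples pooled from a tile and its adjacent tiles.

    Takes the ``train``-split samples whose containing tile is in
    ``neighbors(grid, tile_id)``.  Duplicate points are retained.

    With ``fallback_global``, a class absent from the pool (or below
    ``per_class_floor``) is topped up from the full study area, so every
    tile model knows all classes present anywhere; the tiled classifier
    enables this.  ``per_class_cap`` subsamples over-represented classes
    with a seeded RNG.
    """
    nb = neighbors(grid, tile_id)
    train = [p for p in samples if p.split == "train"]
    pool = [p for p in train if tile_of_point(grid, p.x, p.y) in nb]
    by_class: dict[str, list[SamplePoint]] = {c: [] for c in CLASSES}
    for p in pool:
        by_class[p.label].append(p)
    rng = random.Random(seed)
    out: list[SamplePoint] = []
    for cls in CLASSES:
        members = list(by_class[cls])
        floor = max(per_class_floor, 1)
        if fallback_global and len(members) < floor:
            in_pool = set(id(p) for p in members)
            extra = [
                p for p in train
                if p.label == cls and id(p) not in in_pool
            ]
            if per_class_floor > 0:
                members += extra[: floor - len(members)]
            elif not members:
                members = extra
        if per_class_cap is not None and len(members) > per_class_cap:
            members = rng.sample(members, per_class_cap)
        out.extend(members)
    return out


def grid_geojson(grid: TileGrid) -> dict:
    """Tile boundaries as a GeoJSON FeatureCollection (for inspection)."""
    feats = []
    for t in range(grid.n_tiles):
        x0, y0, x1, y1 = grid.tile_bounds(t)
        feats.append(
            {
                "type": "Feature",
                "properties": {"tile_id": t},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                    ],
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
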