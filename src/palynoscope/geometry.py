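"""Tiled SEM montage geometry.

A montage is a rectangular grid of partially overlapping SEM images
(tiles).  Each tile has a fixed pixel raster and a horizontal field of
view in micrometres; neighbouring tiles share an overlap strip whose
width is a fixed fraction of the tile extent on each axis.  This module
models the montage coordinate frame (origin at the top-left corner of
the top-left tile, x rightward, y downward, micrometre units, 0-based
tile indices, closed tile intervals), converts between tile-local and
montage-global coordinates, and computes the acquisition budget:
pixel pitch, montage extent, unique imaged area and imaging time.

Extents are reported with the rounding convention used for survey
summaries: per-axis extents rounded to 0.1 mm, the per-montage area as
the product of the rounded extents (to 3 decimals in cm**2), and the
dataset total as the sum of those products rounded to 2 decimals.
Unrounded values are exposed alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "TileGrid",
    "Point",
    "TileIndex",
    "TileFootprint",
    "MontageExtent",
    "DatasetTotals",
    "tile_footprint",
    "montage_extent",
    "local_to_global",
    "global_to_tile_local",
    "tiles_covering",
    "dataset_totals",
]


class Point(NamedTuple):
    """A position in micrometres, montage-global unless stated otherwise."""

    x_um: float
    y_um: float


class TileIndex(NamedTuple):
    """0-based (column, row) position of a tile in the montage grid."""

    col: int
    row: int


@dataclass(frozen=True)
class TileGrid:
    """Acquisition geometry of one tiled montage.

    Parameters
    ----------
    n_cols, n_rows:
        Grid dimensions in tiles.
    tile_px_x, tile_px_y:
        Pixel raster of a single tile.
    fov_width_um:
        Horizontal field of view of one tile, in micrometres.  The tile
        height follows from the pixel aspect ratio (square pixels).
    overlap_frac:
        Fraction of the tile extent shared with each neighbouring tile,
        applied identically on both axes.
    dwell_s_per_image:
        Acquisition time per tile in seconds.
    """

    n_cols: int
    n_rows: int
    tile_px_x: int
    tile_px_y: int
    fov_width_um: float
    overlap_frac: float = 0.0
    dwell_s_per_image: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one tile per axis")
        if self.tile_px_x < 1 or self.tile_px_y < 1:
            raise ValueError("tile pixel dimensions must be >= 1")
        if not (0.0 <= self.overlap_frac < 1.0):
            raise ValueError("overlap_frac must be in [0, 1)")
        if not self.fov_width_um > 0:
            raise ValueError("fov_width_um must be positive")
        if self.dwell_s_per_image < 0:
            raise ValueError("dwell_s_per_image must be >= 0")

    # -- derived tile quantities ------------------------------------------

    @property
    def pixel_pitch_um(self) -> float:
        return self.fov_width_um / self.tile_px_x

    @property
    def tile_width_um(self) -> float:
        return self.fov_width_um

    @property
    def tile_height_um(self) -> float:
        return self.tile_px_y * self.pixel_pitch_um

    @property
    def step_x_um(self) -> float:
        """Stage step between neighbouring tile origins, x axis."""
        return self.tile_width_um * (1.0 - self.overlap_frac)

    @property
    def step_y_um(self) -> float:
        return self.tile_height_um * (1.0 - self.overlap_frac)

    @property
    def n_images(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def width_um(self) -> float:
        """Unrounded montage width."""
        return _axis_extent(self.tile_width_um, self.n_cols, self.overlap_frac)

    @property
    def height_um(self) -> float:
        return _axis_extent(self.tile_height_um, self.n_rows, self.overlap_frac)

    @property
    def area_cm2(self) -> float:
        """Unrounded unique imaged area in cm**2."""
        return self.width_um * self.height_um / 1e8

    def contains(self, p: Point) -> bool:
        return 0.0 <= p.x_um <= self.width_um and 0.0 <= p.y_um <= self.height_um

    def validate_tile(self, tile: TileIndex) -> None:
        if not (0 <= tile.col < self.n_cols and 0 <= tile.row < self.n_rows):
            raise IndexError(
                f"tile {tile} outside {self.n_cols}x{self.n_rows} grid"
            )

    def all_tiles(self) -> Iterable[TileIndex]:
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield TileIndex(col, row)


def _axis_extent(tile_um: float, n: int, overlap: float) -> float:
    return tile_um * (1.0 + (n - 1) * (1.0 - overlap))


class TileFootprint(NamedTuple):
    width_um: float
    height_um: float
    pixel_pitch_nm: float


def tile_footprint(grid: TileGrid) -> TileFootprint:
    """Physical size of a single tile and its pixel pitch in nanometres."""
    pitch_um = grid.pixel_pitch_um
    return TileFootprint(grid.tile_width_um, grid.tile_px_y * pitch_um, pitch_um * 1000.0)


class MontageExtent(NamedTuple):
    """Montage extent with both reported (rounded) and exact values."""

    width_mm: float          # rounded to 0.1 mm
    height_mm: float         # rounded to 0.1 mm
    area_cm2: float          # product of rounded extents, rounded to 3 dp
    width_um_exact: float
    height_um_exact: float
    area_cm2_exact: float
    area_cm2_from_rounded: float  # product of rounded extents, unrounded


def montage_extent(grid: TileGrid) -> MontageExtent:
    """Overall montage extent and unique imaged area.

    Per axis, extent = tile_extent * (1 + (n - 1) * (1 - overlap_frac)).
    Reported extents are rounded to 0.1 mm and the reported area is the
    product of the rounded extents converted to cm**2 (3 decimals);
    exact values are returned alongside.
    """
    w_um, h_um = grid.width_um, grid.height_um
    w_mm, h_mm = round(w_um / 1000.0, 1), round(h_um / 1000.0, 1)
    area_rounded = w_mm * h_mm / 100.0  # mm**2 -> cm**2
    return MontageExtent(
        width_mm=w_mm,
        height_mm=h_mm,
        area_cm2=round(area_rounded, 3),
        width_um_exact=w_um,
        height_um_exact=h_um,
        area_cm2_exact=w_um * h_um / 1e8,
        area_cm2_from_rounded=area_rounded,
    )


def local_to_global(grid: TileGrid, tile: TileIndex, local: Point) -> Point:
    """Map a tile-local position to the montage-global frame."""
    grid.validate_tile(tile)
    if not (0.0 <= local.x_um <= grid.tile_width_um and 0.0 <= local.y_um <= grid.tile_height_um):
        raise ValueError(f"local point {local} outside tile footprint")
    return Point(tile.col * grid.step_x_um + local.x_um, tile.row * grid.step_y_um + local.y_um)


def global_to_tile_local(grid: TileGrid, tile: TileIndex, p: Point) -> Point:
    """Inverse of :func:`local_to_global` for the same tile."""
    grid.validate_tile(tile)
    return Point(p.x_um - tile.col * grid.step_x_um, p.y_um - tile.row * grid.step_y_um)


def _covering_indices(x: float, tile_um: float, step_um: float, n: int) -> range:
    # closed interval [i*step, i*step + tile] contains x
    if step_um <= 0.0:  # degenerate single-column/row guard (overlap < 1 so step > 0)
        return range(0, n)
    lo = max(0, math.ceil((x - tile_um) / step_um - 1e-9))
    hi = min(n - 1, math.floor(x / step_um + 1e-9))
    return range(lo, hi + 1)


def tiles_covering(grid: TileGrid, p: Point) -> frozenset[TileIndex]:
    """All tiles whose footprint contains ``p`` (closed intervals).

    Interior points lie in exactly one tile; points in a one-axis
    overlap strip in two; points in a four-tile overlap corner in four.
    A point outside the montage yields the empty set.
    """
    if not grid.contains(p):
        return frozenset()
    cols = _covering_indices(p.x_um, grid.tile_width_um, grid.step_x_um, grid.n_cols)
    rows = _covering_indices(p.y_um, grid.tile_height_um, grid.step_y_um, grid.n_rows)
    return frozenset(TileIndex(c, r) for c in cols for r in rows)


class DatasetTotals(NamedTuple):
    n_images: int
    total_area_cm2: float            # sum of reported per-montage areas, 2 dp
    acquisition_hours: tuple[float, ...]  # per montage
    total_area_cm2_exact: float


def dataset_totals(grids: Sequence[TileGrid]) -> DatasetTotals:
    """Image count, unique imaged area and per-montage imaging time.

    The reported total area sums each montage's rounded-extent area
    (see :func:`montage_extent`) and rounds the sum to 2 decimals;
    acquisition time per montage is n_images * dwell / 3600 hours.
    """
    if not grids:
        raise ValueError("dataset_totals requires at least one montage")
    extents = [montage_extent(g) for g in grids]
    return DatasetTotals(
        n_images=sum(g.n_images for g in grids),
        total_area_cm2=round(sum(e.area_cm2_from_rounded for e in extents), 2),
        acquisition_hours=tuple(g.n_images * g.dwell_s_per_image / 3600.0 for g in grids),
        total_area_cm2_exact=sum(e.area_cm2_exact for e in extents),
    )
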