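"""Raster grid containers shared across the sampling pipeline.

Both grids use a north-up convention: row 0 is the northmost row, col 0 the
westmost column.  ``origin_x``/``origin_y`` are the coordinates of the grid's
west and north edges.  Cell extents are half-open ``[west, east) x [south,
north)``; cell centres sit at the middle of each cell.  Missing data is
represented as NaN in the ``values`` array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PopulationGrid",
    "ZoneGrid",
    "GridAlignmentError",
    "check_aligned",
]

#: Mean Earth radius in metres, used to turn degree-sized cells into ground
#: distances when the georeference looks geographic.
EARTH_RADIUS_M = 6_371_008.8

_GEOGRAPHIC_HINTS = ("4326", "wgs 84", "wgs84", "degree", "longlat", "geographic")


class GridAlignmentError(ValueError):
    """Raised when companion rasters do not share shape and georeference."""


@dataclass
class _BaseGrid:
    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_width: float = 1.0
    cell_height: float = 1.0
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if self.cell_width <= 0 or self.cell_height <= 0:
            raise ValueError("cell_width and cell_height must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing cells."""
        return np.isnan(self.values)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the centre of cell ``(row, col)``."""
        x = self.origin_x + (col + 0.5) * self.cell_width
        y = self.origin_y - (row + 0.5) * self.cell_height
        return x, y

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_width

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_height

    def is_geographic(self) -> bool:
        """Heuristic: does the georeference look like decimal degrees?

        True when the CRS label names a geographic system, or (with no label)
        when the extent fits inside lon/lat bounds with sub-0.1-unit cells.
        """
        label = self.crs_label.lower()
        if label:
            return any(h in label for h in _GEOGRAPHIC_HINTS)
        if self.cell_width >= 0.1 or self.cell_height >= 0.1:
            return False
        east = self.origin_x + self.n_cols * self.cell_width
        south = self.origin_y - self.n_rows * self.cell_height
        return (
            -180.0 <= self.origin_x <= 180.0
            and -180.0 <= east <= 180.0
            and -90.0 <= south <= 90.0
            and -90.0 <= self.origin_y <= 90.0
        )

    def centroid_cell_ground_size(self) -> tuple[float, float]:
        """Ground (metre) extents of the grid's central cell.

        Projected grids are assumed to be in metres.  Geographic grids use a
        spherical approximation at the central cell's latitude, mirroring the
        use of the centroid cell as the representative cell of the study area.
        """
        if not self.is_geographic():
            return float(self.cell_width), float(self.cell_height)
        _, lat = self.cell_center(self.n_rows // 2, self.n_cols // 2)
        m_per_deg = EARTH_RADIUS_M * math.pi / 180.0
        width = self.cell_width * m_per_deg * math.cos(math.radians(lat))
        height = self.cell_height * m_per_deg
        return float(width), float(height)

    def cell_area_km2(self) -> float:
        """Ground area of the centroid cell in km^2 (used for all cells)."""
        w, h = self.centroid_cell_ground_size()
        return w * h / 1e6


@dataclass
class PopulationGrid(_BaseGrid):
    """Gridded population estimates: one nonnegative person count per cell."""

    def __post_init__(self) -> None:
        super().__post_init__()
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("population values must be >= 0 where not missing")

    def total_population(self) -> float:
        return float(np.nansum(self.values))


@dataclass
class ZoneGrid(_BaseGrid):
    """Integer zone identifiers (strata or urban flags) on the same grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        valid = self.values[~np.isnan(self.values)]
        if valid.size and not np.allclose(valid, np.round(valid)):
            raise ValueError("zone values must be integers where not missing")

    def zone_ids(self) -> list[int]:
        """Sorted distinct zone ids present in the grid."""
        valid = self.values[~np.isnan(self.values)]
        return sorted(int(v) for v in np.unique(valid))

    def with_values(self, values: np.ndarray) -> "ZoneGrid":
        return replace(self, values=np.asarray(values, dtype=np.float64))


def check_aligned(reference: _BaseGrid, *others: _BaseGrid) -> None:
    """Verify companion grids share shape and georeference with ``reference``.

    Raises :class:`GridAlignmentError` otherwise — the caller is expected to
    have rasterized all vector inputs onto the population grid beforehand.
    """
    for g in others:
        if g.shape != reference.shape:
            raise GridAlignmentError(
                f"grid shape {g.shape} does not match population grid "
                f"{reference.shape}; rasterize inputs onto the population grid"
            )
        geo_a = (reference.origin_x, reference.origin_y, reference.cell_width, reference.cell_height)
        geo_b = (g.origin_x, g.origin_y, g.cell_width, g.cell_height)
        if not np.allclose(geo_a, geo_b, rtol=1e-9, atol=1e-9):
            raise GridAlignmentError(
                f"grid georeference {geo_b} does not match population grid {geo_a}"
            )
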