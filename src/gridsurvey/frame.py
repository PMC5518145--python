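"""Build the serpentine-ordered sampling frame from aligned rasters.

The frame is the flat table of *eligible* grid cells — cells with a known,
sufficiently large population and a valid stratum — ordered boustrophedon
style: rows north to south, alternating west-to-east and east-to-west so
that consecutive cells are spatially adjacent.  Systematic sampling along
this ordering yields an implicitly spatially stratified sample.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely

from .config import SampleConfig
from .geotiff import read_raster
from .grids import GridAlignmentError, PopulationGrid, ZoneGrid, check_aligned

__all__ = [
    "GridFrame",
    "load_population_raster",
    "load_zone_raster",
    "rasterize_zones",
    "aggregate_cells",
    "aggregate_zones",
    "classify_urban_by_density",
    "build_frame",
    "serpentine_order",
]

FRAME_COLUMNS = [
    "cell_id",
    "row",
    "col",
    "x_center",
    "y_center",
    "population",
    "stratum_id",
    "urban",
    "serpentine_index",
]


@dataclass
class GridFrame:
    """Serpentine-ordered table of eligible cells plus grid georeference."""

    cells: pd.DataFrame  # one record per eligible cell, FRAME_COLUMNS
    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    cell_width: float
    cell_height: float
    crs_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in FRAME_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"frame is missing columns: {missing}")
        self.cells = self.cells.sort_values("serpentine_index").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def stratum_ids(self) -> list[int]:
        return sorted(int(s) for s in self.cells["stratum_id"].unique())

    def stratum_cells(self, stratum_id: int) -> pd.DataFrame:
        """Cells of one stratum, in serpentine order."""
        return self.cells[self.cells["stratum_id"] == stratum_id]

    def stratum_population(self, stratum_id: int) -> float:
        return float(self.stratum_cells(stratum_id)["population"].sum())

    def cell_area_km2(self) -> float:
        return self._as_grid().cell_area_km2()

    def is_geographic(self) -> bool:
        return self._as_grid().is_geographic()

    def centroid_cell_ground_size(self) -> tuple[float, float]:
        return self._as_grid().centroid_cell_ground_size()

    def _as_grid(self) -> PopulationGrid:
        return PopulationGrid(
            values=np.zeros((self.n_rows, self.n_cols)),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_width=self.cell_width,
            cell_height=self.cell_height,
            crs_label=self.crs_label,
        )


def load_population_raster(path: str | os.PathLike, band: int | None = None) -> PopulationGrid:
    """Read a single-band population GeoTIFF; nodata cells become missing."""
    data = read_raster(path, band=band)
    return PopulationGrid(
        values=data.values,
        origin_x=data.origin_x,
        origin_y=data.origin_y,
        cell_width=data.cell_width,
        cell_height=data.cell_height,
        crs_label=data.crs_label,
    )


def load_zone_raster(path: str | os.PathLike, band: int | None = None) -> ZoneGrid:
    """Read an integer zone raster (strata ids or a 0/1 urban mask)."""
    data = read_raster(path, band=band)
    return ZoneGrid(
        values=data.values,
        origin_x=data.origin_x,
        origin_y=data.origin_y,
        cell_width=data.cell_width,
        cell_height=data.cell_height,
        crs_label=data.crs_label,
    )


def rasterize_zones(
    polygons: Iterable[tuple[shapely.Geometry, int]],
    template: PopulationGrid | ZoneGrid,
    label_field: str = "label",
) -> ZoneGrid:
    """Burn labelled polygons onto the template grid by cell-centre membership.

    Each cell takes the label of the polygon containing (or touching) its
    centre; the first polygon in input order wins on overlap.  Cells whose
    centre lies in no polygon are missing.  Labels must be integers.
    """
    items = list(polygons)
    if not items:
        raise ValueError("empty polygon set")
    for _, label in items:
        if int(label) != label:
            raise ValueError(f"non-integer {label_field}: {label!r}")

    xs = template.x_centers()
    ys = template.y_centers()
    xx, yy = np.meshgrid(xs, ys)
    out = np.full(template.shape, np.nan)
    unassigned = np.ones(template.shape, dtype=bool)
    for geom, label in items:
        shapely.prepare(geom)
        hit = shapely.intersects_xy(geom, xx, yy) & unassigned
        out[hit] = int(label)
        unassigned &= ~hit
    return ZoneGrid(
        values=out,
        origin_x=template.origin_x,
        origin_y=template.origin_y,
        cell_width=template.cell_width,
        cell_height=template.cell_height,
        crs_label=template.crs_label,
    )


def aggregate_cells(grid: PopulationGrid, factor: int) -> PopulationGrid:
    """Sum ``factor x factor`` blocks into coarser cells.

    Missing cells contribute 0 inside a block that has any valid cell; blocks
    that are entirely missing stay missing.  Partial blocks at the south/east
    edges are retained, so total population is always conserved.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("aggregation factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return grid

    n_rows = math.ceil(grid.n_rows / factor)
    n_cols = math.ceil(grid.n_cols / factor)
    padded = np.full((n_rows * factor, n_cols * factor), np.nan)
    padded[: grid.n_rows, : grid.n_cols] = grid.values
    blocks = padded.reshape(n_rows, factor, n_cols, factor)
    filled = np.nan_to_num(blocks, nan=0.0).sum(axis=(1, 3))
    all_missing = np.isnan(blocks).all(axis=(1, 3))
    filled[all_missing] = np.nan
    return PopulationGrid(
        values=filled,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        cell_width=grid.cell_width * factor,
        cell_height=grid.cell_height * factor,
        crs_label=grid.crs_label,
    )


def aggregate_zones(zone: ZoneGrid, factor: int) -> ZoneGrid:
    """Coarsen a zone raster by block majority vote.

    Companion to :func:`aggregate_cells` so zone rasters can follow the
    population grid through ``cfg_desired_cell_size``.  Ties go to the
    smallest zone id; all-missing blocks stay missing.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("aggregation factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return zone

    n_rows = math.ceil(zone.n_rows / factor)
    n_cols = math.ceil(zone.n_cols / factor)
    out = np.full((n_rows, n_cols), np.nan)
    for r in range(n_rows):
        for c in range(n_cols):
            block = zone.values[
                r * factor : (r + 1) * factor, c * factor : (c + 1) * factor
            ]
            valid = block[~np.isnan(block)]
            if valid.size == 0:
                continue
            ids, counts = np.unique(valid, return_counts=True)
            out[r, c] = ids[np.argmax(counts)]  # ids sorted asc -> tie to smallest
    return ZoneGrid(
        values=out,
        origin_x=zone.origin_x,
        origin_y=zone.origin_y,
        cell_width=zone.cell_width * factor,
        cell_height=zone.cell_height * factor,
        crs_label=zone.crs_label,
    )


def classify_urban_by_density(
    grid: PopulationGrid, urban_population_fraction: float
) -> tuple[float, ZoneGrid]:
    """Split cells into urban/rural so the densest cells hold a population share.

    The threshold is the largest observed cell value ``v`` such that cells
    with value >= ``v`` hold at least ``urban_population_fraction`` of the
    total population; cells at or above it are urban (1), the rest rural (0).
    Missing cells stay missing in the returned mask.
    """
    if not 0.0 < urban_population_fraction <= 1.0:
        raise ValueError("urban_population_fraction must lie in (0, 1]")
    values = grid.values
    valid = ~np.isnan(values)
    total = float(values[valid].sum())
    if total <= 0:
        raise ValueError("cannot classify an all-zero population grid")

    positives = np.sort(values[valid & (values > 0)])[::-1]
    cum = np.cumsum(positives)
    target = urban_population_fraction * total
    # first index (densest-first) where the running share reaches the target
    idx = int(np.searchsorted(cum, target - 1e-12 * total, side="left"))
    idx = min(idx, len(positives) - 1)
    threshold = float(positives[idx])

    urban = np.full(grid.shape, np.nan)
    urban[valid] = (values[valid] >= threshold).astype(float)
    return threshold, ZoneGrid(
        values=urban,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        cell_width=grid.cell_width,
        cell_height=grid.cell_height,
        crs_label=grid.crs_label,
    )


def serpentine_order(rows: Sequence[int] | np.ndarray, cols: Sequence[int] | np.ndarray, n_cols: int) -> np.ndarray:
    """Rank cells boustrophedon: rows north→south, even rows west→east,
    odd rows east→west.  Returns ranks 0..N-1 aligned with the inputs."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    within = np.where(rows % 2 == 0, cols, n_cols - 1 - cols)
    key = rows * n_cols + within
    order = np.argsort(key, kind="stable")
    ranks = np.empty(len(key), dtype=np.int64)
    ranks[order] = np.arange(len(key))
    return ranks


def build_frame(
    pop: PopulationGrid,
    strata: ZoneGrid,
    urban: ZoneGrid | None,
    cfg: SampleConfig,
) -> GridFrame:
    """Assemble the eligible-cell frame in serpentine order.

    Eligibility: population known and >= ``cfg_min_pop_per_cell``, stratum id
    present.  Cells with a missing urban flag are kept and treated as rural.
    A stratum whose eligible population is zero cannot be sampled and raises.
    """
    try:
        if urban is None:
            check_aligned(pop, strata)
        else:
            check_aligned(pop, strata, urban)
    except GridAlignmentError:
        raise

    pop_values = pop.values
    eligible = (
        ~np.isnan(pop_values)
        & (pop_values >= cfg.cfg_min_pop_per_cell)
        & ~np.isnan(strata.values)
    )
    rows, cols = np.nonzero(eligible)
    if rows.size == 0:
        raise ValueError("no eligible cells: frame would be empty")

    if urban is None:
        urban_flags = np.zeros(rows.size, dtype=bool)
    else:
        u = urban.values[rows, cols]
        urban_flags = np.nan_to_num(u, nan=0.0) > 0

    cells = pd.DataFrame(
        {
            "cell_id": rows.astype(np.int64) * pop.n_cols + cols,
            "row": rows.astype(np.int64),
            "col": cols.astype(np.int64),
            "x_center": pop.origin_x + (cols + 0.5) * pop.cell_width,
            "y_center": pop.origin_y - (rows + 0.5) * pop.cell_height,
            "population": pop_values[rows, cols],
            "stratum_id": strata.values[rows, cols].astype(np.int64),
            "urban": urban_flags,
            "serpentine_index": serpentine_order(rows, cols, pop.n_cols),
        }
    )

    empty = [
        int(s)
        for s, total in cells.groupby("stratum_id")["population"].sum().items()
        if total <= 0
    ]
    # strata present in the raster but with no eligible cell at all
    raster_strata = {
        int(v) for v in np.unique(strata.values[~np.isnan(strata.values) & ~np.isnan(pop_values)])
    }
    absent = sorted(raster_strata - set(int(s) for s in cells["stratum_id"].unique()))
    if empty or absent:
        bad = sorted(set(empty) | set(absent))
        raise ValueError(f"strata with zero eligible population: {bad}")

    return GridFrame(
        cells=cells,
        n_rows=pop.n_rows,
        n_cols=pop.n_cols,
        origin_x=pop.origin_x,
        origin_y=pop.origin_y,
        cell_width=pop.cell_width,
        cell_height=pop.cell_height,
        crs_label=pop.crs_label,
    )
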