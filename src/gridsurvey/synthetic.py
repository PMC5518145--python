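"""Seeded synthetic fixtures: population surfaces, strata blocks, urban masks.

Everything here is a pure function of its :class:`FixtureSpec`, so test
fixtures and demo data are generated at run time rather than shipped.  The
``write_fixture_suite`` helper materializes a spec as genuine GeoTIFFs so
the full file I/O path can be exercised.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .frame import classify_urban_by_density
from .geotiff import write_raster
from .grids import PopulationGrid, ZoneGrid

__all__ = ["FixtureSpec", "make_population", "make_strata", "make_urban", "write_fixture_suite"]

SURFACES = ("uniform", "gradient", "blobs")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic raster triplet (population, strata, urban)."""

    n_rows: int = 20
    n_cols: int = 20
    surface: str = "uniform"
    uniform_value: float = 1.0
    blob_count: int = 3
    blob_scale: float = 3.0  # Gaussian sigma in cells
    blob_mass: float = 500.0  # persons per bump
    strata_layout: tuple[int, int] = (1, 1)  # (rows, cols) of block strata
    urban_rule: float = 0.0  # fraction of population in the densest cells
    nodata_fraction: float = 0.0
    seed: int = 0
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_width: float = 100.0
    cell_height: float = 100.0
    crs_label: str = "synthetic metres"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("fixture dimensions must be positive")
        if self.surface not in SURFACES:
            raise ValueError(f"surface must be one of {SURFACES}")
        if not 0.0 <= self.urban_rule <= 1.0:
            raise ValueError("urban_rule must lie in [0, 1]")
        if not 0.0 <= self.nodata_fraction <= 1.0:
            raise ValueError("nodata_fraction must lie in [0, 1]")


def _geometry(spec: FixtureSpec) -> dict:
    return dict(
        origin_x=spec.origin_x,
        origin_y=spec.origin_y,
        cell_width=spec.cell_width,
        cell_height=spec.cell_height,
        crs_label=spec.crs_label,
    )


def make_population(spec: FixtureSpec) -> PopulationGrid:
    """Deterministic population surface for the fixture recipe."""
    rng = np.random.default_rng(spec.seed)
    rows = np.arange(spec.n_rows)[:, None]
    cols = np.arange(spec.n_cols)[None, :]

    if spec.surface == "uniform":
        values = np.full((spec.n_rows, spec.n_cols), float(spec.uniform_value))
    elif spec.surface == "gradient":
        # west-to-east linear ramp from ~0 to 2x the uniform value
        ramp = (cols + 0.5) / spec.n_cols
        values = np.broadcast_to(2.0 * spec.uniform_value * ramp, (spec.n_rows, spec.n_cols)).copy()
    else:  # blobs
        values = np.zeros((spec.n_rows, spec.n_cols))
        centers = rng.uniform(
            low=(0, 0), high=(spec.n_rows, spec.n_cols), size=(spec.blob_count, 2)
        )
        sigma = spec.blob_scale
        for cr, cc in centers:
            bump = np.exp(-(((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sigma**2)))
            values += spec.blob_mass * bump / (2 * np.pi * sigma**2)

    if spec.nodata_fraction > 0:
        holes = rng.random((spec.n_rows, spec.n_cols)) < spec.nodata_fraction
        values = values.copy()
        values[holes] = np.nan
    return PopulationGrid(values=values, **_geometry(spec))


def make_strata(spec: FixtureSpec) -> ZoneGrid:
    """Rectangular block partition with ids 1..(rows*cols), row-major."""
    br, bc = spec.strata_layout
    if br < 1 or bc < 1:
        raise ValueError("strata_layout must be positive")
    row_block = np.minimum(np.arange(spec.n_rows) * br // spec.n_rows, br - 1)
    col_block = np.minimum(np.arange(spec.n_cols) * bc // spec.n_cols, bc - 1)
    ids = row_block[:, None] * bc + col_block[None, :] + 1
    return ZoneGrid(values=ids.astype(float), **_geometry(spec))


def make_urban(spec: FixtureSpec, pop: PopulationGrid) -> ZoneGrid:
    """Density-threshold urban mask at the recipe's population fraction."""
    if spec.urban_rule <= 0:
        values = np.where(np.isnan(pop.values), np.nan, 0.0)
        return ZoneGrid(values=values, **_geometry(spec))
    _, urban = classify_urban_by_density(pop, spec.urban_rule)
    return urban


def write_fixture_suite(spec: FixtureSpec, directory: str | os.PathLike) -> dict[str, Path]:
    """Materialize the triplet as GeoTIFFs; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pop = make_population(spec)
    strata = make_strata(spec)
    urban = make_urban(spec, pop)
    paths = {}
    for name, grid in (("population", pop), ("strata", strata), ("urban", urban)):
        path = directory / f"{name}.tif"
        write_raster(
            path,
            grid.values,
            origin_x=grid.origin_x,
            origin_y=grid.origin_y,
            cell_width=grid.cell_width,
            cell_height=grid.cell_height,
            crs_label=grid.crs_label,
        )
        paths[name] = path
    return paths
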