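"""Grow seeds into contiguous PSUs by randomized dilation.

Each seed owns a Voronoi region — the eligible cells of its own stratum
nearer to it than to any other seed of that stratum — and may only grow
inside it.  Growth proceeds in round-robin passes over PSU id: every
unfinished PSU adds one uniformly random cell from the 4-neighbour frontier
of its current members, until it reaches the population target, hits the
area cap, or runs out of frontier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import SampleConfig
from .frame import GridFrame
from .selection import SeedSet

__all__ = ["GrowthRegion", "Psu", "partition_regions", "grow_psus"]

logger = logging.getLogger(__name__)


@dataclass
class GrowthRegion:
    """Nearest-seed partition of eligible cells, within strata."""

    assignment: dict[int, int]  # cell_id -> psu_id
    region_cells: dict[int, set[int]]  # psu_id -> allowed cell_ids


@dataclass
class Psu:
    """A grown primary sampling unit."""

    psu_id: int
    seed_cell: int
    member_cells: set[int]
    psu_pop: float
    psu_u_pop: float
    psu_r_pop: float
    area_km2: float
    stratum_id: int
    urban: bool
    centroid_x: float
    centroid_y: float


def partition_regions(seeds: SeedSet, frame: GridFrame) -> GrowthRegion:
    """Assign every eligible cell to the nearest seed of its own stratum.

    Distances are planar Euclidean between cell centres; ties go to the
    lowest psu_id.  PSU ids are the row positions in the SeedSet (0-based),
    so the partition is deterministic given seeds and frame.
    """
    cells = frame.cells
    lookup = cells.set_index("cell_id")
    assignment: dict[int, int] = {}
    region_cells: dict[int, set[int]] = {
        int(pid): set() for pid in range(len(seeds.seeds))
    }

    for stratum in frame.stratum_ids:
        seed_rows = seeds.seeds[seeds.seeds["stratum_id"] == stratum]
        if seed_rows.empty:
            raise ValueError(f"stratum {stratum} has no seed")
        psu_ids = seed_rows.index.to_numpy()
        sx = lookup.loc[seed_rows["cell_id"], "x_center"].to_numpy(dtype=np.float64)
        sy = lookup.loc[seed_rows["cell_id"], "y_center"].to_numpy(dtype=np.float64)

        strat_cells = cells[cells["stratum_id"] == stratum]
        cx = strat_cells["x_center"].to_numpy(dtype=np.float64)
        cy = strat_cells["y_center"].to_numpy(dtype=np.float64)
        # (cells x seeds) distance matrix; argmin takes the first (lowest
        # psu_id) on exact ties because seed_rows are in psu_id order
        d2 = (cx[:, None] - sx[None, :]) ** 2 + (cy[:, None] - sy[None, :]) ** 2
        nearest = psu_ids[np.argmin(d2, axis=1)]
        for cell_id, pid in zip(strat_cells["cell_id"].to_numpy(), nearest):
            assignment[int(cell_id)] = int(pid)
            region_cells[int(pid)].add(int(cell_id))
    return GrowthRegion(assignment=assignment, region_cells=region_cells)


def grow_psus(
    seeds: SeedSet,
    regions: GrowthRegion,
    frame: GridFrame,
    cfg: SampleConfig,
    rng: np.random.Generator,
) -> list[Psu]:
    """Dilate each seed into a PSU; with growth off, PSUs are single cells."""
    cells = frame.cells.set_index("cell_id")
    cell_area = frame.cell_area_km2()
    n_cols = frame.n_cols

    psus: list[_GrowState] = []
    claimed: set[int] = set()
    for psu_id, row in enumerate(seeds.seeds.itertuples(index=False)):
        seed_id = int(row.cell_id)
        info = cells.loc[seed_id]
        state = _GrowState(
            psu_id=psu_id,
            seed_cell=seed_id,
            stratum_id=int(row.stratum_id),
            urban=bool(row.urban),
            centroid_x=float(info["x_center"]),
            centroid_y=float(info["y_center"]),
        )
        state.add(seed_id, float(info["population"]), bool(info["urban"]))
        claimed.add(seed_id)
        psus.append(state)

    if cfg.cfg_psu_growth:
        _dilate(psus, regions, cells, claimed, cfg, cell_area, n_cols, rng)

    out = []
    for s in psus:
        if cfg.cfg_psu_growth and s.psu_pop < cfg.cfg_pop_per_psu:
            logger.warning(
                "PSU %d stopped below the population target (%.1f < %.1f)",
                s.psu_id, s.psu_pop, cfg.cfg_pop_per_psu,
            )
        out.append(
            Psu(
                psu_id=s.psu_id,
                seed_cell=s.seed_cell,
                member_cells=set(s.members),
                psu_pop=s.psu_pop,
                psu_u_pop=s.psu_u_pop,
                psu_r_pop=s.psu_r_pop,
                area_km2=len(s.members) * cell_area,
                stratum_id=s.stratum_id,
                urban=s.urban,
                centroid_x=s.centroid_x,
                centroid_y=s.centroid_y,
            )
        )
    return out


@dataclass
class _GrowState:
    psu_id: int
    seed_cell: int
    stratum_id: int
    urban: bool
    centroid_x: float
    centroid_y: float
    members: set[int] = field(default_factory=set)
    frontier: set[int] = field(default_factory=set)
    psu_pop: float = 0.0
    psu_u_pop: float = 0.0
    psu_r_pop: float = 0.0
    finished: bool = False

    def add(self, cell_id: int, population: float, cell_urban: bool) -> None:
        self.members.add(cell_id)
        self.psu_pop += population
        if cell_urban:
            self.psu_u_pop += population
        else:
            self.psu_r_pop += population


def _neighbours(cell_id: int, n_cols: int) -> tuple[int, ...]:
    row, col = divmod(cell_id, n_cols)
    out = []
    if row > 0:
        out.append(cell_id - n_cols)
    out.append(cell_id + n_cols)
    if col > 0:
        out.append(cell_id - 1)
    if col < n_cols - 1:
        out.append(cell_id + 1)
    return tuple(out)


def _dilate(psus, regions, cells, claimed, cfg, cell_area, n_cols, rng) -> None:
    max_size = cfg.cfg_max_psu_size
    for s in psus:
        region = regions.region_cells[s.psu_id]
        s.frontier = {
            nb
            for nb in _neighbours(s.seed_cell, n_cols)
            if nb in region and nb not in claimed
        }
        if s.psu_pop >= cfg.cfg_pop_per_psu:
            s.finished = True
        if max_size is not None and len(s.members) * cell_area >= max_size:
            s.finished = True

    while any(not s.finished for s in psus):
        for s in psus:  # round-robin by psu_id
            if s.finished:
                continue
            # frontier is maintained incrementally; cells claimed by other
            # PSUs since insertion are filtered out lazily here
            s.frontier -= claimed
            if not s.frontier:
                s.finished = True
                continue
            candidates = sorted(s.frontier)
            pick = int(candidates[rng.integers(len(candidates))])
            info = cells.loc[pick]
            s.add(pick, float(info["population"]), bool(info["urban"]))
            claimed.add(pick)
            s.frontier.discard(pick)
            region = regions.region_cells[s.psu_id]
            for nb in _neighbours(pick, n_cols):
                if nb in region and nb not in claimed:
                    s.frontier.add(nb)
            if s.psu_pop >= cfg.cfg_pop_per_psu:
                s.finished = True
            if max_size is not None and len(s.members) * cell_area >= max_size:
                s.finished = True
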