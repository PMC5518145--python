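"""Post-selection seed adjustments: sub-domain minima and spatial coverage.

Both adjustments swap seeds one-for-one within a stratum, so the per-stratum
PSU counts fixed at selection time are never disturbed.  The fixed pipeline
order is: select seeds, then enforce the urban/rural sub-domain minimum,
then enforce spatial coverage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SampleConfig
from .frame import GridFrame
from .selection import SeedSet

__all__ = [
    "CoarseGrid",
    "InfeasibleSampleError",
    "enforce_subdomain_minimum",
    "build_coarse_grid",
    "enforce_spatial_coverage",
]

logger = logging.getLogger(__name__)

_SEED_DTYPES = {"cell_id": "int64", "stratum_id": "int64", "urban": "bool"}


def _swap_rows(df, drop_idx: int, new_row: dict):
    """Drop one seed row and append another, keeping stable dtypes."""
    out = pd.concat(
        [df.drop(index=drop_idx), pd.DataFrame([new_row])], ignore_index=True
    )
    return out.astype(_SEED_DTYPES)


class InfeasibleSampleError(RuntimeError):
    """The requested adjustment cannot be satisfied on this frame."""


def _implied_households(seeds: SeedSet, cfg: SampleConfig, urban: bool) -> int:
    return seeds.count_subdomain(urban) * cfg.hh_per_psu(urban)


def enforce_subdomain_minimum(
    seeds: SeedSet,
    frame: GridFrame,
    cfg: SampleConfig,
    rng: np.random.Generator,
    swap_log: list | None = None,
) -> SeedSet:
    """Swap seeds until each sub-domain implies >= cfg_hh_per_stratum households.

    While a sub-domain is under-represented study-wide, the next non-seed
    cell of that sub-domain in serpentine order (from any stratum) becomes a
    seed, and one randomly chosen seed of the opposite sub-domain in that
    same stratum is dropped.  Urban is processed first when both fall short.
    Idempotent once both minima hold.
    """
    if not cfg.cfg_sample_rururb:
        return seeds
    if not frame.cells["urban"].any():
        raise InfeasibleSampleError(
            "urban/rural sampling requested but the frame has no urban cells"
        )

    result = seeds.copy()
    for target_urban in (True, False):  # urban first by convention
        while _implied_households(result, cfg, target_urban) < cfg.cfg_hh_per_stratum:
            if not _swap_into_subdomain(result, frame, target_urban, rng, swap_log):
                raise InfeasibleSampleError(
                    "cannot reach the household minimum for the "
                    f"{'urban' if target_urban else 'rural'} sub-domain: no "
                    "swappable candidate/seed pair remains"
                )
    for target_urban in (True, False):
        if _implied_households(result, cfg, target_urban) < cfg.cfg_hh_per_stratum:
            raise InfeasibleSampleError(
                "sub-domain household minima are jointly infeasible on this frame"
            )
    return result


def _swap_into_subdomain(
    seeds: SeedSet,
    frame: GridFrame,
    target_urban: bool,
    rng: np.random.Generator,
    swap_log: list | None,
) -> bool:
    """Perform one add/drop swap toward ``target_urban``; False if impossible."""
    seed_ids = seeds.cell_ids()
    candidates = frame.cells[
        (frame.cells["urban"] == target_urban) & ~frame.cells["cell_id"].isin(seed_ids)
    ]
    for cand in candidates.itertuples(index=False):  # serpentine order
        stratum = int(cand.stratum_id)
        opposite = seeds.seeds[
            (seeds.seeds["stratum_id"] == stratum) & (seeds.seeds["urban"] != target_urban)
        ]
        if opposite.empty:
            continue
        drop_idx = int(rng.choice(opposite.index.to_numpy()))
        dropped = int(seeds.seeds.at[drop_idx, "cell_id"])
        seeds.seeds = _swap_rows(
            seeds.seeds,
            drop_idx,
            {"cell_id": int(cand.cell_id), "stratum_id": stratum, "urban": bool(target_urban)},
        )
        event = {
            "reason": "subdomain_minimum",
            "subdomain": "urban" if target_urban else "rural",
            "added": int(cand.cell_id),
            "dropped": dropped,
            "stratum_id": stratum,
        }
        logger.info("swap %s", event)
        if swap_log is not None:
            swap_log.append(event)
        return True
    return False


@dataclass(frozen=True)
class CoarseGrid:
    """Coarse cells overlaid on the fine grid for spatially balanced sampling."""

    scale_km: float
    cells_per_side: int
    n_coarse_rows: int
    n_coarse_cols: int

    def coarse_id(self, row, col):
        """Coarse cell id for fine cell(s) (row, col); vectorizes over arrays."""
        return (np.asarray(row) // self.cells_per_side) * self.n_coarse_cols + (
            np.asarray(col) // self.cells_per_side
        )


def build_coarse_grid(frame: GridFrame, scale_km: float) -> CoarseGrid:
    """Overlay a coarse grid of ``scale_km``-sided cells anchored at the origin.

    The representative fine-cell side is taken from the ground area of the
    study area's centroid cell, which smooths over the slight cell-size drift
    of geographic grids.
    """
    if scale_km <= 0:
        raise ValueError("scale_km must be positive")
    width_m, height_m = frame.centroid_cell_ground_size()
    side_m = math.sqrt(width_m * height_m)
    cells_per_side = max(1, round(scale_km * 1000.0 / side_m))
    return CoarseGrid(
        scale_km=float(scale_km),
        cells_per_side=int(cells_per_side),
        n_coarse_rows=math.ceil(frame.n_rows / cells_per_side),
        n_coarse_cols=math.ceil(frame.n_cols / cells_per_side),
    )


def enforce_spatial_coverage(
    seeds: SeedSet,
    frame: GridFrame,
    coarse: CoarseGrid,
    rng: np.random.Generator,
    swap_log: list | None = None,
) -> SeedSet:
    """Ensure every coarse cell holding eligible population also holds a seed.

    An empty-but-populated coarse cell gains its first frame cell (serpentine
    order) as a seed; in exchange one randomly chosen seed of the same
    stratum and sub-domain is dropped — never a seed that is the only one in
    its own coarse cell, which would just move the hole.  Insertions whose
    paired drop is impossible are skipped and logged; per-stratum and
    per-sub-domain counts are preserved exactly.
    """
    result = seeds.copy()
    cells = frame.cells
    cell_coarse = {
        int(c): int(g)
        for c, g in zip(cells["cell_id"], coarse.coarse_id(cells["row"], cells["col"]))
    }
    populated = sorted(set(cell_coarse.values()))

    for coarse_cell in populated:
        seed_coarse = result.seeds["cell_id"].map(cell_coarse)
        if (seed_coarse == coarse_cell).any():
            continue
        in_cell = cells[coarse.coarse_id(cells["row"], cells["col"]) == coarse_cell]
        cand = in_cell.iloc[0]  # first in serpentine order
        stratum = int(cand["stratum_id"])
        urban = bool(cand["urban"])

        coarse_counts = seed_coarse.value_counts()
        droppable = result.seeds[
            (result.seeds["stratum_id"] == stratum)
            & (result.seeds["urban"] == urban)
            & (seed_coarse.map(coarse_counts) > 1)
        ]
        if droppable.empty:
            event = {
                "reason": "spatial_coverage_skipped",
                "coarse_cell": int(coarse_cell),
                "candidate": int(cand["cell_id"]),
                "stratum_id": stratum,
                "subdomain": "urban" if urban else "rural",
            }
            logger.warning("skip %s", event)
            if swap_log is not None:
                swap_log.append(event)
            continue

        drop_idx = int(rng.choice(droppable.index.to_numpy()))
        dropped = int(result.seeds.at[drop_idx, "cell_id"])
        result.seeds = _swap_rows(
            result.seeds,
            drop_idx,
            {"cell_id": int(cand["cell_id"]), "stratum_id": stratum, "urban": urban},
        )
        event = {
            "reason": "spatial_coverage",
            "coarse_cell": int(coarse_cell),
            "added": int(cand["cell_id"]),
            "dropped": dropped,
            "stratum_id": stratum,
            "subdomain": "urban" if urban else "rural",
        }
        logger.info("swap %s", event)
        if swap_log is not None:
            swap_log.append(event)
    return result
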