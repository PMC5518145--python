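"""Seed-cell selection: per-stratum PPES systematic sampling.

Within each stratum, cells are laid end-to-end along the serpentine ordering
to form a cumulative population line of length P.  With n_k seeds requested,
the sampling interval is I = P / n_k; a single random start u = r * I places
sampling points u, u + I, ..., u + (n_k - 1) I, and each point selects the
cell whose half-open cumulative interval contains it.  One shared random
number r reproduces the whole sample.
"""

from __future__ import annotations

import math
import secrets
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .config import SampleConfig
from .frame import GridFrame

__all__ = ["SeedSet", "allocate_psus", "systematic_ppes", "select_seeds", "rng_from_random_number"]


@dataclass
class SeedSet:
    """Selected seed cells with stratum / sub-domain labels."""

    seeds: pd.DataFrame  # columns: cell_id, stratum_id, urban
    n_per_stratum: dict[int, int]
    random_number_used: float

    def __post_init__(self) -> None:
        if self.seeds["cell_id"].duplicated().any():
            raise ValueError("seed cell_ids must be distinct")
        counts = self.seeds.groupby("stratum_id").size().to_dict()
        expected = {int(k): int(v) for k, v in self.n_per_stratum.items()}
        actual = {int(k): int(v) for k, v in counts.items()}
        if actual != expected:
            raise ValueError(f"per-stratum seed counts {actual} != allocation {expected}")

    def __len__(self) -> int:
        return len(self.seeds)

    def cell_ids(self) -> set[int]:
        return set(int(c) for c in self.seeds["cell_id"])

    def count_subdomain(self, urban: bool) -> int:
        return int((self.seeds["urban"] == urban).sum())

    def copy(self) -> "SeedSet":
        return SeedSet(
            seeds=self.seeds.copy().reset_index(drop=True),
            n_per_stratum=dict(self.n_per_stratum),
            random_number_used=self.random_number_used,
        )


def allocate_psus(cfg: SampleConfig, strata_ids: Iterable[int]) -> dict[int, int]:
    """PSUs per stratum: ceil(households per stratum / households per urban PSU).

    Ceiling keeps the household target met or exceeded in every stratum.
    """
    n_k = max(1, math.ceil(cfg.cfg_hh_per_stratum / cfg.cfg_hh_per_urban))
    return {int(s): n_k for s in strata_ids}


def systematic_ppes(frame: GridFrame, stratum: int, n_k: int, start: float) -> list[int]:
    """Draw ``n_k`` distinct seed cells from one stratum.

    ``start`` is the unit-interval random start scaled by the sampling
    interval.  A cell whose population spans more than one sampling point
    would be hit twice; duplicates are resolved by advancing to the next
    not-yet-selected cell in serpentine order, wrapping within the stratum,
    so exactly ``n_k`` distinct cells are always returned.
    """
    if n_k < 1:
        raise ValueError("n_k must be >= 1")
    if not 0.0 <= start < 1.0:
        raise ValueError("start must lie in [0, 1)")
    cells = frame.stratum_cells(stratum)
    if len(cells) < n_k:
        raise ValueError(
            f"stratum {stratum}: {n_k} PSUs requested but only {len(cells)} eligible cells"
        )
    pops = cells["population"].to_numpy(dtype=np.float64)
    total = float(pops.sum())
    if total <= 0:
        raise ValueError(f"stratum {stratum} has zero eligible population")

    interval = total / n_k
    points = start * interval + interval * np.arange(n_k)
    cum = np.cumsum(pops)
    # half-open intervals [cum[i-1], cum[i]) -> side="right"
    hits = np.searchsorted(cum, points, side="right")
    hits = np.minimum(hits, len(pops) - 1)  # guard float edge at the very end

    chosen: list[int] = []
    taken = np.zeros(len(pops), dtype=bool)
    cell_ids = cells["cell_id"].to_numpy()
    for h in hits:
        pos = int(h)
        while taken[pos]:
            pos = (pos + 1) % len(pops)
        taken[pos] = True
        chosen.append(int(cell_ids[pos]))
    return chosen


def rng_from_random_number(random_number: float) -> np.random.Generator:
    """Derive the run's generator from the single recorded random number."""
    return np.random.default_rng(int(random_number * 2**53))


def select_seeds(
    frame: GridFrame, cfg: SampleConfig, rng: np.random.Generator | None = None
) -> SeedSet:
    """Select seeds in every stratum with one shared random start.

    Uses ``cfg_random_number`` when given; otherwise draws one number from
    ``rng`` (or fresh entropy).  The number used is recorded in the result so
    the sample can be reproduced exactly.
    """
    if len(frame) == 0:
        raise ValueError("empty frame")
    if cfg.cfg_random_number is not None:
        r = float(cfg.cfg_random_number)
    elif rng is not None:
        r = float(rng.random())
    else:
        r = secrets.randbelow(2**53) / 2**53

    allocation = allocate_psus(cfg, frame.stratum_ids)
    records = []
    lookup = frame.cells.set_index("cell_id")
    for stratum in frame.stratum_ids:
        for cell_id in systematic_ppes(frame, stratum, allocation[stratum], r):
            records.append(
                {
                    "cell_id": int(cell_id),
                    "stratum_id": int(stratum),
                    "urban": bool(lookup.at[cell_id, "urban"]),
                }
            )
    seeds = pd.DataFrame.from_records(records, columns=["cell_id", "stratum_id", "urban"])
    return SeedSet(seeds=seeds, n_per_stratum=allocation, random_number_used=r)
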