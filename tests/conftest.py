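import numpy as np
import pytest

from gridsurvey import (
    PopulationGrid,
    SampleConfig,
    ZoneGrid,
    build_frame,
)


def make_pop(values, **geo) -> PopulationGrid:
    return PopulationGrid(values=np.asarray(values, dtype=float), **geo)


def make_zones(values, **geo) -> ZoneGrid:
    return ZoneGrid(values=np.asarray(values, dtype=float), **geo)


def uniform_frame(n_rows, n_cols, value=1.0, n_strata=1, cfg=None, urban_mask=None, **geo):
    """Single- or block-strata frame with constant population per cell."""
    pop = make_pop(np.full((n_rows, n_cols), float(value)), **geo)
    if n_strata == 1:
        strata = make_zones(np.ones((n_rows, n_cols)), **geo)
    else:
        # vertical bands of roughly equal width
        cols = np.arange(n_cols)
        band = np.minimum(cols * n_strata // n_cols, n_strata - 1) + 1
        strata = make_zones(np.broadcast_to(band, (n_rows, n_cols)).astype(float), **geo)
    urban = None
    if urban_mask is not None:
        urban = make_zones(np.asarray(urban_mask, dtype=float), **geo)
    cfg = cfg or basic_cfg()
    return build_frame(pop, strata, urban, cfg)


def basic_cfg(**overrides) -> SampleConfig:
    defaults = dict(
        cfg_hh_per_stratum=20,
        cfg_hh_per_urban=10,
        cfg_pop_per_psu=5.0,
        cfg_psu_growth=True,
        cfg_min_pop_per_cell=0.0,
    )
    defaults.update(overrides)
    return SampleConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
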