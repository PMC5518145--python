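# gridsurvey

Select household-survey primary sampling units (PSUs) directly from a
gridded population raster instead of census enumeration areas.

Given a population raster, a strata raster (e.g. districts), and optionally
an urban/rural mask, `gridsurvey`:

1. builds a **serpentine-ordered sampling frame** of eligible grid cells
   (boustrophedon: west→east, east→west on alternating rows, north→south);
2. draws **seed cells** per stratum by systematic sampling with probability
   proportionate to estimated population size (PPES), from a single recorded
   random number so any sample can be reproduced exactly;
3. optionally **rebalances seeds** so urban and rural sub-domains each reach
   the per-stratum household minimum, and so every coarse grid cell of a
   chosen spatial scale contains at least one seed (spatially balanced
   oversampling);
4. **grows each seed into a contiguous PSU** by randomized dilation, bounded
   by the seed's Voronoi region and stratum, until a population target or an
   area cap (km²) is met;
5. writes the PSU polygons (GeoJSON or ESRI shapefile) with the attribute
   schema needed for design weights, plus an attribute CSV and a JSON run
   manifest;
6. computes **household and individual design weights** (base, segment,
   response, and combined) from a per-household fieldwork ledger.

Raster I/O is a minimal single-band GeoTIFF layer built on `tifffile`;
polygon inputs are rasterized by cell-centre membership using `shapely`.
Inputs must already share one georeference (no reprojection).

## Test

```sh
python -m pytest -q tests/
```

One acceptance test (`TestCriterion7RwandaReplication`) replicates a
published national survey design and needs external data that cannot be
redistributed: the WorldPop Rwanda 2010 UN-adjusted 100 m raster and the 30
district boundaries rasterized onto it. Put `population.tif` and
`strata.tif` in a directory and set `GRIDSURVEY_RWANDA_DIR` to run it; it
fails with an explanatory message otherwise.

## CLI

Generate a synthetic input triplet, run a sample, and compute weights:

```sh
gridsurvey fixtures --out-dir demo/inputs --rows 40 --cols 40 --seed 7

cat > demo/run.cfg <<EOF
population_raster = demo/inputs/population.tif
strata_raster    = demo/inputs/strata.tif
urban_raster     = demo/inputs/urban.tif
cfg_hh_per_stratum = 40
cfg_hh_per_urban   = 10
cfg_pop_per_psu    = 120
cfg_min_pop_per_cell = 0.01
cfg_sample_rururb  = true
sample_name = demo
EOF

gridsurvey sample --config demo/run.cfg --out-dir demo/out
gridsurvey weights --ledger ledger.csv --out-prefix demo/out/w
```

`sample` prints the random number used; pass it back via
`--set cfg_random_number=<value>` to reproduce a run byte-for-byte.
Configuration keys mirror the `cfg_*` parameter names throughout
(`cfg_hh_per_stratum`, `cfg_hh_per_urban`, `cfg_hh_per_rural`,
`cfg_pop_per_psu`, `cfg_psu_growth`, `cfg_max_psu_size`,
`cfg_min_pop_per_cell`, `cfg_desired_cell_size`, `cfg_sample_rururb`,
`cfg_sample_spatial`, `cfg_sample_spatial_scale`, `cfg_random_number`).

## Library layout

| module | purpose |
| --- | --- |
| `gridsurvey.frame` | raster ingest, aggregation, urban classification, serpentine frame |
| `gridsurvey.selection` | PSU allocation and PPES systematic seed sampling |
| `gridsurvey.oversample` | urban/rural sub-domain swaps; coarse-grid spatial coverage |
| `gridsurvey.growth` | Voronoi partition and randomized dilation growth |
| `gridsurvey.output` | attribute schema, polygon dissolve, GeoJSON/shapefile/CSV writers |
| `gridsurvey.weights` | household/individual design weights from a fieldwork ledger |
| `gridsurvey.synthetic` | seeded fixture generator (uniform/gradient/blob surfaces) |
| `gridsurvey.cli` | `gridsurvey sample | weights | fixtures` |
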