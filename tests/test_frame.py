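import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from gridsurvey import (
    GridAlignmentError,
    PopulationGrid,
    aggregate_cells,
    aggregate_zones,
    build_frame,
    classify_urban_by_density,
    load_population_raster,
    rasterize_zones,
)
from gridsurvey.frame import serpentine_order
from gridsurvey.geotiff import read_raster, write_raster

from conftest import basic_cfg, make_pop, make_zones


class TestGeoTiffIO:
    def test_identity_ingest_3x3_ones(self, tmp_path):
        path = tmp_path / "ones.tif"
        write_raster(path, np.ones((3, 3)), 0.0, 3.0, 1.0, 1.0)
        grid = load_population_raster(path)
        assert grid.n_rows == grid.n_cols == 3
        assert np.all(grid.values == 1.0)

    def test_nodata_cells_marked_missing(self, tmp_path):
        values = np.array([[1.0, -9999.0], [3.0, 4.0]])
        path = tmp_path / "nodata.tif"
        write_raster(path, values, 0.0, 2.0, 1.0, 1.0, nodata=-9999.0)
        grid = load_population_raster(path)
        assert np.isnan(grid.values[0, 1])
        assert grid.total_population() == 8.0

    def test_round_trip_bit_for_bit(self, tmp_path):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 50, size=(7, 5))
        path = tmp_path / "rt.tif"
        write_raster(path, values, 30.0, -1.5, 0.001, 0.001, crs_label="WGS 84")
        data = read_raster(path)
        np.testing.assert_array_equal(data.values, values)
        assert data.origin_x == 30.0
        assert data.origin_y == -1.5
        assert data.cell_width == 0.001
        assert data.crs_label == "WGS 84"

    def test_multiband_without_selector_errors(self, tmp_path):
        import tifffile

        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8), photometric="rgb")
        with pytest.raises(ValueError, match="band"):
            read_raster(path)

    def test_unreadable_file_errors(self, tmp_path):
        with pytest.raises(Exception):
            read_raster(tmp_path / "missing.tif")


class TestRasterizeZones:
    def template(self, n=4):
        return make_pop(np.ones((n, n)), origin_x=0.0, origin_y=float(n))

    def test_full_cover_single_label(self):
        zones = rasterize_zones([(box(-1, -1, 5, 5), 7)], self.template())
        assert np.all(zones.values == 7)

    def test_two_half_planes(self):
        # left half x<2, right half x>=2 on a 4x4 grid of unit cells
        left = box(0, 0, 2, 4)
        right = box(2, 0, 4, 4)
        zones = rasterize_zones([(left, 1), (right, 2)], self.template())
        assert (zones.values == 1).sum() == 8
        assert (zones.values == 2).sum() == 8
        assert np.all(zones.values[:, :2] == 1)
        assert np.all(zones.values[:, 2:] == 2)

    def test_matches_point_in_polygon_oracle(self):
        rng = np.random.default_rng(5)
        template = self.template(6)
        tri = Polygon([(0.2, 0.3), (5.7, 1.1), (2.9, 5.6)])
        zones = rasterize_zones([(tri, 3)], template)
        for row in range(6):
            for col in range(6):
                x, y = template.cell_center(row, col)
                from shapely.geometry import Point

                expected = 3.0 if tri.intersects(Point(x, y)) else np.nan
                got = zones.values[row, col]
                assert (np.isnan(expected) and np.isnan(got)) or expected == got

    def test_no_centre_covered_all_missing(self):
        tiny = box(0.9, 0.9, 1.1, 1.1)  # between cell centres at .5 offsets
        zones = rasterize_zones([(tiny, 4)], self.template())
        assert np.isnan(zones.values).all()

    def test_non_integer_label_errors(self):
        with pytest.raises(ValueError, match="non-integer"):
            rasterize_zones([(box(0, 0, 4, 4), 1.5)], self.template())

    def test_empty_polygon_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            rasterize_zones([], self.template())


class TestAggregateCells:
    def test_factor_one_identity(self):
        grid = make_pop([[1, 2], [3, 4]])
        assert aggregate_cells(grid, 1) is grid

    def test_2x2_conservation(self):
        grid = make_pop([[1, 2], [3, 4]])
        out = aggregate_cells(grid, 2)
        assert out.shape == (1, 1)
        assert out.values[0, 0] == 10.0
        assert out.cell_width == 2.0

    def test_partial_edge_blocks_conserve_total(self):
        rng = np.random.default_rng(2)
        grid = make_pop(rng.uniform(0, 9, size=(5, 5)))
        out = aggregate_cells(grid, 3)
        assert out.shape == (2, 2)
        assert np.isclose(out.values.sum(), grid.values.sum())

    def test_missing_within_block_treated_as_zero(self):
        grid = make_pop([[1, np.nan], [np.nan, np.nan]])
        out = aggregate_cells(grid, 2)
        assert out.values[0, 0] == 1.0

    def test_all_missing_block_stays_missing(self):
        values = np.full((4, 4), np.nan)
        values[:2, :2] = 1.0
        out = aggregate_cells(make_pop(values), 2)
        assert out.values[0, 0] == 4.0
        assert np.isnan(out.values[1, 1])

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            aggregate_cells(make_pop([[1.0]]), 0)

    @given(st.integers(min_value=1, max_value=6), st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_conservation_property(self, factor, seed):
        rng = np.random.default_rng(seed)
        grid = make_pop(rng.uniform(0, 5, size=(rng.integers(1, 12), rng.integers(1, 12))))
        out = aggregate_cells(grid, factor)
        assert np.isclose(out.values.sum(), grid.values.sum())


class TestClassifyUrbanByDensity:
    def test_sort_and_accumulate_oracle(self):
        grid = make_pop([[10.0, 5.0], [3.0, 2.0]])
        threshold, urban = classify_urban_by_density(grid, 0.25)
        assert threshold == 10.0
        assert urban.values[0, 0] == 1.0
        assert urban.values.sum() == 1.0

    def test_full_population_fraction(self):
        grid = make_pop([[0.0, 4.0], [2.0, 8.0]])
        threshold, urban = classify_urban_by_density(grid, 1.0)
        assert threshold == 2.0  # minimum positive value
        assert urban.values.sum() == 3.0  # all populated cells urban
        assert urban.values[0, 0] == 0.0  # zero cell stays rural

    def test_threshold_is_observed_value_and_ties_are_urban(self):
        grid = make_pop([[5.0, 5.0], [3.0, 1.0]])
        threshold, urban = classify_urban_by_density(grid, 0.5)
        assert threshold == 5.0
        assert urban.values[0, 1] == 1.0  # tie cell at the threshold is urban

    def test_missing_cells_stay_missing(self):
        grid = make_pop([[np.nan, 4.0], [2.0, 8.0]])
        _, urban = classify_urban_by_density(grid, 0.5)
        assert np.isnan(urban.values[0, 0])

    def test_all_zero_grid_errors(self):
        with pytest.raises(ValueError):
            classify_urban_by_density(make_pop(np.zeros((2, 2))), 0.16)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_fraction(self, seed):
        rng = np.random.default_rng(seed)
        grid = make_pop(rng.uniform(0, 20, size=(6, 6)))
        fractions = [0.1, 0.3, 0.5, 0.8, 1.0]
        thresholds = [classify_urban_by_density(grid, f)[0] for f in fractions]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_threshold_definition_holds(self):
        rng = np.random.default_rng(9)
        grid = make_pop(rng.uniform(0, 20, size=(8, 8)))
        frac = 0.3
        threshold, _ = classify_urban_by_density(grid, frac)
        total = grid.values.sum()
        tail = grid.values[grid.values >= threshold].sum()
        assert tail >= frac * total
        # no strictly larger observed value also satisfies the share
        larger = grid.values[grid.values > threshold]
        if larger.size:
            next_v = larger.min()
            assert grid.values[grid.values >= next_v].sum() < frac * total


class TestBuildFrame:
    def test_boustrophedon_enumeration_2x2(self):
        frame = make_frame_2x2()
        coords = list(zip(frame.cells["row"], frame.cells["col"]))
        assert coords == [(0, 0), (0, 1), (1, 1), (1, 0)]
        assert list(frame.cells["serpentine_index"]) == [0, 1, 2, 3]

    def test_min_pop_per_cell_excludes(self):
        pop = make_pop([[1.0, 0.005], [0.5, 2.0]])
        strata = make_zones(np.ones((2, 2)))
        cfg = basic_cfg(cfg_min_pop_per_cell=0.01)
        frame = build_frame(pop, strata, None, cfg)
        assert len(frame) == 3
        assert 1 not in set(frame.cells["cell_id"])  # cell (0,1)

    def test_missing_stratum_excludes_cell(self):
        pop = make_pop(np.ones((2, 2)))
        strata = make_zones([[1.0, np.nan], [1.0, 1.0]])
        frame = build_frame(pop, strata, None, basic_cfg())
        assert len(frame) == 3

    def test_missing_population_excludes_cell(self):
        pop = make_pop([[1.0, np.nan], [1.0, 1.0]])
        strata = make_zones(np.ones((2, 2)))
        frame = build_frame(pop, strata, None, basic_cfg())
        assert len(frame) == 3

    def test_urban_defaults_false(self):
        frame = make_frame_2x2()
        assert not frame.cells["urban"].any()

    def test_missing_urban_flag_kept_as_rural(self):
        pop = make_pop(np.ones((2, 2)))
        strata = make_zones(np.ones((2, 2)))
        urban = make_zones([[1.0, np.nan], [0.0, 0.0]])
        frame = build_frame(pop, strata, urban, basic_cfg())
        assert len(frame) == 4
        assert frame.cells.set_index("cell_id").loc[1, "urban"] == False  # noqa: E712

    def test_shape_mismatch_errors(self):
        pop = make_pop(np.ones((2, 2)))
        strata = make_zones(np.ones((3, 3)))
        with pytest.raises(GridAlignmentError):
            build_frame(pop, strata, None, basic_cfg())

    def test_georeference_mismatch_errors(self):
        pop = make_pop(np.ones((2, 2)), origin_x=0.0)
        strata = make_zones(np.ones((2, 2)), origin_x=5.0)
        with pytest.raises(GridAlignmentError):
            build_frame(pop, strata, None, basic_cfg())

    def test_zero_population_stratum_errors(self):
        pop = make_pop([[1.0, 0.0], [1.0, 0.0]])
        strata = make_zones([[1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="zero eligible population"):
            build_frame(pop, strata, None, basic_cfg())

    def test_population_conservation_per_stratum(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 5, size=(6, 6))
        pop = make_pop(values)
        strata = make_zones(np.repeat([[1, 1, 1, 2, 2, 2]], 6, axis=0).astype(float))
        frame = build_frame(pop, strata, None, basic_cfg())
        for sid, mask in ((1, np.s_[:, :3]), (2, np.s_[:, 3:])):
            assert np.isclose(frame.stratum_population(sid), values[mask].sum())

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_serpentine_bijection_and_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        n_rows, n_cols = int(rng.integers(1, 9)), int(rng.integers(1, 9))
        values = rng.uniform(0.1, 2, size=(n_rows, n_cols))
        values[rng.random((n_rows, n_cols)) < 0.2] = np.nan
        if np.isnan(values).all():
            values[0, 0] = 1.0
        frame = build_frame(
            make_pop(values), make_zones(np.ones((n_rows, n_cols))), None, basic_cfg()
        )
        idx = frame.cells["serpentine_index"].to_numpy()
        assert sorted(idx) == list(range(len(frame)))
        # within each row, order is monotone: west->east on even rows,
        # east->west on odd rows; adjacency is exact when the row has no holes
        cells = frame.cells.sort_values("serpentine_index")
        full = not np.isnan(values).any()
        for (_, a), (_, b) in zip(cells.iterrows(), cells.iloc[1:].iterrows()):
            if a["row"] == b["row"]:
                step = b["col"] - a["col"]
                assert step > 0 if a["row"] % 2 == 0 else step < 0
                if full:
                    assert abs(step) == 1
            else:
                assert b["row"] > a["row"]

    def test_serpentine_row_direction_alternates(self):
        ranks = serpentine_order([0, 0, 1, 1], [0, 1, 0, 1], n_cols=2)
        assert list(ranks) == [0, 1, 3, 2]


class TestAggregateZones:
    def test_majority_vote(self):
        zones = make_zones([[1, 1], [1, 2]])
        out = aggregate_zones(zones, 2)
        assert out.values[0, 0] == 1.0

    def test_tie_goes_to_smallest_id(self):
        zones = make_zones([[2, 2], [1, 1]])
        out = aggregate_zones(zones, 2)
        assert out.values[0, 0] == 1.0

    def test_all_missing_block(self):
        zones = make_zones([[np.nan, np.nan], [np.nan, 3.0]])
        out = aggregate_zones(zones, 2)
        assert out.values[0, 0] == 3.0


def make_frame_2x2():
    pop = make_pop(np.ones((2, 2)))
    strata = make_zones(np.ones((2, 2)))
    return build_frame(pop, strata, None, basic_cfg())
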