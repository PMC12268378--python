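"""Raster/vector round-trips, adjacency construction and zonal assignment."""

import json

import numpy as np
import pytest
import tifffile
from shapely.geometry import box

from airineq.geoio import (
    GridField,
    MissingGeoreferenceError,
    MultiBandRasterError,
    OrphanTractError,
    RegionSet,
    CountyRecord,
    TractRecord,
    WeightsMatrix,
    ZeroAreaError,
    build_adjacency,
    county_index_grid,
    grid_adjacency,
    read_grid,
    read_regions,
    write_grid,
    write_regions,
)
from airineq.synth import make_regions, _county_index
from tests.conftest import small_config


class TestGridIO:
    def test_constant_field_round_trip(self, tmp_path):
        field = GridField(np.full((10, 10), 5.0), cell_size_km=1.0,
                          origin=(0.0, 10.0), label="PM1")
        path = write_grid(field, tmp_path / "c.tif")
        back = read_grid(path, label="PM1")
        assert back.values.shape == (10, 10)
        assert np.array_equal(back.values, field.values)
        assert back.cell_size_km == 1.0
        assert back.origin == (0.0, 10.0)

    def test_nodata_cells_masked(self, tmp_path):
        vals = np.arange(16, dtype=float).reshape(4, 4) + 1
        vals[0, 0] = vals[1, 2] = vals[3, 3] = np.nan
        field = GridField(vals, cell_size_km=2.0)
        back = read_grid(write_grid(field, tmp_path / "m.tif"))
        assert back.n_masked == 3
        assert np.array_equal(np.isnan(back.values), np.isnan(vals))

    def test_finite_nodata_sentinel(self, tmp_path):
        vals = np.ones((3, 3))
        vals[1, 1] = np.nan
        field = GridField(vals, cell_size_km=1.0, nodata=-9999.0)
        back = read_grid(write_grid(field, tmp_path / "s.tif"))
        assert back.n_masked == 1

    def test_random_field_round_trip(self, tmp_path, rng):
        vals = rng.exponential(size=(20, 15))
        field = GridField(vals, cell_size_km=0.5, origin=(12.0, 30.0))
        back = read_grid(write_grid(field, tmp_path / "r.tif"))
        np.testing.assert_allclose(back.values, vals, rtol=1e-12)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_grid(tmp_path / "absent.tif")

    def test_multiband_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "rgb.tif", np.zeros((8, 8, 3), dtype=np.float32),
                         photometric="rgb")
        with pytest.raises(MultiBandRasterError):
            read_grid(tmp_path / "rgb.tif")

    def test_missing_georeference(self, tmp_path):
        tifffile.imwrite(tmp_path / "plain.tif", np.zeros((8, 8), dtype=np.float32))
        with pytest.raises(MissingGeoreferenceError):
            read_grid(tmp_path / "plain.tif")

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            GridField(np.array([[-1.0, 2.0]]), cell_size_km=1.0)


class TestRegions:
    def test_square_partition(self, tmp_path):
        cfg = small_config(n_counties_x=2, n_counties_y=2, county_size_km=10.0,
                           tracts_per_county=4)
        regions = make_regions(cfg)
        write_regions(regions, tmp_path / "c.geojson", tmp_path / "t.geojson")
        back = read_regions(tmp_path / "c.geojson", tmp_path / "t.geojson")
        assert len(back.counties) == 4
        assert len(back.tracts) == 16
        for t in back.tracts:
            assert t.area_km2 == pytest.approx(25.0, rel=1e-3)
        assert back.county_ids == regions.county_ids

    def test_round_trip_preserves_income(self, tmp_path, small_province):
        write_regions(small_province.regions, tmp_path / "c.geojson",
                      tmp_path / "t.geojson")
        back = read_regions(tmp_path / "c.geojson", tmp_path / "t.geojson")
        for a, b in zip(small_province.regions.tracts, back.tracts):
            assert a.tract_id == b.tract_id
            assert b.area_km2 == pytest.approx(a.area_km2, rel=1e-3)
            assert b.population == pytest.approx(a.population, rel=1e-9)
            assert b.low_income_count == pytest.approx(a.low_income_count,
                                                       rel=1e-9)

    def test_orphan_tract_rejected(self, tmp_path):
        counties = [{"type": "Feature", "geometry":
                     json.loads(json.dumps({"type": "Polygon", "coordinates":
                                            [[[0, 0], [1, 0], [1, 1], [0, 1],
                                              [0, 0]]]})),
                     "properties": {"county_id": "A"}}]
        tracts = [dict(counties[0], properties={"county_id": "GHOST",
                                                "tract_id": "T0"})]
        (tmp_path / "c.geojson").write_text(json.dumps(
            {"type": "FeatureCollection", "features": counties}))
        (tmp_path / "t.geojson").write_text(json.dumps(
            {"type": "FeatureCollection", "features": tracts}))
        with pytest.raises(OrphanTractError):
            read_regions(tmp_path / "c.geojson", tmp_path / "t.geojson")

    def test_zero_area_rejected(self):
        with pytest.raises(ZeroAreaError):
            RegionSet(counties=[CountyRecord("A", box(0, 0, 1, 1), 0.0)],
                      tracts=[])

    def test_low_income_bounds_enforced(self):
        with pytest.raises(ValueError):
            RegionSet(
                counties=[CountyRecord("A", box(0, 0, 1, 1), 1.0)],
                tracts=[TractRecord("A", "T0", box(0, 0, 1, 1), 1.0,
                                    population=10, low_income_count=11)])


class TestAdjacency:
    def test_2x2_grid_rook(self):
        w = grid_adjacency((2, 2), "rook")
        assert (w.w.sum(axis=0) == 2).all()

    def test_2x2_grid_queen(self):
        w = grid_adjacency((2, 2), "queen")
        assert (w.w.sum(axis=0) == 3).all()

    def test_build_adjacency_accepts_grid_shape(self):
        w = build_adjacency((3, 3), "rook")
        # corner cells 2 neighbors, edges 3, center 4
        assert sorted(w.w.sum(axis=0)) == [2, 2, 2, 2, 3, 3, 3, 3, 4]

    def test_single_unit(self):
        w = build_adjacency([box(0, 0, 1, 1)], "queen")
        assert w.n == 1 and w.w.sum() == 0

    @pytest.mark.parametrize("rule", ["rook", "queen"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_polygon_adjacency_matches_brute_force(self, rule, seed, rng):
        # random rectangular tessellation: 4x5 grid with random breakpoints
        r = np.random.default_rng(seed)
        xs = np.concatenate([[0], np.sort(r.uniform(0.2, 9.8, 4)), [10]])
        ys = np.concatenate([[0], np.sort(r.uniform(0.2, 9.8, 3)), [10]])
        polys = [box(xs[i], ys[j], xs[i + 1], ys[j + 1])
                 for i in range(5) for j in range(4)]
        w = build_adjacency(polys, rule).w
        n = len(polys)
        for i in range(n):
            for j in range(n):
                if i == j:
                    expect = 0
                else:
                    inter = polys[i].intersection(polys[j])
                    touches = not inter.is_empty
                    expect = int(inter.length > 0 if rule == "rook" else touches)
                assert w[i, j] == expect

    @pytest.mark.parametrize("seed", [0, 7])
    def test_queen_contains_rook_and_symmetry(self, seed):
        r = np.random.default_rng(seed)
        xs = np.concatenate([[0], np.sort(r.uniform(1, 9, 3)), [10]])
        ys = np.concatenate([[0], np.sort(r.uniform(1, 9, 3)), [10]])
        polys = [box(xs[i], ys[j], xs[i + 1], ys[j + 1])
                 for i in range(4) for j in range(4)]
        rook = build_adjacency(polys, "rook").w
        queen = build_adjacency(polys, "queen").w
        assert np.all(queen >= rook)
        assert np.array_equal(queen, queen.T)
        assert np.all(np.diag(queen) == 0)

    def test_weights_matrix_validation(self):
        with pytest.raises(ValueError):
            WeightsMatrix(np.array([[0, 1], [0, 0]]))  # asymmetric
        with pytest.raises(ValueError):
            WeightsMatrix(np.array([[1, 0], [0, 0]]))  # nonzero diagonal


class TestZonalAssignment:
    def test_matches_analytic_county_layout(self, small_province):
        cfg = small_province.config
        grid = small_province.population
        idx = county_index_grid(small_province.regions, grid)
        assert np.array_equal(idx, _county_index(cfg))

    def test_outside_cells_unassigned(self):
        regions = RegionSet(
            counties=[CountyRecord("A", box(0, 0, 2, 2), 4.0)], tracts=[])
        grid = GridField(np.ones((4, 4)), cell_size_km=1.0, origin=(0.0, 4.0))
        idx = county_index_grid(regions, grid)
        assert (idx[2:, :2] == 0).all()
        assert (idx[:2, :] == -1).all()
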