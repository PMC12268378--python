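"""Urban centrality components, densities and the fuzzy-sum CPI."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from airineq.geoio import (CountyRecord, GridField, RegionSet, TractRecord,
                           UndefinedMetricError)
from airineq.urbanform import (densities, fuzzy_sum_cpi, local_coefficient,
                               separation_value, uci, vmax)


def simplex_grid_max(D: np.ndarray, step: int = 250) -> float:
    """Dense grid search over the simplex — the independent vmax oracle.

    Enumerates all share vectors on a resolution-1/step lattice
    (vectorised for 3 or 4 tracts); the grid maximum undershoots the true
    maximum by O(step^-2), so ``step=250`` resolves it to about 1e-4.
    """
    n = D.shape[0]
    if n == 3:
        i, j = np.meshgrid(np.arange(step + 1), np.arange(step + 1),
                           indexing="ij")
        ok = i + j <= step
        s = np.stack([i[ok], j[ok], step - i[ok] - j[ok]], axis=1) / step
    elif n == 4:
        grids = np.meshgrid(*([np.arange(step + 1)] * 3), indexing="ij")
        i, j, k = (g.ravel() for g in grids)
        ok = i + j + k <= step
        s = np.stack([i[ok], j[ok], k[ok], step - i[ok] - j[ok] - k[ok]],
                     axis=1) / step
    else:  # pragma: no cover - slow generic fallback
        best = 0.0
        for combo in itertools.combinations(range(step + n - 1), n - 1):
            parts = np.diff((-1,) + combo + (step + n - 1,)) - 1
            v = parts / step
            best = max(best, float(v @ D @ v))
        return best
    return float(np.einsum("ij,jk,ik->i", s, D, s).max())


def four_tract_county(cid="A", size=4.0) -> RegionSet:
    half = size / 2
    county = CountyRecord(cid, box(0, 0, size, size), size * size)
    tracts = [TractRecord(cid, f"T{i}", box(x, y, x + half, y + half),
                          half * half)
              for i, (x, y) in enumerate([(0, half), (half, half),
                                          (0, 0), (half, 0)])]
    return RegionSet(counties=[county], tracts=tracts)


class TestLocalCoefficient:
    def test_uniform_shares_give_zero(self):
        assert local_coefficient(np.full(5, 0.2)) == pytest.approx(0.0)

    def test_point_mass_four_tracts(self):
        assert local_coefficient([1.0, 0, 0, 0]) == pytest.approx(0.75)

    def test_hand_case(self):
        assert local_coefficient([0.5, 0.3, 0.2, 0.0]) == pytest.approx(0.30)

    def test_upper_bound(self, rng):
        for _ in range(10):
            e = rng.exponential(size=6)
            lc = local_coefficient(e / e.sum())
            assert 0.0 <= lc <= 5 / 6 + 1e-12

    def test_unnormalised_shares_rejected(self):
        with pytest.raises(ValueError):
            local_coefficient([0.5, 0.4])


class TestSeparationValue:
    def test_point_mass_is_zero(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert separation_value([1.0, 0.0], D) == 0.0

    def test_even_split_two_tracts(self):
        d = 7.0
        D = np.array([[0.0, d], [d, 0.0]])
        assert separation_value([0.5, 0.5], D) == pytest.approx(d / 2)

    def test_matches_double_loop(self, rng):
        n = 5
        pts = rng.uniform(0, 10, size=(n, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        e = rng.exponential(size=n)
        s = e / e.sum()
        loop = sum(s[i] * s[j] * D[i, j] for i in range(n) for j in range(n))
        assert separation_value(s, D) == pytest.approx(loop, rel=1e-12)

    def test_invalid_distance_matrix(self):
        with pytest.raises(ValueError):
            separation_value([0.5, 0.5], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestVmax:
    def test_two_tracts_closed_form(self):
        d = 5.0
        D = np.array([[0.0, d], [d, 0.0]])
        assert vmax(D) == pytest.approx(d / 2)

    def test_equilateral_matches_grid_search(self):
        d = 2.0
        D = d * (np.ones((3, 3)) - np.eye(3))
        want = simplex_grid_max(D, step=300)
        assert vmax(D) == pytest.approx(want, abs=1e-4)
        # barycentric allocation attains the maximum here
        assert vmax(D) == pytest.approx(2 * d / 3, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_four_tracts_match_grid_search(self, seed):
        r = np.random.default_rng(seed)
        pts = r.uniform(0, 10, size=(4, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        assert vmax(D) == pytest.approx(simplex_grid_max(D), abs=1e-4)

    def test_dominates_any_allocation(self, rng):
        pts = rng.uniform(0, 10, size=(6, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        vm = vmax(D)
        for _ in range(20):
            e = rng.exponential(size=6)
            s = e / e.sum()
            assert vm >= separation_value(s, D) - 1e-9

    def test_dominates_best_pair_split_large_n(self, rng):
        pts = rng.uniform(0, 100, size=(15, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        assert vmax(D) >= D.max() / 2 - 1e-9

    def test_single_tract(self):
        assert vmax(np.zeros((1, 1))) == 0.0


class TestUci:
    def test_point_mass_composition(self):
        regions = four_tract_county()
        xy = np.tile([[0.5, 3.5]], (10, 1))  # all POIs in the NW tract
        comp = uci(xy, regions, "A")
        assert comp.LC == pytest.approx(0.75)
        assert comp.V == pytest.approx(0.0)
        assert comp.PI == pytest.approx(1.0)
        assert comp.UCI == pytest.approx(0.75)

    def test_uniform_counts_give_zero(self):
        regions = four_tract_county()
        xy = np.array([[0.5, 3.5], [2.5, 3.5], [0.5, 0.5], [2.5, 0.5]] * 3)
        assert uci(xy, regions, "A").UCI == pytest.approx(0.0)

    def test_within_tract_position_irrelevant(self, rng):
        regions = four_tract_county()
        base = np.array([[0.5, 3.5], [0.7, 2.3], [2.5, 1.5], [3.9, 0.1],
                         [1.1, 3.9]])
        jitter = base + rng.uniform(-0.05, 0.05, size=base.shape)
        assert uci(base, regions, "A").UCI == pytest.approx(
            uci(jitter, regions, "A").UCI)

    def test_no_pois_undefined(self):
        with pytest.raises(UndefinedMetricError):
            uci(np.empty((0, 2)), four_tract_county(), "A")


class TestDensities:
    def test_simple_division(self, rng):
        regions = RegionSet(
            counties=[CountyRecord("A", box(0, 0, 5, 5), 25.0)], tracts=[])
        import pandas as pd
        poi = pd.DataFrame({"x": rng.uniform(0, 5, 50),
                            "y": rng.uniform(0, 5, 50),
                            "category": "park"})
        roads = pd.DataFrame({"county_id": ["A"], "n_segments": [100]})
        pop = GridField(np.full((5, 5), 8.0), cell_size_km=1.0, origin=(0, 5))
        out = densities(regions, poi, roads, pop)
        assert out.loc["A", "poi_density"] == pytest.approx(2.0)
        assert out.loc["A", "road_density"] == pytest.approx(4.0)
        assert out.loc["A", "pop_density"] == pytest.approx(8.0)

    def test_doubling_area_halves_density(self, rng):
        import pandas as pd
        poi = pd.DataFrame({"x": rng.uniform(0, 5, 40),
                            "y": rng.uniform(0, 5, 40), "category": "bank"})
        roads = pd.DataFrame({"county_id": ["A"], "n_segments": [60]})
        small = RegionSet(counties=[CountyRecord("A", box(0, 0, 5, 5), 25.0)],
                          tracts=[])
        big = RegionSet(counties=[CountyRecord("A", box(0, 0, 10, 10), 100.0)],
                        tracts=[])
        pop_s = GridField(np.ones((5, 5)), cell_size_km=1.0, origin=(0, 5))
        pop_b = GridField(np.ones((10, 10)), cell_size_km=1.0, origin=(0, 10))
        d_small = densities(small, poi, roads, pop_s)
        d_big = densities(big, poi, roads, pop_b)
        assert d_big.loc["A", "poi_density"] == pytest.approx(
            d_small.loc["A", "poi_density"] / 4)

    def test_poi_count_matches_brute_force(self, small_province):
        out = densities(small_province.regions, small_province.poi,
                        small_province.roads, small_province.population)
        county = small_province.regions.counties[7]
        inside = 0
        for _, row in small_province.poi.iterrows():
            minx, miny, maxx, maxy = county.polygon.bounds
            if minx <= row.x <= maxx and miny <= row.y <= maxy:
                inside += 1
        assert out.loc[county.county_id, "poi_density"] == pytest.approx(
            inside / county.area_km2)


class TestFuzzySum:
    def test_zero_identity(self):
        assert fuzzy_sum_cpi(0.0, 0.0) == 0.0

    @pytest.mark.parametrize("x", [0.0, 0.3, 1.0])
    def test_one_absorbs(self, x):
        assert fuzzy_sum_cpi(1.0, x) == pytest.approx(1.0)

    def test_half_half(self):
        assert fuzzy_sum_cpi(0.5, 0.5) == pytest.approx(0.75)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_commutative_monotone_bounded(self, a, b, c):
        ab = fuzzy_sum_cpi(a, b)
        assert ab == pytest.approx(fuzzy_sum_cpi(b, a))
        assert max(a, b) - 1e-12 <= ab <= 1.0
        if c >= b:
            assert fuzzy_sum_cpi(a, c) >= ab - 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_sum_cpi(1.2, 0.5)
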