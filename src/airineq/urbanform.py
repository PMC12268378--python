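"""Urban-form and environmental indicators.

The urban centrality index (UCI) is the product of the local
coefficient LC = 1/2 sum_i |k_i - 1/N| (unevenness of the POI shares
k_i across a county's N tracts) and the proximity index
PI = 1 - V/Vmax, where V = k' D k is the distance-weighted quadratic
form of the shares over the tract-centroid distance matrix D and Vmax
is the maximum of that form over the probability simplex.  A point mass
in one tract gives LC = (N-1)/N, V = 0, PI = 1 — maximal centrality;
shares spread over mutually distant tracts drive PI toward 0.

Also here: POI / road / population densities (count or total divided by
county area) and the conversion-pressure index, the fuzzy sum
(probabilistic OR) of projected human modification and development
suitability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import shapely

from .geoio import GridField, RegionSet, UndefinedMetricError, county_index_grid

__all__ = ["UCIComponents", "local_coefficient", "separation_value", "vmax",
           "uci", "uci_table", "densities", "fuzzy_sum_cpi"]


@dataclass(frozen=True)
class UCIComponents:
    LC: float
    V: float
    Vmax: float
    PI: float
    UCI: float
    n_tracts: int
    n_poi: int
    degenerate: bool = False  # single tract: PI = 1 by convention


def local_coefficient(poi_shares: np.ndarray) -> float:
    """LC = 1/2 sum_i |k_i - 1/N| for POI proportions k_i summing to 1."""
    k = np.asarray(poi_shares, dtype=float)
    if k.ndim != 1 or k.size == 0:
        raise ValueError("poi_shares must be a non-empty vector")
    if abs(k.sum() - 1.0) > 1e-9:
        raise ValueError(f"poi_shares must sum to 1, got {k.sum()!r}")
    n = len(k)
    return float(0.5 * np.abs(k - 1.0 / n).sum())


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("D must be symmetric, non-negative, zero-diagonal")
    return D


def separation_value(poi_shares: np.ndarray, D: np.ndarray) -> float:
    """V = k' D k, the average pairwise distance weighted by share mass."""
    k = np.asarray(poi_shares, dtype=float)
    D = _check_distance_matrix(D)
    if len(k) != D.shape[0]:
        raise ValueError("shares and D must be conformable")
    return float(k @ D @ k)


# counties sharing one tract template (regular subdivisions) share D, so
# the simplex maximisation is memoised on a fingerprint of the matrix
_VMAX_CACHE: dict[bytes, float] = {}
_VMAX_CACHE_MAX = 256


def vmax(D: np.ndarray, n_starts: int = 32, seed: int = 0) -> float:
    """Maximum of s' D s over the probability simplex.

    For up to 12 tracts, exact by support enumeration: on each candidate
    support the stationary point solves D_S s = mu 1 with s >= 0 summing
    to 1, and all vertices/edges are covered by the subset sweep.  Above
    12 tracts, multi-start projected gradient ascent seeded at every
    pairwise split (the best two-point value max_ij D_ij / 2 is always a
    lower bound).
    """
    D = _check_distance_matrix(D)
    n = D.shape[0]
    if n == 1:
        return 0.0
    key = np.round(D, 9).tobytes()
    if key in _VMAX_CACHE:
        return _VMAX_CACHE[key]
    pair_best = float(D.max() / 2.0)
    if n <= 12:
        best = 0.0
        idx = np.arange(n)
        for size in range(2, n + 1):
            for S in combinations(idx, size):
                Ds = D[np.ix_(S, S)]
                try:
                    u = np.linalg.solve(Ds, np.ones(size))
                except np.linalg.LinAlgError:
                    continue
                total = u.sum()
                if abs(total) < 1e-12:
                    continue
                s = u / total
                if np.any(s < -1e-10):
                    continue
                s = np.clip(s, 0.0, None)
                s /= s.sum()
                best = max(best, float(s @ Ds @ s))
        return _vmax_store(key, max(best, pair_best))
    # large-n fallback: projected gradient ascent from pairwise splits
    rng = np.random.default_rng(seed)
    starts = [np.full(n, 1.0 / n)]
    i, j = np.unravel_index(np.argmax(D), D.shape)
    s0 = np.zeros(n)
    s0[[i, j]] = 0.5
    starts.append(s0)
    for _ in range(n_starts):
        e = rng.exponential(size=n)
        starts.append(e / e.sum())
    best = pair_best
    for s in starts:
        s = s.copy()
        for _ in range(500):
            g = 2.0 * D @ s
            step = 0.1 / max(np.abs(g).max(), 1e-12)
            s_new = _project_simplex(s + step * g)
            if np.abs(s_new - s).max() < 1e-10:
                s = s_new
                break
            s = s_new
        best = max(best, float(s @ D @ s))
    return _vmax_store(key, best)


def _vmax_store(key: bytes, value: float) -> float:
    if len(_VMAX_CACHE) >= _VMAX_CACHE_MAX:
        _VMAX_CACHE.clear()
    _VMAX_CACHE[key] = value
    return value


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / (np.arange(len(v)) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def uci(poi_xy: np.ndarray, regions: RegionSet, county_id: str) -> UCIComponents:
    """UCI of one county from POI coordinates and its tract polygons.

    Counts POIs per tract (point in polygon), forms shares and composes
    LC, V, Vmax, PI = 1 - V/Vmax and UCI = LC * PI.  Zero POIs in the
    county is undefined; a single tract gets PI = 1 by convention and is
    flagged ``degenerate``.
    """
    tracts = regions.tracts_of(county_id)
    if not tracts:
        raise ValueError(f"county {county_id} has no tracts")
    xy = np.asarray(poi_xy, dtype=float).reshape(-1, 2)
    counts = np.zeros(len(tracts))
    claimed = np.zeros(len(xy), dtype=bool)
    for i, t in enumerate(tracts):
        if len(xy) == 0:
            break
        hit = shapely.intersects_xy(t.polygon, xy[:, 0], xy[:, 1]) & ~claimed
        counts[i] = hit.sum()
        claimed |= hit
    n_poi = int(counts.sum())
    if n_poi == 0:
        raise UndefinedMetricError(f"county {county_id}: no POIs, UCI undefined")
    shares = counts / n_poi
    lc = local_coefficient(shares)
    cents = np.array([[t.polygon.centroid.x, t.polygon.centroid.y] for t in tracts])
    D = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=-1)
    v = separation_value(shares, D)
    if len(tracts) == 1:
        return UCIComponents(LC=lc, V=0.0, Vmax=0.0, PI=1.0, UCI=lc * 1.0,
                             n_tracts=1, n_poi=n_poi, degenerate=True)
    vm = vmax(D)
    pi = 1.0 - v / vm if vm > 0 else 1.0
    return UCIComponents(LC=lc, V=v, Vmax=vm, PI=pi, UCI=lc * pi,
                         n_tracts=len(tracts), n_poi=n_poi)


def uci_table(poi: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """UCI components per county; POIs assigned by their coordinates.

    Counties without POIs get NaN components and are listed in
    ``attrs['undefined']``.
    """
    rows, undefined = [], []
    xy_all = poi[["x", "y"]].to_numpy()
    for ci, county in enumerate(regions.counties):
        minx, miny, maxx, maxy = county.polygon.bounds
        sel = ((xy_all[:, 0] >= minx) & (xy_all[:, 0] <= maxx)
               & (xy_all[:, 1] >= miny) & (xy_all[:, 1] <= maxy))
        try:
            comp = uci(xy_all[sel], regions, county.county_id)
            rows.append((county.county_id, comp.LC, comp.V, comp.Vmax,
                         comp.PI, comp.UCI, comp.n_poi))
        except UndefinedMetricError:
            undefined.append(county.county_id)
            rows.append((county.county_id, *([np.nan] * 5), 0))
    out = pd.DataFrame(rows, columns=["county_id", "LC", "V", "Vmax", "PI",
                                      "UCI", "n_poi"]).set_index("county_id")
    out.attrs["undefined"] = undefined
    return out


def densities(regions: RegionSet, poi: pd.DataFrame, roads: pd.DataFrame,
              pop: GridField) -> pd.DataFrame:
    """POI, road and population density per county (per km^2)."""
    area = pd.Series({c.county_id: c.area_km2 for c in regions.counties})
    xy = poi[["x", "y"]].to_numpy()
    counts = pd.Series(0.0, index=area.index)
    for county in regions.counties:
        hit = shapely.intersects_xy(county.polygon, xy[:, 0], xy[:, 1])
        counts[county.county_id] = float(hit.sum())
    road_counts = roads.set_index("county_id")["n_segments"].reindex(area.index,
                                                                     fill_value=0)
    cidx = county_index_grid(regions, pop)
    pops = np.zeros(len(area))
    ok = cidx.ravel() >= 0
    np.add.at(pops, cidx.ravel()[ok], np.nan_to_num(pop.values.ravel())[ok])
    out = pd.DataFrame({
        "poi_density": counts / area,
        "road_density": road_counts / area,
        "pop_density": pd.Series(pops, index=area.index) / area,
    })
    out.index.name = "county_id"
    return out


def fuzzy_sum_cpi(hm2030, dsi):
    """Conversion-pressure index: fuzzy sum 1 - (1 - HM2030)(1 - DSI).

    Accepts scalars or arrays in [0, 1]; commutative, monotone, and
    bounded below by max of the inputs (probabilistic OR).
    """
    a = np.asarray(hm2030, dtype=float)
    b = np.asarray(dsi, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("fuzzy_sum_cpi inputs must lie in [0, 1]")
    out = 1.0 - (1.0 - a) * (1.0 - b)
    return float(out) if out.ndim == 0 else out
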