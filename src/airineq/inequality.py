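"""Within-county inequality measures.

Two statistics: the spatial Gini index (SGI) of the pollution surface,
whose numerator sums absolute differences only over spatially adjacent
sub-unit pairs,

    SGI = sum_i sum_j w_ij |x_i - x_j| / (2 N^2 xbar),

and the dissimilarity index (DI) of income segregation across a
county's tracts,

    DI = 1/2 sum_i |P_i/P - Q_i/Q|,

with P_i the low-income and Q_i the total population of tract i.  SGI is
computed within each county over its pixels (rook adjacency by default);
because only adjacent pairs enter the numerator while the 2 N^2 xbar
normalisation counts all pairs, SGI is bounded above by the classical
Gini of the same values and shrinks with pixel count at fixed surface
roughness — it is a relative, not absolute, inequality scale across
counties of similar size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geoio import (
    GridField,
    RegionSet,
    UndefinedMetricError,
    WeightsMatrix,
    county_index_grid,
)

__all__ = ["spatial_gini", "county_sgi", "sgi_table",
           "dissimilarity_index", "segregation_table"]


def spatial_gini(x: np.ndarray, w: WeightsMatrix) -> float:
    """Adjacency-restricted Gini: sum_ij w_ij |x_i - x_j| / (2 N^2 xbar)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != w.n:
        raise ValueError("x must be a vector conformable with w")
    if np.any(x < 0):
        raise ValueError("spatial_gini requires non-negative values")
    xbar = x.mean()
    if not xbar > 0:
        raise UndefinedMetricError("spatial_gini undefined for zero-mean values")
    diff = np.abs(x[:, None] - x[None, :])
    return float((w.w * diff).sum() / (2.0 * len(x) ** 2 * xbar))


def _grid_sgi(values: np.ndarray, rule: str) -> float:
    """SGI of a rectangular pixel block, without materialising W.

    Sums |differences| over horizontal/vertical (and diagonal, for
    queen) neighbor pairs; NaN pixels are excluded from both the pairs
    and the mean.
    """
    v = values
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedMetricError("county has no valid pixels")
    xbar = float(v[ok].mean())
    if not xbar > 0:
        raise UndefinedMetricError("spatial_gini undefined for zero-mean values")
    if n == 1:
        return 0.0
    pairs = [(v[:, :-1], v[:, 1:]), (v[:-1, :], v[1:, :])]
    if rule == "queen":
        pairs += [(v[:-1, :-1], v[1:, 1:]), (v[:-1, 1:], v[1:, :-1])]
    total = 0.0
    for a, b in pairs:
        d = np.abs(a - b)
        total += np.nansum(d)
    # each unordered neighbor pair counted once above; the double sum
    # counts ordered pairs, hence the factor 2
    return float(2.0 * total / (2.0 * n ** 2 * xbar))


def county_sgi(conc_decayed: GridField, regions: RegionSet, rule: str = "rook",
               pop: GridField | None = None) -> pd.Series:
    """SGI per county over its pixels.

    Sub-units are the pixels whose centers fall in the county; adjacency
    is rook (shared edge) or queen (edge or corner) on the pixel grid.
    With ``pop`` given, x_i is the population-weighted value P_i C_i^d
    (inequality of exposure rather than of concentration).  Counties
    whose pixels are all nodata get NaN and are listed in
    ``attrs['undefined']``; single-pixel counties get 0.
    """
    if rule not in ("rook", "queen"):
        raise ValueError(f"unknown adjacency rule {rule!r}")
    values = conc_decayed.values
    if pop is not None:
        values = values * pop.values
    cidx = county_index_grid(regions, conc_decayed)
    out = np.full(len(regions.counties), np.nan)
    undefined = []
    for i, cid in enumerate(regions.county_ids):
        rows, cols = np.nonzero(cidx == i)
        if rows.size == 0:
            undefined.append(cid)
            continue
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        block = np.full((r1 - r0, c1 - c0), np.nan)
        block[rows - r0, cols - c0] = values[rows, cols]
        try:
            out[i] = _grid_sgi(block, rule)
        except UndefinedMetricError:
            undefined.append(cid)
    res = pd.Series(out, index=pd.Index(regions.county_ids, name="county_id"),
                    name="SGI")
    res.attrs["undefined"] = undefined
    return res


def sgi_table(decayed: dict[str, GridField], regions: RegionSet,
              rule: str = "rook", pop: GridField | None = None) -> pd.DataFrame:
    """SGI per pollutant plus the combined surface, one row per county."""
    from .exposure import combine_pollutants

    cols = {f"SGI_{p.replace('.', '')}": county_sgi(f, regions, rule, pop)
            for p, f in decayed.items()}
    combined = combine_pollutants(decayed["PM1"], decayed["PM2.5"], decayed["PM10"])
    cols["SGI_combined"] = county_sgi(combined, regions, rule, pop)
    return pd.DataFrame(cols)


def dissimilarity_index(low_income: np.ndarray, total: np.ndarray) -> float:
    """DI = 1/2 sum_i |P_i/P - Q_i/Q| over one county's tracts."""
    p = np.asarray(low_income, dtype=float)
    q = np.asarray(total, dtype=float)
    if p.shape != q.shape:
        raise ValueError("low_income and total must align")
    if np.any(p < 0) or np.any(q < 0) or np.any(p > q):
        raise ValueError("need 0 <= low_income <= total per tract")
    P, Q = p.sum(), q.sum()
    if not P > 0:
        raise UndefinedMetricError("DI undefined: no low-income individuals")
    if not Q > 0:
        raise UndefinedMetricError("DI undefined: empty county")
    return float(0.5 * np.abs(p / P - q / Q).sum())


def segregation_table(regions: RegionSet) -> pd.DataFrame:
    """DI per county from the tract population/low-income counts."""
    rows, undefined = [], []
    for cid in regions.county_ids:
        tr = regions.tracts_of(cid)
        p = np.array([t.low_income_count for t in tr])
        q = np.array([t.population for t in tr])
        try:
            rows.append((cid, dissimilarity_index(p, q)))
        except UndefinedMetricError:
            rows.append((cid, np.nan))
            undefined.append(cid)
    out = pd.DataFrame(rows, columns=["county_id", "DI"]).set_index("county_id")
    out.attrs["undefined"] = undefined
    return out
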