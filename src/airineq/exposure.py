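"""Population-weighted air-pollution exposure (APE) per county.

The county exposure is APE = sum_i P_i C_i^d / sum_i P_i over the
county's pixels, where C^d is the concentration after a distance-decay
adjustment: a kernel-weighted mean over all cells whose centers lie
within a buffer distance (1 km by default) of the target cell, which
folds the influence of nearby pollution into each pixel.  The combined
pollution indicator is the cell-wise sum of the PM1, PM2.5 and PM10
surfaces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

from .geoio import GridField, RegionSet, UndefinedMetricError, county_index_grid

__all__ = ["decay_adjust", "compute_ape", "combine_pollutants", "exposure_table"]


def _kernel(buffer_km: float, cell_km: float, kind: str) -> np.ndarray:
    """Kernel over cell-center offsets within ``buffer_km`` of the center."""
    r = int(np.floor(buffer_km / cell_km + 1e-9))
    off = np.arange(-r, r + 1) * cell_km
    d = np.hypot(off[:, None], off[None, :])
    inside = d <= buffer_km + 1e-9
    if kind == "uniform":
        k = inside.astype(float)
    elif kind == "inverse_distance":
        # weight 1/(d + half cell) so the center cell dominates but stays finite
        k = np.where(inside, 1.0 / (d + cell_km / 2.0), 0.0)
    else:
        raise ValueError(f"unknown kernel {kind!r}")
    return k


def decay_adjust(conc: GridField, buffer_km: float = 1.0,
                 kernel: str = "uniform") -> GridField:
    """Distance-decay adjustment: kernel mean within the buffer.

    ``buffer_km = 0`` returns the field unchanged.  Nodata cells are
    excluded from every kernel and stay nodata in the output.
    """
    if buffer_km == 0:
        return conc.like(conc.values.copy())
    if buffer_km < conc.cell_size_km:
        raise ValueError("buffer_km must be 0 or at least one cell size")
    mask = conc.mask
    if mask.all():
        raise UndefinedMetricError("decay_adjust: all cells are nodata")
    k = _kernel(buffer_km, conc.cell_size_km, kernel)
    filled = np.where(mask, 0.0, conc.values)
    valid = (~mask).astype(float)
    num = convolve(filled, k, mode="constant", cval=0.0)
    den = convolve(valid, k, mode="constant", cval=0.0)
    out = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    out[mask] = np.nan
    return conc.like(out)


def combine_pollutants(pm1: GridField, pm25: GridField, pm10: GridField) -> GridField:
    """Cell-wise sum of the three fractions; nodata anywhere propagates."""
    for other in (pm25, pm10):
        if other.shape != pm1.shape or other.cell_size_km != pm1.cell_size_km \
                or other.origin != pm1.origin:
            raise ValueError("pollutant grids must share geometry")
    return pm1.like(pm1.values + pm25.values + pm10.values, label="combined")


def compute_ape(conc_decayed: GridField, pop: GridField,
                regions: RegionSet) -> pd.Series:
    """Population-weighted mean of the decayed concentration per county.

    Counties with zero total population (or no valid pixels) get NaN and
    are reported via the returned Series' ``attrs['undefined']`` list
    rather than silently dropped.
    """
    if conc_decayed.shape != pop.shape:
        raise ValueError("concentration and population grids must share geometry")
    cidx = county_index_grid(regions, conc_decayed)
    n = len(regions.counties)
    c = conc_decayed.values.ravel()
    p = np.nan_to_num(pop.values.ravel())
    ci = cidx.ravel()
    ok = (ci >= 0) & ~np.isnan(c)
    num = np.bincount(ci[ok], weights=(p * np.nan_to_num(c))[ok], minlength=n)
    den = np.bincount(ci[ok], weights=p[ok], minlength=n)
    ape = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    out = pd.Series(ape, index=pd.Index(regions.county_ids, name="county_id"),
                    name="APE")
    out.attrs["undefined"] = [cid for cid, d in zip(regions.county_ids, den) if d <= 0]
    return out


def exposure_table(concentrations: dict[str, GridField], pop: GridField,
                   regions: RegionSet, buffer_km: float = 1.0,
                   kernel: str = "uniform") -> pd.DataFrame:
    """APE per pollutant plus the combined indicator, one row per county.

    The decay adjustment is applied to each pollutant before summing;
    for linear kernels this equals decaying the sum.
    """
    decayed = {p: decay_adjust(f, buffer_km, kernel)
               for p, f in concentrations.items()}
    cols = {}
    for p, f in decayed.items():
        cols[f"APE_{p.replace('.', '')}"] = compute_ape(f, pop, regions)
    combined = combine_pollutants(decayed["PM1"], decayed["PM2.5"], decayed["PM10"])
    cols["APE_combined"] = compute_ape(combined, pop, regions)
    return pd.DataFrame(cols)
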