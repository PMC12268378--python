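"""Synthetic study-region generator with planted statistical structure.

Produces a fully artificial province — gridded pollutant and population
surfaces, county/tract polygons, POI points, road counts and county
covariate tables — whose joint distribution contains controllable,
recoverable structure:

* spatially autocorrelated log-concentration fields (exponential
  covariance, configurable range);
* a heavy-tailed (log-normal) population surface with per-county density
  peaks whose sharpness is set by ``centrality_level``;
* within-county income segregation set by ``segregation_level`` and, per
  county, by a latent "economic activity / segregation" factor;
* POI clustering governed by ``centrality_level``;
* county covariates organised around two independent latent county
  factors — F1 ("development density": population, POI and road density,
  temperature, depressed NDVI) and F2 ("economic activity and
  segregation": GDP, land-conversion pressure, income segregation);
* planted linear effects of covariates on log county-mean concentration
  (``effect_sizes``), and within-county concentration heterogeneity tied
  to the county's segregation draw, so that mean exposure and its
  spatial inequality are controlled independently.

All randomness derives from one global seed through fixed per-stream
sub-seeds, so adding a stream never perturbs the others and every
``simulate_*`` function is deterministic given the config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geoio import (
    CountyRecord,
    GridField,
    RegionSet,
    TractRecord,
    county_index_grid,
    write_grid,
    write_regions,
)

__all__ = [
    "SyntheticConfig",
    "Province",
    "POLLUTANTS",
    "INDICATOR_NAMES",
    "make_regions",
    "simulate_concentration",
    "simulate_population",
    "simulate_tracts_income",
    "simulate_poi_roads",
    "simulate_covariates",
    "county_segregation",
    "generate_province",
    "write_province",
]

POLLUTANTS = ("PM1", "PM2.5", "PM10")
# annual-mean levels (ug/m3) anchoring the three fractions; strictly
# increasing so the cell-wise ordering PM1 < PM2.5 < PM10 always holds
_BASE_LEVEL = {"PM1": 21.0, "PM2.5": 33.0, "PM10": 54.0}

INDICATOR_NAMES = (
    "road_density", "poi_density", "UCI", "pop_density", "GDP",
    "income_segregation", "CPI", "MAT", "MAP", "NDVI", "SAP", "VC",
)
# covariates usable as planted drivers of log county-mean concentration
_TILTABLE = set(INDICATOR_NAMES) - {"UCI"}

# fixed sub-stream codes; appending here never perturbs existing streams
_STREAM = {"latent": 1, "conc": 2, "pop": 3, "income": 4, "poi": 5,
           "roads": 6, "covars": 7, "tilt": 8, "rough": 9}

_POI_CATEGORIES = ("restaurant", "school", "grocery", "gas_station",
                   "pharmacy", "bank", "hospital", "park", "shopping")


def _default_effects() -> dict[str, float]:
    return {"pop_density": 0.3, "MAT": 0.3, "NDVI": -0.3}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic province.

    ``effect_sizes`` maps indicator names to linear effects on the
    z-score scale of log county-mean concentration; heavy-tailed
    covariates (pop_density, GDP, poi_density, MAP, SAP, VC) enter
    through the z-score of their natural log, matching the scale on
    which the driver analysis operates.
    """

    n_counties_x: int = 10
    n_counties_y: int = 10
    county_size_km: float = 10.0
    cell_size_km: float = 1.0
    tracts_per_county: int = 16
    seed: int = 0
    spatial_range_km: float = 25.0
    conc_log_sd: float = 0.2
    population_lognormal_mu: float = 5.0
    population_lognormal_sigma: float = 1.0
    segregation_level: float = 0.3
    centrality_level: float = 0.5
    effect_sizes: dict[str, float] = dc_field(default_factory=_default_effects)
    noise_sd: float = 0.1
    poi_cluster_sd_km: float = 1.0
    poi_per_capita: float = 0.005
    roads_per_capita: float = 0.02
    heterogeneity_base: float = 0.5
    heterogeneity_gain: float = 2.0
    roughness_sd: float = 0.35
    roughness_range_km: float = 3.0
    tilt_smoothing_km: float = 2.0
    latent_range_km: float = 12.0
    poi_rate_log_sd: float = 0.4

    def __post_init__(self) -> None:
        ratio = self.county_size_km / self.cell_size_km
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("county_size_km must be a multiple of cell_size_km")
        for name, val in (("segregation_level", self.segregation_level),
                          ("centrality_level", self.centrality_level)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        unknown = set(self.effect_sizes) - _TILTABLE
        if unknown:
            raise ValueError(f"unknown indicator(s) in effect_sizes: {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    # grid geometry -----------------------------------------------------
    @property
    def cells_per_county_side(self) -> int:
        return int(round(self.county_size_km / self.cell_size_km))

    @property
    def grid_shape(self) -> tuple[int, int]:
        m = self.cells_per_county_side
        return self.n_counties_y * m, self.n_counties_x * m

    @property
    def n_counties(self) -> int:
        return self.n_counties_x * self.n_counties_y

    @property
    def origin(self) -> tuple[float, float]:
        return (0.0, self.n_counties_y * self.county_size_km)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2 ** 31), _STREAM[stream]])


@dataclass
class Province:
    """Everything the downstream pipeline consumes."""

    config: SyntheticConfig
    regions: RegionSet
    concentration: dict[str, GridField]
    population: GridField
    poi: pd.DataFrame
    roads: pd.DataFrame
    covariates: pd.DataFrame


# ---------------------------------------------------------------------------
# geometry


def _tract_layout(t: int) -> tuple[int, int]:
    """Divisor pair of ``t`` closest to square (rows, cols)."""
    best = (1, t)
    for r in range(1, int(np.sqrt(t)) + 1):
        if t % r == 0:
            best = (r, t // r)
    return best


def make_regions(config: SyntheticConfig) -> RegionSet:
    """Rectangular grid of square counties, each a regular tract grid."""
    size = config.county_size_km
    top = config.n_counties_y * size
    tr, tc = _tract_layout(config.tracts_per_county)
    counties, tracts = [], []
    for cy in range(config.n_counties_y):
        for cx in range(config.n_counties_x):
            cid = f"C{cy * config.n_counties_x + cx:03d}"
            x0, x1 = cx * size, (cx + 1) * size
            y1, y0 = top - cy * size, top - (cy + 1) * size
            counties.append(CountyRecord(cid, box(x0, y0, x1, y1), size * size))
            dy, dx = size / tr, size / tc
            for ty in range(tr):
                for tx in range(tc):
                    tracts.append(TractRecord(
                        county_id=cid,
                        tract_id=f"{cid}_T{ty * tc + tx:02d}",
                        polygon=box(x0 + tx * dx, y1 - (ty + 1) * dy,
                                    x0 + (tx + 1) * dx, y1 - ty * dy),
                        area_km2=dx * dy,
                    ))
    return RegionSet(counties=counties, tracts=tracts)


def _county_index(config: SyntheticConfig) -> np.ndarray:
    """Pixel-to-county index for the regular layout (analytic, no geometry)."""
    ny, nx = config.grid_shape
    m = config.cells_per_county_side
    row_c = np.arange(ny) // m
    col_c = np.arange(nx) // m
    return (row_c[:, None] * config.n_counties_x + col_c[None, :]).astype(np.int64)


# ---------------------------------------------------------------------------
# Gaussian random field


def _gaussian_field(shape: tuple[int, int], cell_km: float, range_km: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary field with exponential covariance exp(-h/r).

    Exact Cholesky factorisation for small grids; circulant embedding on
    the doubled torus (negative embedding eigenvalues clipped to zero)
    for larger ones.
    """
    ny, nx = shape
    if range_km <= 0:
        return rng.standard_normal(shape)
    if ny * nx <= 2500:
        yy, xx = np.mgrid[0:ny, 0:nx]
        pts = np.column_stack([xx.ravel() * cell_km, yy.ravel() * cell_km])
        h = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        cov = np.exp(-h / range_km)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
        return (chol @ rng.standard_normal(len(cov))).reshape(shape)
    m, n = 2 * ny, 2 * nx
    wy = np.minimum(np.arange(m), m - np.arange(m)) * cell_km
    wx = np.minimum(np.arange(n), n - np.arange(n)) * cell_km
    h = np.hypot(wy[:, None], wx[None, :])
    lam = np.fft.fft2(np.exp(-h / range_km)).real
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
    f = np.fft.fft2(np.sqrt(lam / (m * n)) * z)
    return f.real[:ny, :nx]


def _shared_log_anomaly(config: SyntheticConfig) -> np.ndarray:
    """The latent log-concentration anomaly shared by all three pollutants."""
    return _gaussian_field(config.grid_shape, config.cell_size_km,
                           config.spatial_range_km, config.rng("conc"))


def simulate_concentration(config: SyntheticConfig, pollutant: str) -> GridField:
    """Log-Gaussian concentration surface for one particulate fraction.

    All fractions share a single latent field per seed, scaled by
    fraction-specific base levels, so PM1 < PM2.5 < PM10 cell-wise.
    """
    if pollutant not in _BASE_LEVEL:
        raise ValueError(f"unknown pollutant {pollutant!r}; expected one of {POLLUTANTS}")
    z = _shared_log_anomaly(config)
    values = _BASE_LEVEL[pollutant] * np.exp(config.conc_log_sd * z)
    return GridField(values=values, cell_size_km=config.cell_size_km,
                     origin=config.origin, label=pollutant)


# ---------------------------------------------------------------------------
# latent county factors


def _latent_factors(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Two independent unit-variance county factors (F1, F2).

    Both are spatially smooth over the county lattice (exponential
    covariance, range ``latent_range_km``), as development intensity and
    economic activity are in real provinces; neighbouring counties thus
    have similar covariates and the concentration surface stays free of
    large artificial county-border steps.
    """
    rng = config.rng("latent")
    shape = (config.n_counties_y, config.n_counties_x)
    f1 = _gaussian_field(shape, config.county_size_km, config.latent_range_km, rng)
    f2 = _gaussian_field(shape, config.county_size_km, config.latent_range_km, rng)
    return f1.ravel(), f2.ravel()


def county_segregation(config: SyntheticConfig) -> np.ndarray:
    """Per-county segregation intensity in [0, 1].

    Centred on ``segregation_level`` and spread along the latent F2
    (economic activity / segregation) factor; exactly degenerate at the
    endpoints 0 and 1.
    """
    _, f2 = _latent_factors(config)
    s = config.segregation_level
    spread = 0.25 * min(s, 1.0 - s) / 0.5
    return np.clip(s + spread * f2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# population


def simulate_population(config: SyntheticConfig) -> GridField:
    """Log-normal marks times a smooth per-county density surface.

    The within-county surface peaks at the county center with sharpness
    set by ``centrality_level``; the county-level scale loads on the
    latent F1 factor so population density is part of the "development
    density" axis.
    """
    rng = config.rng("pop")
    ny, nx = config.grid_shape
    marks = np.exp(config.population_lognormal_mu
                   + config.population_lognormal_sigma * rng.standard_normal((ny, nx)))
    m = config.cells_per_county_side
    # within-county distance (cells) to the county-center cell
    off = (np.arange(m) - (m - 1) / 2.0) * config.cell_size_km
    d2 = off[:, None] ** 2 + off[None, :] ** 2
    sigma = max(config.county_size_km / 6.0, config.cell_size_km)
    peak = np.exp(-d2 / (2.0 * sigma ** 2))
    c = config.centrality_level
    tile = (1.0 - c) + c * peak
    weight = np.tile(tile, (config.n_counties_y, config.n_counties_x))
    f1, _ = _latent_factors(config)
    scale = np.exp(0.8 * f1)[_county_index(config)]
    return GridField(values=marks * weight * scale, cell_size_km=config.cell_size_km,
                     origin=config.origin, label="population")


# ---------------------------------------------------------------------------
# tracts and income


def _tract_population(config: SyntheticConfig, regions: RegionSet,
                      pop: GridField) -> dict[str, float]:
    """Sum the population surface over each tract (pixel centers)."""
    totals: dict[str, float] = {}
    x, y = pop.cell_centers()
    xf, yf = x.ravel(), y.ravel()
    vals = np.nan_to_num(pop.values.ravel())
    for t in regions.tracts:
        minx, miny, maxx, maxy = t.polygon.bounds
        sel = (xf >= minx) & (xf < maxx) & (yf > miny) & (yf <= maxy)
        totals[t.tract_id] = float(vals[sel].sum())
    return totals


def simulate_tracts_income(config: SyntheticConfig, regions: RegionSet,
                           pop: GridField | None = None) -> RegionSet:
    """Fill tract populations and low-income counts.

    Per county, the low-income population (share drawn near one half —
    "below the median income") is allocated to tracts as a mixture of
    the proportional allocation and the fully packed allocation
    (largest tracts filled first), with mixing weight equal to the
    county's segregation intensity.  The downstream dissimilarity index
    is exactly 0 at segregation 0 and increases monotonically with it.
    """
    if pop is None:
        pop = simulate_population(config)
    rng = config.rng("income")
    totals = _tract_population(config, regions, pop)
    seg = county_segregation(config)
    cindex = {c.county_id: i for i, c in enumerate(regions.counties)}
    share = np.clip(0.5 + 0.1 * rng.standard_normal(len(regions.counties)), 0.2, 0.8)

    new_tracts = []
    for cid in regions.county_ids:
        tr = [t for t in regions.tracts if t.county_id == cid]
        q = np.array([totals[t.tract_id] for t in tr])
        Q = q.sum()
        s_c = seg[cindex[cid]]
        L = share[cindex[cid]] * Q
        prop = L * q / Q if Q > 0 else np.zeros_like(q)
        packed = np.zeros_like(q)
        remaining = L
        for i in np.argsort(-q):
            take = min(q[i], remaining)
            packed[i] = take
            remaining -= take
            if remaining <= 0:
                break
        low = (1.0 - s_c) * prop + s_c * packed
        for t, qi, li in zip(tr, q, low):
            new_tracts.append(TractRecord(
                county_id=t.county_id, tract_id=t.tract_id, polygon=t.polygon,
                area_km2=t.area_km2, population=float(qi),
                low_income_count=float(min(li, qi)),
            ))
    return RegionSet(counties=list(regions.counties), tracts=new_tracts)


# ---------------------------------------------------------------------------
# POIs and roads


def simulate_poi_roads(config: SyntheticConfig, regions: RegionSet,
                       pop: GridField | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """POI points and per-county road-segment counts.

    POIs are a mixture of a uniform component and a Gaussian cluster at
    the county center with weight given by the county's centrality;
    road counts are proportional to county population with log-normal
    noise.
    """
    if pop is None:
        pop = simulate_population(config)
    rng = config.rng("poi")
    rng_roads = config.rng("roads")
    f1, _ = _latent_factors(config)
    cidx = _county_index(config)
    pops = np.zeros(config.n_counties)
    np.add.at(pops, cidx.ravel(), np.nan_to_num(pop.values.ravel()))

    c0 = config.centrality_level
    spread = 0.15 * min(c0, 1.0 - c0) / 0.5
    cent = np.clip(c0 + spread * f1, 0.0, 1.0)
    # county-level rate noise keeps POI density from being a pure copy of
    # population density, so the two stay distinguishable downstream
    rate = config.poi_per_capita * np.exp(
        config.poi_rate_log_sd * rng.standard_normal(config.n_counties))

    rows = []
    for i, county in enumerate(regions.counties):
        minx, miny, maxx, maxy = county.polygon.bounds
        n_poi = rng.poisson(rate[i] * pops[i])
        if n_poi == 0:
            continue
        clustered = rng.random(n_poi) < cent[i]
        cxm, cym = (minx + maxx) / 2.0, (miny + maxy) / 2.0
        x = np.where(clustered,
                     np.clip(cxm + config.poi_cluster_sd_km * rng.standard_normal(n_poi),
                             minx, np.nextafter(maxx, minx)),
                     rng.uniform(minx, maxx, n_poi))
        y = np.where(clustered,
                     np.clip(cym + config.poi_cluster_sd_km * rng.standard_normal(n_poi),
                             miny, np.nextafter(maxy, miny)),
                     rng.uniform(miny, maxy, n_poi))
        cat = rng.choice(_POI_CATEGORIES, n_poi)
        for xi, yi, ki in zip(x, y, cat):
            rows.append((county.county_id, float(xi), float(yi), str(ki)))
    poi = pd.DataFrame(rows, columns=["county_id", "x", "y", "category"])

    segs = np.rint(config.roads_per_capita * pops
                   * np.exp(0.3 * rng_roads.standard_normal(config.n_counties)))
    roads = pd.DataFrame({
        "county_id": [c.county_id for c in regions.counties],
        "n_segments": np.maximum(segs, 1).astype(int),
    })
    return poi, roads


# ---------------------------------------------------------------------------
# covariates and planted effects


def simulate_covariates(config: SyntheticConfig, regions: RegionSet) -> pd.DataFrame:
    """Per-county socio-economic and environmental covariate table.

    GDP and land-conversion pressure load on the latent F2 factor (and
    GDP partly on F1); temperature loads on F1 and NDVI negatively on F1
    (urbanised counties are warmer and less vegetated); precipitation,
    surface pressure and ventilation are independent noise.  The CPI is
    the fuzzy sum (probabilistic OR) of the projected human-modification
    and development-suitability surfaces, both synthetic.
    """
    from .urbanform import fuzzy_sum_cpi

    rng = config.rng("covars")
    f1, f2 = _latent_factors(config)
    n = config.n_counties
    eps = rng.standard_normal((8, n))

    def sigmoid(v: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-v))

    gdp = np.exp(10.0 + 0.5 * f1 + 0.6 * f2 + 0.3 * eps[0])
    hm2030 = sigmoid(-0.5 + 0.8 * f2 + 0.4 * eps[1])
    dsi = sigmoid(-0.5 + 0.6 * f2 + 0.3 * f1 + 0.4 * eps[2])
    cpi = fuzzy_sum_cpi(hm2030, dsi)
    mat = 19.0 + 1.2 * f1 + 1.0 * eps[3]
    map_ = 1500.0 * np.exp(0.15 * eps[4])
    ndvi = np.clip(0.65 - 0.05 * f1 + 0.04 * eps[5], 0.05, 0.95)
    sap = 1000.0 + 5.0 * eps[6]
    vc = 3.3 * np.exp(0.1 * eps[7])
    return pd.DataFrame({
        "county_id": [c.county_id for c in regions.counties],
        "GDP": gdp, "CPI": cpi, "hm2030": hm2030, "dsi": dsi,
        "MAT": mat, "MAP": map_, "NDVI": ndvi, "SAP": sap, "VC": vc,
    })


_LOG_SCALE = {"GDP", "poi_density", "pop_density", "MAP", "SAP", "VC"}


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    x = np.log(v) if name in _LOG_SCALE else np.asarray(v, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def covariate_tilt_multipliers(county_table: pd.DataFrame,
                               effect_sizes: dict[str, float],
                               noise_sd: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Per-county multiplicative exposure factors exp(sum_k beta_k z_k + eps)."""
    log_mult = noise_sd * rng.standard_normal(len(county_table))
    for name, beta in effect_sizes.items():
        if name not in county_table.columns:
            raise ValueError(f"effect on {name!r} requested but column missing")
        log_mult = log_mult + beta * _zscore(county_table[name].to_numpy(), name)
    return np.exp(log_mult)


def _roughness_factor(config: SyntheticConfig, cidx: np.ndarray,
                      amplitude: np.ndarray) -> np.ndarray:
    """Mean-preserving within-county roughness multiplier.

    A short-range unit-variance field W (range ``roughness_range_km``)
    enters the log concentration with per-county amplitude
    a_c * roughness_sd; the log-normal Jensen term is subtracted so the
    county arithmetic mean is (to first order) unchanged.  Counties
    with larger amplitude thus get more within-county inequality at the
    same mean exposure.
    """
    w = _gaussian_field(config.grid_shape, config.cell_size_km,
                        config.roughness_range_km, config.rng("rough"))
    sd = config.roughness_sd * amplitude
    return np.exp(sd[cidx] * w - 0.5 * (sd ** 2)[cidx])


def _smooth_tilt_field(config: SyntheticConfig, cidx: np.ndarray,
                       tilt: np.ndarray) -> np.ndarray:
    """Spatially smoothed per-pixel tilt multiplier.

    The planted county effects are blurred over a few km so the
    concentration surface stays continuous across county borders, as a
    real pollution field is — otherwise border discontinuities would
    leak into the adjacency-based inequality statistics.
    """
    from scipy.ndimage import gaussian_filter

    log_t = np.log(tilt)[cidx]
    sigma = config.tilt_smoothing_km / config.cell_size_km
    if sigma > 0:
        log_t = gaussian_filter(log_t, sigma=sigma, mode="nearest")
    return np.exp(log_t)


# ---------------------------------------------------------------------------
# full province


def generate_province(config: SyntheticConfig) -> Province:
    """Generate every input the downstream pipeline needs, deterministically."""
    regions = make_regions(config)
    pop = simulate_population(config)
    regions = simulate_tracts_income(config, regions, pop)
    poi, roads = simulate_poi_roads(config, regions, pop)
    covars = simulate_covariates(config, regions)

    cidx = _county_index(config)
    area = np.array([c.area_km2 for c in regions.counties])
    pops = np.zeros(config.n_counties)
    np.add.at(pops, cidx.ravel(), np.nan_to_num(pop.values.ravel()))
    poi_counts = poi.groupby("county_id").size().reindex(
        regions.county_ids, fill_value=0).to_numpy()
    table = covars.copy()
    table["pop_density"] = np.maximum(pops, 1e-9) / area
    table["poi_density"] = np.maximum(poi_counts, 1) / area
    table["road_density"] = roads["n_segments"].to_numpy() / area
    table["income_segregation"] = county_segregation(config)

    tilt = covariate_tilt_multipliers(table, config.effect_sizes,
                                      config.noise_sd, config.rng("tilt"))
    amp = config.heterogeneity_base + config.heterogeneity_gain * table[
        "income_segregation"].to_numpy()
    tilt_px = _smooth_tilt_field(config, cidx, tilt)
    rough_px = _roughness_factor(config, cidx, amp)

    concentration = {}
    for p in POLLUTANTS:
        fld = simulate_concentration(config, p)
        concentration[p] = fld.like(fld.values * rough_px * tilt_px)
    return Province(config=config, regions=regions, concentration=concentration,
                    population=pop, poi=poi, roads=roads, covariates=covars)


# ---------------------------------------------------------------------------
# serialisation


def config_to_text(config: SyntheticConfig) -> str:
    lines = []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if f.name == "effect_sizes":
            v = ",".join(f"{k}:{x}" for k, x in v.items())
        lines.append(f"{f.name} = {v}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> SyntheticConfig:
    kwargs: dict = {}
    fields = {f.name: f for f in dataclasses.fields(SyntheticConfig)}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        if key == "effect_sizes":
            eff = {}
            if raw:
                for part in raw.split(","):
                    k, _, x = part.partition(":")
                    eff[k.strip()] = float(x)
            kwargs[key] = eff
        elif fields[key].type in ("int", int):
            kwargs[key] = int(raw)
        else:
            kwargs[key] = float(raw)
    return SyntheticConfig(**kwargs)


def write_province(province: Province, outdir: str | Path) -> Path:
    """Write rasters (GeoTIFF), polygons (GeoJSON) and tables (CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = {"PM1": "pm1", "PM2.5": "pm25", "PM10": "pm10"}
    for p, fld in province.concentration.items():
        write_grid(fld, outdir / f"{name[p]}.tif")
    write_grid(province.population, outdir / "population.tif")
    write_regions(province.regions, outdir / "counties.geojson",
                  outdir / "tracts.geojson")
    province.poi.to_csv(outdir / "poi.csv", index=False)
    province.roads.to_csv(outdir / "roads.csv", index=False)
    province.covariates.to_csv(outdir / "covariates.csv", index=False)
    (outdir / "config.txt").write_text(config_to_text(province.config))
    return outdir
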