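"""Shared fixtures: small synthetic provinces and indicator tables."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from airineq.drivers import assemble_indicators
from airineq.exposure import decay_adjust, exposure_table
from airineq.inequality import segregation_table, sgi_table
from airineq.synth import SyntheticConfig, generate_province
from airineq.urbanform import densities, uci_table


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A 5x5-county province that generates in well under a second."""
    kwargs = dict(n_counties_x=5, n_counties_y=5, county_size_km=6.0,
                  cell_size_km=1.0, tracts_per_county=4, seed=seed,
                  spatial_range_km=10.0, latent_range_km=8.0)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def build_indicator_table(config: SyntheticConfig):
    """Run the pipeline stages up to the assembled per-county table."""
    prov = generate_province(config)
    expo = exposure_table(prov.concentration, prov.population, prov.regions)
    decayed = {p: decay_adjust(f, 1.0) for p, f in prov.concentration.items()}
    sgi = sgi_table(decayed, prov.regions)
    seg = segregation_table(prov.regions)
    dens = densities(prov.regions, prov.poi, prov.roads, prov.population)
    urban = dens.join(uci_table(prov.poi, prov.regions)[["UCI"]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assemble_indicators(expo, sgi, seg, urban, prov.covariates)


@pytest.fixture(scope="session")
def small_province():
    return generate_province(small_config(seed=3))


@pytest.fixture(scope="session")
def small_table():
    return build_indicator_table(small_config(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
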