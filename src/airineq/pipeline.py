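"""End-to-end orchestration: simulate → exposure → inequality → urban form
→ drivers → network, with a run manifest for reproducibility.

Every stage writes CSV artifacts into the output directory; the
manifest records the configuration, seed, package version and per-stage
row counts.  Reruns with the same configuration and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import __version__
from .drivers import (assemble_indicators, component_regressions, ols_table,
                      run_pca)
from .exposure import combine_pollutants, decay_adjust, exposure_table
from .geoio import GridField, RegionSet, read_grid, read_regions
from .inequality import segregation_table, sgi_table
from .pcnet import bootstrap_network, fit_network, network_metrics
from .synth import (POLLUTANTS, SyntheticConfig, generate_province,
                    write_province)
from .urbanform import densities, uci_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_all", "load_province_dir"]

_RASTER_NAME = {"PM1": "pm1.tif", "PM2.5": "pm25.tif", "PM10": "pm10.tif"}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage}: {message}")


@dataclass
class RunConfig:
    """Defaults follow the study conventions: 1-km decay buffer, rook
    adjacency, natural logs on the large-scale columns, EBIC gamma 0.5."""

    synthetic: SyntheticConfig = dc_field(default_factory=SyntheticConfig)
    input_dir: str | None = None     # read inputs instead of simulating
    simulate: bool = True
    buffer_km: float = 1.0
    kernel: str = "uniform"
    adjacency_rule: str = "rook"
    sgi_population_weighted: bool = False
    pca_components: int | None = None
    gamma: float = 0.5
    n_lambda: int = 100
    bootstrap_B: int = 0             # 0 disables the bootstrap stage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed != self.synthetic.seed:
            self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)


def load_province_dir(path: str | Path
                      ) -> tuple[dict[str, GridField], GridField, RegionSet,
                                 pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read a written province directory back into pipeline inputs."""
    path = Path(path)
    conc = {}
    for p, fname in _RASTER_NAME.items():
        f = path / fname
        if not f.exists():
            raise FileNotFoundError(f)
        conc[p] = read_grid(f, label=p)
    pop = read_grid(path / "population.tif", label="population")
    regions = read_regions(path / "counties.geojson", path / "tracts.geojson")
    poi = pd.read_csv(path / "poi.csv")
    roads = pd.read_csv(path / "roads.csv")
    covars = pd.read_csv(path / "covariates.csv")
    return conc, pop, regions, poi, roads, covars


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full analysis; returns the artifact directory.

    Raises :class:`PipelineError` naming the failing stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": []}

    def stage_done(name: str, t0: float, **counts) -> None:
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3),
                                   **counts})
        logger.info("stage %s done (%s)", name, counts)

    # 1. inputs ---------------------------------------------------------
    t0 = time.time()
    try:
        if config.input_dir is not None:
            conc, pop, regions, poi, roads, covars = load_province_dir(
                config.input_dir)
        elif config.simulate:
            prov = generate_province(config.synthetic)
            write_province(prov, out / "province")
            conc, pop, regions = prov.concentration, prov.population, prov.regions
            poi, roads, covars = prov.poi, prov.roads, prov.covariates
        else:
            raise FileNotFoundError("no input_dir given and simulate disabled")
    except Exception as exc:
        raise PipelineError("geodata_io", str(exc)) from exc
    stage_done("simulate" if config.input_dir is None else "load",
               t0, n_counties=len(regions.counties), n_tracts=len(regions.tracts))

    # 2. exposure -------------------------------------------------------
    t0 = time.time()
    try:
        expo = exposure_table(conc, pop, regions, buffer_km=config.buffer_km,
                              kernel=config.kernel)
        expo.to_csv(out / "exposure.csv")
    except Exception as exc:
        raise PipelineError("exposure", str(exc)) from exc
    stage_done("exposure", t0, n_rows=len(expo))

    # 3. inequality -----------------------------------------------------
    t0 = time.time()
    try:
        decayed = {p: decay_adjust(f, config.buffer_km, config.kernel)
                   for p, f in conc.items()}
        sgi = sgi_table(decayed, regions, rule=config.adjacency_rule)
        if config.sgi_population_weighted:
            weighted = sgi_table(decayed, regions, rule=config.adjacency_rule,
                                 pop=pop)
            sgi = sgi.join(weighted.add_suffix("_popweighted"))
        sgi.to_csv(out / "sgi.csv")
        seg = segregation_table(regions)
        seg.to_csv(out / "segregation.csv")
    except Exception as exc:
        raise PipelineError("inequality", str(exc)) from exc
    stage_done("inequality", t0, n_rows=len(sgi))

    # 4. urban form -----------------------------------------------------
    t0 = time.time()
    try:
        dens = densities(regions, poi, roads, pop)
        ucis = uci_table(poi, regions)
        urban = dens.join(ucis[["UCI", "LC", "PI"]])
        urban.to_csv(out / "urbanform.csv")
    except Exception as exc:
        raise PipelineError("urban_form", str(exc)) from exc
    stage_done("urban_form", t0, n_rows=len(urban))

    # 5. drivers --------------------------------------------------------
    t0 = time.time()
    try:
        table = assemble_indicators(expo, sgi[["SGI_PM1", "SGI_PM25",
                                               "SGI_PM10", "SGI_combined"]],
                                    seg, urban[["poi_density", "road_density",
                                                "pop_density", "UCI"]], covars)
        table.to_csv(out / "indicators.csv")
        ols = ols_table(table)
        ols.to_csv(out / "ols.csv", index=False)
        pca = run_pca(table, n_components=config.pca_components)
        pca.loadings.to_csv(out / "pca_loadings.csv")
        pd.DataFrame({"component": [f"PC{i+1}" for i in
                                    range(len(pca.explained_variance_ratio))],
                      "explained_variance_ratio": pca.explained_variance_ratio}
                     ).to_csv(out / "pca_ratios.csv", index=False)
        pcreg = component_regressions(pca, table)
        pcreg.to_csv(out / "pc_regressions.csv", index=False)
    except Exception as exc:
        raise PipelineError("drivers", str(exc)) from exc
    stage_done("drivers", t0, n_rows=len(table))

    # 6. network --------------------------------------------------------
    t0 = time.time()
    try:
        for target, tag in (("APE_combined", "ape"), ("SGI_combined", "sgi")):
            net = fit_network(table, target, gamma=config.gamma,
                              n_lambda=config.n_lambda)
            net.edges.to_csv(out / f"network_{tag}_edges.csv", index=False)
            met = network_metrics(net)
            pd.DataFrame({"strength": met.strength,
                          "expected_influence": met.expected_influence}
                         ).to_csv(out / f"network_{tag}_metrics.csv")
            if config.bootstrap_B > 0:
                boot = bootstrap_network(table, target, B=config.bootstrap_B,
                                         seed=config.seed, gamma=config.gamma,
                                         n_lambda=min(config.n_lambda, 50))
                boot.edge_frequency.to_csv(
                    out / f"network_{tag}_edge_frequency.csv", index=False)
                boot.centrality_stability.to_csv(
                    out / f"network_{tag}_stability.csv", index=False)
    except Exception as exc:
        raise PipelineError("pcnet", str(exc)) from exc
    stage_done("network", t0, n_rows=len(table))

    manifest["config"] = _config_dict(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
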