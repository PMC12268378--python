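"""Driver analysis: indicator assembly, bivariate OLS and PCA.

Per county, twelve indicators — six urban-form / socio-economic
(road_density, poi_density, UCI, pop_density, GDP, income_segregation)
and six environmental (CPI, MAT, MAP, NDVI, SAP, VC) — are related to
the combined-pollution exposure (APE) and its spatial inequality (SGI)
by log-transformed bivariate least squares with 90% confidence
intervals, and summarised by PCA on the standardised indicators
(correlation-matrix decomposition; APE and SGI are regression targets
only, never PCA inputs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["INDICATORS", "LOG_COLUMNS", "OLSFit", "PCAModel",
           "assemble_indicators", "log_transform", "bivariate_ols",
           "ols_table", "run_pca", "component_regressions"]

INDICATORS = ["road_density", "poi_density", "UCI", "pop_density", "GDP",
              "income_segregation", "CPI", "MAT", "MAP", "NDVI", "SAP", "VC"]
#: columns whose scale dwarfs the others; natural-logged before analysis
LOG_COLUMNS = ("GDP", "poi_density", "pop_density", "MAP", "SAP", "VC")
TARGETS = ("APE_combined", "SGI_combined")


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    r2: float
    p_value: float
    ci90: tuple[float, float]
    n: int


@dataclass
class PCAModel:
    loadings: pd.DataFrame          # indicators x components
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame            # counties x components


def assemble_indicators(exposure: pd.DataFrame, sgi: pd.DataFrame,
                        segregation: pd.DataFrame, urban: pd.DataFrame,
                        covariates: pd.DataFrame) -> pd.DataFrame:
    """Inner-join all per-county outputs into the indicator table.

    Counties lost to undefined metrics (NaN anywhere) are dropped and
    logged by id.  ``segregation``'s DI column becomes
    ``income_segregation``.
    """
    covars = covariates.copy()
    if "county_id" in covars.columns:
        covars = covars.set_index("county_id")
    seg = segregation.rename(columns={"DI": "income_segregation"})
    table = (exposure.join(sgi, how="inner").join(seg, how="inner")
             .join(urban, how="inner").join(covars, how="inner"))
    if table.empty:
        raise ValueError("indicator join produced no counties")
    wanted = [c for c in table.columns
              if c in INDICATORS or c.startswith(("APE_", "SGI_"))]
    table = table[wanted]
    bad = table.index[table.isna().any(axis=1)]
    if len(bad):
        logger.warning("dropping %d counties with undefined metrics: %s",
                       len(bad), list(bad))
        table = table.drop(index=bad)
    return table


def log_transform(table: pd.DataFrame,
                  columns: tuple[str, ...] = LOG_COLUMNS) -> pd.DataFrame:
    """Natural log of the named large-scale columns; others untouched.

    Zeros are offset by half the smallest positive value in the column
    (with a warning); negative values are an error.
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        x = out[col].to_numpy(dtype=float)
        if np.any(x < 0):
            raise ValueError(f"column {col} has negative values; cannot log")
        if np.any(x == 0):
            pos = x[x > 0]
            if pos.size == 0:
                raise ValueError(f"column {col} is all zeros; cannot log")
            eps = pos.min() / 2.0
            warnings.warn(f"column {col}: {int((x == 0).sum())} zeros offset "
                          f"by {eps:g} before log", stacklevel=2)
            x = x + eps
        out[col] = np.log(x)
    return out


def bivariate_ols(x: np.ndarray, y: np.ndarray, ci_level: float = 0.90) -> OLSFit:
    """Least-squares fit y = a + b x with R^2, two-sided p and 90% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned x, y with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    lo, hi = res.conf_int(alpha=1.0 - ci_level)[1]
    return OLSFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                  r2=float(res.rsquared), p_value=float(res.pvalues[1]),
                  ci90=(float(lo), float(hi)), n=len(x))


def ols_table(table: pd.DataFrame, log: bool = True) -> pd.DataFrame:
    """All 12 x 2 bivariate fits of each indicator against APE and SGI."""
    data = log_transform(table) if log else table
    rows = []
    for target in TARGETS:
        for ind in INDICATORS:
            if ind not in data.columns or target not in data.columns:
                continue
            fit = bivariate_ols(data[ind].to_numpy(), data[target].to_numpy())
            rows.append((target, ind, fit.slope, fit.intercept, fit.r2,
                         fit.p_value, fit.ci90[0], fit.ci90[1]))
    return pd.DataFrame(rows, columns=["target", "indicator", "slope",
                                       "intercept", "r2", "p_value",
                                       "ci90_low", "ci90_high"])


def run_pca(table: pd.DataFrame, n_components: int | None = None,
            log: bool = True) -> PCAModel:
    """PCA of the standardised indicators (correlation-matrix eigen-analysis).

    APE/SGI columns are excluded.  Sign convention: within each
    component the largest-|loading| entry is made positive, so
    "development density"-type components point in the direction of
    denser counties.
    """
    cols = [c for c in INDICATORS if c in table.columns]
    if len(table) < 2:
        raise ValueError("PCA needs at least 2 counties")
    data = log_transform(table[cols]) if log else table[cols]
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant indicator column; PCA undefined")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.abs(evecs[:, j]).argmax(), j] < 0:
            evecs[:, j] = -evecs[:, j]
    k = n_components or len(cols)
    ratio = evals / evals.sum()
    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAModel(
        loadings=pd.DataFrame(evecs[:, :k], index=cols, columns=comp),
        explained_variance_ratio=ratio[:k],
        scores=pd.DataFrame(z @ evecs[:, :k], index=table.index, columns=comp),
    )


def component_regressions(pca: PCAModel, table: pd.DataFrame) -> pd.DataFrame:
    """Bivariate fits of (PC1, PC2) against (APE_combined, SGI_combined)."""
    rows = []
    for comp in ("PC1", "PC2"):
        for target in TARGETS:
            if target not in table.columns:
                continue
            fit = bivariate_ols(pca.scores[comp].to_numpy(),
                                table[target].to_numpy())
            rows.append((comp, target, fit.slope, fit.r2, fit.p_value,
                         fit.ci90[0], fit.ci90[1]))
    return pd.DataFrame(rows, columns=["component", "target", "slope", "r2",
                                       "p_value", "ci90_low", "ci90_high"])
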