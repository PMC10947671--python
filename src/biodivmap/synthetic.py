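"""Synthetic landscapes, communities, biased citizen-science records and tracts.

The generator produces the study conditions the rest of the pipeline is tested
under, with full ground truth:

* a regular grid of square cells carrying spatially autocorrelated covariate
  surfaces (climate, vegetation, land cover, road density, soil), generated as
  Gaussian random fields with exponential covariance;
* a true diversity surface: log richness is a linear combination of a known
  subset of covariates plus a spatially autocorrelated field plus independent
  noise; the generating coefficients are recorded in the output so recovery
  tests can check them;
* per-cell communities with lognormal species-abundance structure (rare
  species tails make coverage estimation nontrivial);
* occurrence records from observers whose per-cell counts scale with a
  population-density surface, each observer contributing on average ~20
  records drawn from the cell's abundance distribution, with a configurable
  fraction of records corrupted (missing coordinates/taxonomy, cultivated) to
  exercise cleaning — corrupted records carry hidden ledger columns so tests
  can count them exactly;
* rectangular census tracts with SES attributes on 0–100 scales, a county
  label, population density, and a disadvantaged-community (DAC) flag for the
  worst quartile of a composite score. One chosen SES variable is an exact
  affine function of tract-mean true diversity, so the diversity-on-SES slope
  equals ``ses_effect`` by construction.

Fixed seed implies bit-reproducible outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from biodivmap.errors import ConfigurationError
from biodivmap.ingest import GridSpec

logger = logging.getLogger(__name__)

#: covariate surface names by thematic class (stand-ins for the usual
#: climate / vegetation / land-cover / road / soil predictor stack)
COVARIATE_NAMES: tuple[str, ...] = (
    "temperature",
    "precipitation",
    "elevation",
    "evapotranspiration",
    "ndvi",
    "tree_canopy_pct",
    "developed_open_pct",
    "herbaceous_pct",
    "road_density",
    "soil_ph",
    "soil_organic_matter",
    "soil_cec",
)

#: default generating coefficients of log true richness (others are zero)
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "temperature": 0.12,
    "precipitation": 0.18,
    "ndvi": 0.25,
    "tree_canopy_pct": 0.12,
    "soil_ph": -0.10,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    grid_dims: tuple[int, int] = (20, 20)  # (rows, cols)
    cell_size: float = 5000.0  # metres
    origin: tuple[float, float] = (0.0, 0.0)
    n_species_pool: int = 3000
    spatial_range: float = 20000.0  # exponential-covariance range of fields, metres
    field_sd: float = 0.25  # sd of the spatial term in log richness
    noise_sd: float = 0.05  # independent noise in log richness
    richness_base: float = 150.0  # median true cell richness
    sad_sigma: float = 1.5  # lognormal SAD shape (log-scale sd)
    effort_mean_records: float = 20.0  # mean records per observer
    records_dist: str = "poisson"  # or "nbinom"
    nbinom_k: float = 2.0  # nbinom shape when records_dist == "nbinom"
    observer_rate: float = 25.0  # mean observers per cell at unit pop density
    pop_density_sd: float = 0.9  # log-scale sd of the population-density surface
    corruption_frac: float = 0.05
    ses_effect: float = -2.0  # diversity units per % SES (slope of D0 on SES)
    n_counties: int = 10
    coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))

    def __post_init__(self) -> None:
        rows, cols = self.grid_dims
        if rows < 2 or cols < 2:
            raise ConfigurationError(f"grid_dims must each be >= 2, got {self.grid_dims}")
        if self.spatial_range <= 0:
            raise ConfigurationError("spatial_range must be > 0")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be > 0")
        if self.effort_mean_records <= 0:
            raise ConfigurationError("effort_mean_records must be > 0")
        if not (0.0 <= self.corruption_frac < 1.0):
            raise ConfigurationError("corruption_frac must be in [0, 1)")

    @property
    def grid(self) -> GridSpec:
        rows, cols = self.grid_dims
        return GridSpec(origin=self.origin, cell_size=self.cell_size, rows=rows, cols=cols)


@dataclass
class LandscapeTruth:
    """Ground truth for one synthetic landscape."""

    grid: GridSpec
    covariates: pd.DataFrame  # cell_id + one column per covariate surface
    true_diversity: pd.DataFrame  # cell_id, D0, D1, D2
    pop_density: np.ndarray  # per cell, mean ~ 1
    sad_sigma: float
    coefficients: dict[str, float]  # generating coefficients (recovery ledger)
    spatial_field: np.ndarray  # the autocorrelated component of log richness
    communities: list[tuple[np.ndarray, np.ndarray]]  # (species ids, rel. abundances)


def _exp_cov_cholesky(coords: np.ndarray, range_m: float) -> np.ndarray:
    """Cholesky factor of an exponential covariance over points (jittered)."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    cov = np.exp(-d / range_m)
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov)


def generate_truth(config: SyntheticConfig) -> LandscapeTruth:
    """Generate covariate surfaces, the true diversity surface and communities."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    cents = grid.centroids()
    coords = cents[["x", "y"]].to_numpy()
    n = grid.n_cells

    chol = _exp_cov_cholesky(coords, config.spatial_range)
    surfaces = {name: chol @ rng.standard_normal(n) for name in COVARIATE_NAMES}
    covariates = pd.DataFrame({"cell_id": cents["cell_id"], **surfaces})

    spatial_field = config.field_sd * (chol @ rng.standard_normal(n))
    eta = np.log(config.richness_base) + spatial_field + config.noise_sd * rng.standard_normal(n)
    for name, beta in config.coefficients.items():
        if name not in surfaces:
            raise ConfigurationError(f"unknown covariate in coefficients: {name!r}")
        eta = eta + beta * surfaces[name]

    s_cell = np.maximum(1, np.rint(np.exp(eta)).astype(int))
    if config.n_species_pool < s_cell.max():
        raise ConfigurationError(
            f"species pool ({config.n_species_pool}) smaller than richest cell ({s_cell.max()})"
        )

    # lognormal pool weights give consistent commonness/rarity across cells
    pool_w = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_species_pool)
    pool_w /= pool_w.sum()
    communities: list[tuple[np.ndarray, np.ndarray]] = []
    d0 = np.zeros(n)
    d1 = np.zeros(n)
    d2 = np.zeros(n)
    for i in range(n):
        sp = rng.choice(config.n_species_pool, size=s_cell[i], replace=False, p=pool_w)
        ab = rng.lognormal(mean=0.0, sigma=config.sad_sigma, size=s_cell[i])
        p = ab / ab.sum()
        communities.append((np.sort(sp), p[np.argsort(sp)]))
        d0[i] = s_cell[i]
        d1[i] = np.exp(-(p * np.log(p)).sum())
        d2[i] = 1.0 / (p * p).sum()

    pop = np.exp(config.pop_density_sd * (chol @ rng.standard_normal(n)))
    pop /= pop.mean()

    truth = LandscapeTruth(
        grid=grid,
        covariates=covariates,
        true_diversity=pd.DataFrame({"cell_id": cents["cell_id"], "D0": d0, "D1": d1, "D2": d2}),
        pop_density=pop,
        sad_sigma=config.sad_sigma,
        coefficients=dict(config.coefficients),
        spatial_field=spatial_field,
        communities=communities,
    )
    logger.info(
        "generated %dx%d landscape: richness %.0f-%.0f, pop density cv %.2f",
        grid.rows,
        grid.cols,
        d0.min(),
        d0.max(),
        pop.std(),
    )
    return truth


_DEFECTS = ("missing_coordinates", "missing_species", "incomplete_taxonomy", "cultivated")


def generate_occurrences(
    truth: LandscapeTruth,
    config: SyntheticConfig,
    observer_rate: float | None = None,
) -> pd.DataFrame:
    """Darwin-Core-style occurrence table with hidden ground-truth columns.

    Per cell, the observer count is Poisson with mean
    ``observer_rate * pop_density``; each observer contributes a Poisson (or
    negative-binomial) number of records drawn from the cell's lognormal
    abundance distribution, all on a single observation date (the sampling
    unit downstream is the observer-day). Hidden columns (prefix ``_``) record
    the true cell, corruption flag and defect type; writers drop them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    grid = truth.grid
    rate = config.observer_rate if observer_rate is None else observer_rate
    n_obs_cell = rng.poisson(rate * truth.pop_density)

    parts: list[pd.DataFrame] = []
    x0, y0 = grid.origin
    s = grid.cell_size
    day0 = np.datetime64("2019-01-01")
    for cid in range(grid.n_cells):
        n_obs = int(n_obs_cell[cid])
        if n_obs == 0:
            continue
        if config.records_dist == "nbinom":
            k = config.nbinom_k
            n_rec = rng.negative_binomial(k, k / (k + config.effort_mean_records), size=n_obs)
        else:
            n_rec = rng.poisson(config.effort_mean_records, size=n_obs)
        total = int(n_rec.sum())
        if total == 0:
            continue
        sp_ids, p = truth.communities[cid]
        draws = sp_ids[rng.choice(sp_ids.size, size=total, p=p)]
        obs_idx = np.repeat(np.arange(n_obs), n_rec)
        dates = day0 + rng.integers(0, 1461, size=n_obs)  # one date per observer
        iy, ix = divmod(cid, grid.cols)
        xs = x0 + (ix + rng.random(total)) * s
        ys = y0 + (iy + rng.random(total)) * s
        parts.append(
            pd.DataFrame(
                {
                    "scientificName": np.char.add("sp", draws.astype(str)),
                    "decimalLongitude": xs,
                    "decimalLatitude": ys,
                    "recordedBy": np.char.add(f"obs_c{cid}_", obs_idx.astype(str)),
                    "eventDate": dates[obs_idx].astype("datetime64[D]").astype(str),
                    "establishmentMeans": "wild",
                    "taxonRank": "species",
                    "_true_cell": cid,
                }
            )
        )
    if not parts:
        table = pd.DataFrame(
            columns=[
                "scientificName",
                "decimalLongitude",
                "decimalLatitude",
                "recordedBy",
                "eventDate",
                "establishmentMeans",
                "taxonRank",
                "_true_cell",
            ]
        )
        table["_corrupted"] = pd.Series(dtype=bool)
        table["_defect"] = pd.Series(dtype=str)
        return table

    table = pd.concat(parts, ignore_index=True)
    m = len(table)
    corrupted = rng.random(m) < config.corruption_frac
    defect = np.where(corrupted, rng.choice(_DEFECTS, size=m), "")
    table["_corrupted"] = corrupted
    table["_defect"] = defect
    table.loc[defect == "missing_coordinates", ["decimalLongitude", "decimalLatitude"]] = np.nan
    table.loc[defect == "missing_species", "scientificName"] = np.nan
    table.loc[defect == "incomplete_taxonomy", "taxonRank"] = "genus"
    table.loc[defect == "cultivated", "establishmentMeans"] = "cultivated"
    logger.info("generated %d records (%d corrupted)", m, int(corrupted.sum()))
    return table


def _near_square_factors(n: int) -> tuple[int, int]:
    r = int(math.isqrt(n))
    while n % r:
        r -= 1
    return r, n // r


def _interval_overlap(lo1, hi1, lo2, hi2):
    return np.maximum(0.0, np.minimum(hi1, hi2) - np.maximum(lo1, lo2))


def tract_cell_weights(grid: GridSpec, tract_bounds: np.ndarray) -> list[np.ndarray]:
    """Intersection areas (per tract) with every grid cell, analytic rectangles."""
    x0, y0 = grid.origin
    s = grid.cell_size
    ix = np.arange(grid.cols)
    iy = np.arange(grid.rows)
    cx_lo, cx_hi = x0 + ix * s, x0 + (ix + 1) * s
    cy_lo, cy_hi = y0 + iy * s, y0 + (iy + 1) * s
    out = []
    for (tx0, ty0, tx1, ty1) in tract_bounds:
        wx = _interval_overlap(cx_lo, cx_hi, tx0, tx1)  # per column
        wy = _interval_overlap(cy_lo, cy_hi, ty0, ty1)  # per row
        out.append(np.outer(wy, wx).ravel())  # cell_id = iy*cols + ix
    return out


def generate_tracts(
    truth: LandscapeTruth, n_tracts: int, config: SyntheticConfig
) -> pd.DataFrame:
    """Rectangular tracts tiling the grid extent, with SES attributes.

    The poverty variable is an exact affine function of tract-mean true
    richness with slope ``1/ses_effect`` (so richness regressed on poverty has
    slope ``ses_effect``); with ``ses_effect = 0`` it is an independent field.
    The DAC flag marks the worst quartile (``ceil(0.25 n)`` tracts) of a
    composite deprivation score. Columns include county labels (contiguous
    bands), population density, NDVI and tract centroid coordinates.
    """
    if n_tracts < 2:
        raise ConfigurationError("n_tracts must be >= 2")
    if n_tracts > truth.grid.n_cells:
        raise ConfigurationError(
            f"n_tracts ({n_tracts}) exceeds number of cells ({truth.grid.n_cells})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    grid = truth.grid
    tr, tc = _near_square_factors(n_tracts)
    x0, y0 = grid.origin
    w = grid.cols * grid.cell_size / tc
    h = grid.rows * grid.cell_size / tr
    rows = []
    for j in range(tr):
        for i in range(tc):
            rows.append((x0 + i * w, y0 + j * h, x0 + (i + 1) * w, y0 + (j + 1) * h))
    bounds = np.array(rows)
    weights = tract_cell_weights(grid, bounds)

    d0 = truth.true_diversity["D0"].to_numpy()
    d1 = truth.true_diversity["D1"].to_numpy()
    d2 = truth.true_diversity["D2"].to_numpy()
    ndvi = truth.covariates["ndvi"].to_numpy()
    mean_d0 = np.array([np.average(d0, weights=wt) for wt in weights])
    mean_d1 = np.array([np.average(d1, weights=wt) for wt in weights])
    mean_d2 = np.array([np.average(d2, weights=wt) for wt in weights])
    mean_ndvi = np.array([np.average(ndvi, weights=wt) for wt in weights])
    mean_pop = np.array([np.average(truth.pop_density, weights=wt) for wt in weights])

    if config.ses_effect != 0.0:
        poverty = 50.0 + (mean_d0 - mean_d0.mean()) / config.ses_effect
        clipped = np.count_nonzero((poverty < 0) | (poverty > 100))
        if clipped:
            logger.warning(
                "generate_tracts: %d/%d tracts clipped at the 0-100 SES bounds; "
                "the built-in slope is distorted there",
                clipped,
                n_tracts,
            )
        poverty = np.clip(poverty, 0.0, 100.0)
    else:
        poverty = np.clip(50.0 + 15.0 * rng.standard_normal(n_tracts), 0.0, 100.0)

    def _correlated(base: np.ndarray, rho: float, sd: float) -> np.ndarray:
        return np.clip(50 + rho * (base - 50) + sd * rng.standard_normal(base.size), 0, 100)

    education = _correlated(poverty, 0.7, 8.0)  # % without secondary education
    linguistic = _correlated(poverty, 0.6, 10.0)
    unemployment = _correlated(poverty, 0.6, 10.0)
    housing_burden = _correlated(poverty, 0.5, 12.0)
    pop_char_raw = np.clip(
        (poverty + education + unemployment) / 30.0 + 0.5 * rng.standard_normal(n_tracts),
        0.0,
        10.0,
    )  # native 0-10 scale
    pop_char = pop_char_raw * 10.0  # rescaled to 0-100 for comparability

    composite = (poverty + education + linguistic + unemployment + housing_burden) / 5.0
    n_dac = math.ceil(0.25 * n_tracts)
    order = np.argsort(-composite, kind="stable")
    dac = np.zeros(n_tracts, dtype=bool)
    dac[order[:n_dac]] = True

    county = np.minimum(
        (np.arange(n_tracts) * config.n_counties) // n_tracts, config.n_counties - 1
    )

    return pd.DataFrame(
        {
            "tract_id": np.arange(n_tracts),
            "xmin": bounds[:, 0],
            "ymin": bounds[:, 1],
            "xmax": bounds[:, 2],
            "ymax": bounds[:, 3],
            "x": (bounds[:, 0] + bounds[:, 2]) / 2,
            "y": (bounds[:, 1] + bounds[:, 3]) / 2,
            "county": np.char.add("county_", county.astype(str)),
            "mean_D0_true": mean_d0,
            "mean_D1_true": mean_d1,
            "mean_D2_true": mean_d2,
            "poverty_pct": poverty,
            "education_pct": education,
            "linguistic_isolation_pct": linguistic,
            "unemployment_pct": unemployment,
            "housing_burden_pct": housing_burden,
            "pop_char_score": pop_char,
            "ndvi": mean_ndvi,
            "pop_density": mean_pop,
            "dac": dac,
        }
    )


def simulate_tract_outcomes(
    n_tracts: int = 300,
    n_counties: int = 10,
    beta_ses: float = -0.61,
    beta_pop: float = 0.0,
    intercept: float = 150.0,
    county_sd: float = 5.0,
    resid_sd: float = 10.0,
    spatial_range: float = 20000.0,
    spatial_frac: float = 0.5,
    extent: float = 200000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct tract-level simulation for the spatial mixed model.

    outcome = intercept + beta_ses * ses + beta_pop * pop_density
              + county intercept + residual,
    where the residual is Gaussian with variance ``resid_sd**2`` split between
    an exponential-covariance spatial component (fraction ``spatial_frac``)
    and white noise. Used for parameter-recovery and CI-coverage checks.
    """
    rng = np.random.default_rng(seed)
    coords = rng.random((n_tracts, 2)) * extent
    ses = np.clip(50 + 15 * rng.standard_normal(n_tracts), 0, 100)
    pop = np.exp(0.8 * rng.standard_normal(n_tracts))
    county = rng.integers(0, n_counties, size=n_tracts)
    county_eff = county_sd * rng.standard_normal(n_counties)
    chol = _exp_cov_cholesky(coords, spatial_range)
    spat = math.sqrt(spatial_frac) * resid_sd * (chol @ rng.standard_normal(n_tracts))
    eps = math.sqrt(1 - spatial_frac) * resid_sd * rng.standard_normal(n_tracts)
    y = intercept + beta_ses * ses + beta_pop * pop + county_eff[county] + spat + eps
    return pd.DataFrame(
        {
            "tract_id": np.arange(n_tracts),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "ses": ses,
            "pop_density": pop,
            "county": np.char.add("county_", county.astype(str)),
            "outcome": y,
        }
    )
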