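"""Configuration-driven orchestration of the full analysis.

The pipeline is a sequence of stages, each reading the previous stage's
artifacts from the run directory and writing its own:

    simulate -> ingest -> diversity -> validate -> extrapolate -> disparity

``run(config)`` executes all stages and finishes with a machine-readable
manifest (package version, seed, config hash) and a plain-text report of the
headline tables. Outputs carry no timestamps, so a rerun with the same
configuration and seed reproduces the run directory byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import biodivmap
from biodivmap import io as bio_io
from biodivmap.coverage import estimate_cells
from biodivmap.disparity import compare_groups, correlate, fit_spatial_lmm, summarize_to_tracts
from biodivmap.errors import ConfigurationError, InsufficientDataError
from biodivmap.ingest import (
    apply_effort_filter,
    assign_grid,
    build_incidence_by_cell,
    cell_summary,
    clean_records,
    incidence_from_long,
    incidence_long,
)
from biodivmap.synthetic import (
    COVARIATE_NAMES,
    SyntheticConfig,
    generate_occurrences,
    generate_tracts,
    generate_truth,
)
from biodivmap.validation import (
    METHODS,
    compose_final_map,
    cross_validate,
    fit_and_predict,
    select_model,
)

logger = logging.getLogger(__name__)

SES_VARIABLES = (
    "poverty_pct",
    "education_pct",
    "linguistic_isolation_pct",
    "unemployment_pct",
    "housing_burden_pct",
    "pop_char_score",
)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the study's stated values."""

    output_dir: str = "run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    n_tracts: int = 100
    unit_rule: str = "observer-day"
    min_observers: int = 40
    C_threshold: float = 0.80
    C_target: float = 0.80
    collinearity_r: float = 0.8
    screening_r: float = 0.1
    fill_radius_m: float = 8000.0
    cv_k: int = 10
    methods: tuple[str, ...] = METHODS
    metrics: tuple[str, ...] = ("D0", "D1", "D2")
    use_covariates: bool = True

    def __post_init__(self) -> None:
        for name in ("C_threshold", "C_target", "collinearity_r", "screening_r"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        if self.min_observers < 1:
            raise ConfigurationError("min_observers must be >= 1")
        if self.cv_k < 2:
            raise ConfigurationError("cv_k must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        syn = doc.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            if "grid_dims" in syn:
                syn["grid_dims"] = tuple(syn["grid_dims"])
            if "origin" in syn:
                syn["origin"] = tuple(syn["origin"])
            if "coefficients" in syn:
                syn["coefficients"] = dict(syn["coefficients"])
            syn = SyntheticConfig(**syn)
        if "methods" in doc:
            doc["methods"] = tuple(doc["methods"])
        if "metrics" in doc:
            doc["metrics"] = tuple(doc["metrics"])
        return cls(synthetic=syn, **doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _manifest_config(config: PipelineConfig) -> dict:
    # the run directory location must not affect the recorded configuration,
    # otherwise byte-identical reruns into different directories would differ
    d = config.to_dict()
    d.pop("output_dir", None)
    return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_manifest_config(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, out: Path) -> None:
    """Generate landscape, records and tracts; write the raw-input artifacts."""
    if config.synthetic is None:
        raise ConfigurationError(
            "only synthetic mode is supported offline: provide a synthetic block"
        )
    syn = config.synthetic
    truth = generate_truth(syn)
    occ = generate_occurrences(truth, syn)
    tracts = generate_tracts(truth, config.n_tracts, syn)
    bio_io.write_occurrences(occ, out / "occurrences.csv")
    bio_io.write_grid(truth.grid, out / "grid.json")
    cov = truth.covariates.merge(truth.grid.centroids(), on="cell_id")
    cov["pop_density"] = truth.pop_density
    bio_io.write_covariates(cov, out / "covariates.csv")
    truth.true_diversity.to_csv(out / "true_diversity.csv", index=False)
    bio_io.write_tracts_geojson(tracts, out / "tracts.geojson")


def stage_ingest(config: PipelineConfig, out: Path) -> None:
    """Clean records, assign the grid, build per-cell incidence tables."""
    occ = bio_io.read_occurrences(out / "occurrences.csv")
    grid = bio_io.read_grid(out / "grid.json")
    cleaned, clean_log = clean_records(occ)
    assigned, assign_log = assign_grid(cleaned, grid)
    cells = build_incidence_by_cell(assigned, unit=config.unit_rule)
    bio_io.write_json({"cleaning": clean_log, "gridding": assign_log}, out / "ingest_log.json")
    cell_summary(cells).to_csv(out / "cell_summary.csv", index=False)
    incidence_long(cells).to_csv(out / "incidence_long.csv", index=False)


def stage_diversity(config: PipelineConfig, out: Path) -> None:
    """Effort filter, coverage profiles and coverage-standardized Hill numbers."""
    summary = pd.read_csv(out / "cell_summary.csv")
    long = pd.read_csv(out / "incidence_long.csv")
    cells = incidence_from_long(long, summary)
    eligible, _ = apply_effort_filter(cells, config.min_observers)
    if not eligible:
        raise InsufficientDataError("no cells pass the observer-effort filter; no saturated cells")
    div = estimate_cells(eligible, C_target=config.C_target, C_threshold=config.C_threshold)
    div.to_csv(out / "diversity.csv", index=False)
    if not div["saturated"].any():
        raise InsufficientDataError("no saturated cells; cannot train extrapolation models")


def _load_model_inputs(config: PipelineConfig, out: Path):
    cov = bio_io.read_covariates(out / "covariates.csv")
    div = pd.read_csv(out / "diversity.csv")
    sat = div[div["saturated"]].reset_index(drop=True)
    predictors = (
        [c for c in COVARIATE_NAMES if c in cov.columns] if config.use_covariates else []
    )
    methods = tuple(config.methods)
    if not predictors:
        methods = tuple(m for m in methods if m == "OK")
        logger.warning("no covariates available: only the OK model runs")
    model_table = cov.merge(sat[["cell_id", "D0", "D1", "D2"]], on="cell_id")
    return cov, sat, predictors, methods, model_table


def stage_validate(config: PipelineConfig, out: Path) -> None:
    """Cross-validate the candidate models per metric and select the best."""
    _, _, predictors, methods, model_table = _load_model_inputs(config, out)
    reports = []
    for metric in config.metrics:
        rep = cross_validate(
            model_table, metric, predictors, methods=methods, k=config.cv_k, seed=config.seed
        )
        rep.insert(0, "metric", metric)
        reports.append(rep)
    cv_report = pd.concat(reports, ignore_index=True)
    cv_report.to_csv(out / "cv_report.csv", index=False)
    bio_io.write_json(select_model(cv_report), out / "selected_model.json")


def stage_extrapolate(config: PipelineConfig, out: Path, method: str | None = None) -> None:
    """Fit the selected model on all saturated cells; write optimized maps."""
    cov, sat, predictors, methods, model_table = _load_model_inputs(config, out)
    if method is None:
        sel_path = out / "selected_model.json"
        if sel_path.exists():
            method = json.loads(sel_path.read_text())["consensus"]
        else:
            method = methods[-1]
    for metric in config.metrics:
        pred, se, _ = fit_and_predict(
            method,
            model_table,
            cov,
            metric,
            predictors,
            collinearity_r=config.collinearity_r,
            outcome_r=config.screening_r,
        )
        pred_df = pd.DataFrame({"cell_id": cov["cell_id"], "prediction": pred, "se": se})
        pred_df.to_csv(out / f"predictions_{metric}.csv", index=False)
        fmap = compose_final_map(pred_df, sat[["cell_id", metric]], observed_col=metric)
        fmap.table.to_csv(out / f"final_map_{metric}.csv", index=False)


def stage_disparity(config: PipelineConfig, out: Path) -> None:
    """Tract aggregation, DAC comparison, correlations, spatial mixed models."""
    grid = bio_io.read_grid(out / "grid.json")
    tracts = bio_io.read_tracts_geojson(out / "tracts.geojson")
    cell_vals = pd.DataFrame({"cell_id": np.arange(grid.n_cells)})
    for metric in config.metrics:
        fmap = pd.read_csv(out / f"final_map_{metric}.csv")
        cell_vals[metric] = (
            fmap.set_index("cell_id")["value"].reindex(cell_vals["cell_id"]).to_numpy()
        )
    tract_means = summarize_to_tracts(cell_vals, grid, tracts, list(config.metrics))
    tract_full = tracts.merge(tract_means, on="tract_id")
    tract_full.to_csv(out / "tract_summary.csv", index=False)

    metric_cols = [f"mean_{m}" for m in config.metrics]
    compare_groups(tract_full, metric_cols, flag_col="dac").to_csv(
        out / "dac_ttest.csv", index=False
    )
    correlate(tract_full, metric_cols, list(SES_VARIABLES)).to_csv(
        out / "correlations.csv", index=False
    )
    lmm_rows = []
    for metric_col in metric_cols:
        for ses in SES_VARIABLES:
            try:
                fit = fit_spatial_lmm(tract_full, ses, metric_col)
            except InsufficientDataError as exc:
                logger.warning("LMM skipped for %s/%s: %s", metric_col, ses, exc)
                continue
            lmm_rows.append(
                {
                    "outcome": metric_col,
                    "ses_var": ses,
                    "beta": fit.beta,
                    "se": fit.se,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "spatial_range": fit.spatial_range,
                    "county_var": fit.county_var,
                    "resid_var": fit.resid_var,
                    "converged": fit.converged,
                }
            )
    pd.DataFrame(lmm_rows).to_csv(out / "lmm_results.csv", index=False)


def stage_report(config: PipelineConfig, out: Path) -> None:
    """Manifest and human-readable report from the written artifacts."""
    div = pd.read_csv(out / "diversity.csv")
    cv_report = pd.read_csv(out / "cv_report.csv")
    selection = json.loads((out / "selected_model.json").read_text())
    ttest = pd.read_csv(out / "dac_ttest.csv")
    lmm = pd.read_csv(out / "lmm_results.csv")
    occ_rows = sum(1 for _ in open(out / "occurrences.csv")) - 1
    grid = bio_io.read_grid(out / "grid.json")

    manifest = {
        "package": "biodivmap",
        "version": biodivmap.__version__,
        "seed": config.seed,
        "config": _manifest_config(config),
        "config_hash": _config_hash(config),
        "n_cells": int(grid.n_cells),
        "n_records": int(occ_rows),
        "n_eligible_cells": int(len(div)),
        "n_saturated_cells": int(div["saturated"].sum()),
        "selected_model": selection,
    }
    bio_io.write_json(manifest, out / "manifest.json")

    lines = ["biodivmap run report", "=" * 64, ""]
    lines.append(
        f"cells: {grid.n_cells} total, {len(div)} effort-eligible, "
        f"{int(div['saturated'].sum())} saturated "
        f"(coverage at doubled effort >= {config.C_threshold:.0%})"
    )
    lines.append("")
    lines.append("Optimized map statistics (observed + modeled cells):")
    for metric in config.metrics:
        v = pd.read_csv(out / f"final_map_{metric}.csv")["value"]
        lines.append(
            f"  {metric}: mean={v.mean():.1f} median={v.median():.1f} "
            f"min={v.min():.1f} max={v.max():.1f} sd={v.std():.1f}"
        )
    lines.append("")
    lines.append("Cross-validation (pooled held-out predictions):")
    for _, r in cv_report[cv_report["split"] == "validation"].iterrows():
        lines.append(
            f"  {r['metric']:>3} {r['method']:>7}: corr={r['corr']:.2f} "
            f"RMSE={r['RMSE']:.2f} RRMSE={r['RRMSE']:.1f}% MAE={r['MAE']:.2f} RMAE={r['RMAE']:.1f}%"
        )
    lines.append(f"selected model: {selection['consensus']}")
    lines.append("")
    lines.append("DAC vs other tracts (Welch t-test):")
    for _, r in ttest.iterrows():
        lines.append(
            f"  {r['metric']}: DAC {r['flagged_mean']:.1f} ({r['flagged_sd']:.1f}) vs "
            f"other {r['other_mean']:.1f} ({r['other_sd']:.1f}), p={r['p_value']:.2e}"
        )
    lines.append("")
    lines.append("Spatial LMM associations (diversity per % SES, 95% CI):")
    for _, r in lmm.iterrows():
        lines.append(
            f"  {r['outcome']} ~ {r['ses_var']}: {r['beta']:.3f} "
            f"({r['ci_low']:.3f}, {r['ci_high']:.3f})"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def run(config: PipelineConfig) -> Path:
    """Execute the pipeline end to end; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, out)
    stage_ingest(config, out)
    stage_diversity(config, out)
    stage_validate(config, out)
    stage_extrapolate(config, out)
    stage_disparity(config, out)
    stage_report(config, out)
    return out
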