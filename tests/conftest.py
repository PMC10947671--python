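"""Shared fixtures: a reusable synthetic landscape and derived tables."""

import logging
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

logging.getLogger("biodivmap").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message=".*coverage.*capping.*")


@pytest.fixture(scope="session")
def demo_landscape():
    """A 15x15 landscape with records, used by several integration tests."""
    from biodivmap.synthetic import SyntheticConfig, generate_occurrences, generate_truth

    cfg = SyntheticConfig(seed=42, grid_dims=(15, 15), observer_rate=35.0)
    truth = generate_truth(cfg)
    occ = generate_occurrences(truth, cfg)
    return cfg, truth, occ


@pytest.fixture(scope="session")
def demo_cells(demo_landscape):
    """Cleaned, gridded, incidence-built cells of the demo landscape."""
    from biodivmap import ingest

    cfg, truth, occ = demo_landscape
    cleaned, _ = ingest.clean_records(occ)
    assigned, _ = ingest.assign_grid(cleaned, truth.grid)
    cells = ingest.build_incidence_by_cell(assigned)
    return cfg, truth, cells


@pytest.fixture(scope="session")
def saturated_model_table(demo_cells):
    """Covariates + observed coverage-standardized metrics on saturated cells."""
    from biodivmap import ingest
    from biodivmap.coverage import estimate_cells

    cfg, truth, cells = demo_cells
    eligible, _ = ingest.apply_effort_filter(cells, 40)
    div = estimate_cells(eligible)
    sat = div[div["saturated"]].reset_index(drop=True)
    cov = truth.covariates.merge(truth.grid.centroids(), on="cell_id")
    table = cov.merge(sat[["cell_id", "D0", "D1", "D2"]], on="cell_id")
    return truth, cov, table


def random_incidence(rng: np.random.Generator, t_max: int = 12, s_max: int = 15):
    """A random small incidence vector for fuzz tests."""
    from biodivmap.ingest import IncidenceData

    T = int(rng.integers(3, t_max + 1))
    S = int(rng.integers(2, s_max + 1))
    y = np.minimum(rng.geometric(0.35, size=S), T)
    return IncidenceData(cell_id=0, T=T, Y=y)
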