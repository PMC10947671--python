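"""Occurrence-record cleaning, grid assignment and incidence building.

Records arrive in a Darwin-Core-style table (``scientificName``,
``decimalLatitude``, ``decimalLongitude``, ``recordedBy``, ``eventDate``,
``establishmentMeans``, ``taxonRank``). Cleaning removes records with missing
taxonomy or coordinates, records not identified to species level, and
cultivated (non-wild) records. Retained records are assigned to an equal-area
grid of square cells (default 5 km) under a half-open cell convention, and
per-cell abundance is collapsed to incidence: the sampling unit is an
observer-day (configurable to observer), and a species counts at most once per
unit. Cells then pass an effort filter (default: at least 40 unique observers)
before any coverage analysis.

Coordinates are treated as planar metres in a single projected equal-area CRS;
the package performs no reprojection.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from biodivmap.errors import ConfigurationError, SchemaError

logger = logging.getLogger(__name__)

#: default Darwin-Core-style column names, remappable via ``columns=`` kwargs
DEFAULT_COLUMNS: dict[str, str] = {
    "species": "scientificName",
    "x": "decimalLongitude",
    "y": "decimalLatitude",
    "observer": "recordedBy",
    "date": "eventDate",
    "establishment": "establishmentMeans",
    "rank": "taxonRank",
}

#: taxonRank values accepted as taxonomically complete
COMPLETE_RANKS = frozenset({"species", "subspecies", "variety", "form", "hybrid"})

UnitRule = Literal["observer-day", "observer"]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid of square cells in a projected equal-area CRS.

    Cell (ix, iy) covers the half-open box
    ``[x0 + ix*s, x0 + (ix+1)*s) x [y0 + iy*s, y0 + (iy+1)*s)``; a point on a
    shared edge belongs to the higher-index cell. Scalar ids are
    ``iy * cols + ix``.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 5000.0
    rows: int = 1
    cols: int = 1
    crs: str = "local-planar"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError(f"cell_size must be > 0, got {self.cell_size}")
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError(f"grid dims must be >= 1, got {self.rows}x{self.cols}")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Half-open cell indices (ix, iy) of planar points; may be out of range."""
        x0, y0 = self.origin
        ix = np.floor((np.asarray(x, float) - x0) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y, float) - y0) / self.cell_size).astype(int)
        return ix, iy

    def cell_id(self, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        return np.asarray(iy) * self.cols + np.asarray(ix)

    def in_extent(self, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        return (ix >= 0) & (ix < self.cols) & (iy >= 0) & (iy < self.rows)

    def centroids(self) -> pd.DataFrame:
        """Centroid coordinates of all cells, indexed by scalar cell_id."""
        x0, y0 = self.origin
        iy, ix = np.divmod(np.arange(self.n_cells), self.cols)
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "x": x0 + (ix + 0.5) * self.cell_size,
                "y": y0 + (iy + 0.5) * self.cell_size,
            }
        )

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        iy, ix = divmod(int(cell_id), self.cols)
        x0, y0 = self.origin
        s = self.cell_size
        return (x0 + ix * s, y0 + iy * s, x0 + (ix + 1) * s, y0 + (iy + 1) * s)


@dataclass
class IncidenceData:
    """Per-cell incidence-frequency summary.

    ``T`` sampling units; ``Y[i]`` is the number of units in which species i
    was detected (1 <= Y[i] <= T). Derived quantities: total incidences
    ``U = sum(Y)``, observed richness ``S_obs``, uniques ``Q1`` (species seen
    in exactly one unit) and duplicates ``Q2`` (exactly two units).
    """

    cell_id: int
    T: int
    Y: np.ndarray
    species: np.ndarray | None = None
    n_observers: int = 0

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int64)
        if self.T < 0:
            raise ValueError("T must be non-negative")
        if self.Y.size and (self.Y.min() < 1 or self.Y.max() > self.T):
            raise ValueError("incidence frequencies must satisfy 1 <= Y_i <= T")

    @property
    def U(self) -> int:
        return int(self.Y.sum())

    @property
    def S_obs(self) -> int:
        return int(self.Y.size)

    @property
    def Q1(self) -> int:
        return int(np.count_nonzero(self.Y == 1))

    @property
    def Q2(self) -> int:
        return int(np.count_nonzero(self.Y == 2))


def _resolve_columns(columns: Mapping[str, str] | None) -> dict[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    return cols


def _require(df: pd.DataFrame, names: Iterable[str]) -> None:
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise SchemaError(f"occurrence table is missing columns: {missing}")


def clean_records(
    records: pd.DataFrame, columns: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the record-eligibility rules; return (retained, removal log).

    Removal rules, applied as a union (a record failing several rules is
    counted under each but removed once):

    - ``missing_species``: null/empty species name;
    - ``missing_coordinates``: null x or y;
    - ``incomplete_taxonomy``: taxonRank coarser than species;
    - ``not_wild``: establishmentMeans marks the record as cultivated.

    Cleaning is idempotent: applying it to its own output removes nothing.
    """
    c = _resolve_columns(columns)
    _require(records, [c["species"], c["x"], c["y"], c["establishment"], c["rank"]])

    species = records[c["species"]]
    bad_species = species.isna() | (species.astype("string").str.strip() == "")
    bad_coord = records[c["x"]].isna() | records[c["y"]].isna()
    rank = records[c["rank"]].astype("string").str.lower()
    bad_rank = rank.isna() | ~rank.isin(COMPLETE_RANKS)
    est = records[c["establishment"]].astype("string").str.lower()
    not_wild = est.notna() & est.isin({"cultivated", "managed", "introduced (cultivated)"})

    removed = bad_species | bad_coord | bad_rank | not_wild
    log = {
        "missing_species": int(bad_species.sum()),
        "missing_coordinates": int(bad_coord.sum()),
        "incomplete_taxonomy": int(bad_rank.sum()),
        "not_wild": int(not_wild.sum()),
        "removed_total": int(removed.sum()),
        "retained": int((~removed).sum()),
    }
    for rule in ("missing_species", "missing_coordinates", "incomplete_taxonomy", "not_wild"):
        logger.info("clean_records: %s removed %d records", rule, log[rule])
    return records.loc[~removed].copy(), log


def assign_grid(
    records: pd.DataFrame,
    grid: GridSpec,
    columns: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each record to a grid cell; drop records outside the extent.

    Adds ``cell_ix``, ``cell_iy`` and scalar ``cell_id`` columns. Boundary
    points follow the half-open convention (a point exactly on a shared edge
    belongs to the higher-index cell; the grid origin maps to cell (0, 0)).
    """
    c = _resolve_columns(columns)
    _require(records, [c["x"], c["y"]])
    x = pd.to_numeric(records[c["x"]], errors="coerce").to_numpy(float)
    y = pd.to_numeric(records[c["y"]], errors="coerce").to_numpy(float)
    bad = ~np.isfinite(x) | ~np.isfinite(y)
    ix, iy = grid.cell_index(np.where(bad, 0.0, x), np.where(bad, 0.0, y))
    inside = grid.in_extent(ix, iy) & ~bad

    out = records.loc[inside].copy()
    out["cell_ix"] = ix[inside]
    out["cell_iy"] = iy[inside]
    out["cell_id"] = grid.cell_id(ix[inside], iy[inside])
    log = {
        "unparseable_coordinates": int(bad.sum()),
        "outside_extent": int((~inside & ~bad).sum()),
        "assigned": int(inside.sum()),
    }
    if log["outside_extent"] or log["unparseable_coordinates"]:
        logger.info(
            "assign_grid: dropped %d outside extent, %d unparseable",
            log["outside_extent"],
            log["unparseable_coordinates"],
        )
    return out, log


def build_incidence(
    records_in_cell: pd.DataFrame,
    unit: UnitRule = "observer-day",
    columns: Mapping[str, str] | None = None,
    cell_id: int | None = None,
) -> IncidenceData:
    """Collapse one cell's records to incidence frequencies.

    A sampling unit is a distinct (observer, date) pair (``observer-day``) or
    a distinct observer (``observer``). Duplicate records of a species within
    one unit collapse to a single incidence.
    """
    c = _resolve_columns(columns)
    if unit not in ("observer-day", "observer"):
        raise ConfigurationError(f"unknown sampling-unit rule: {unit!r}")
    if records_in_cell.empty:
        return IncidenceData(cell_id=-1 if cell_id is None else cell_id, T=0, Y=np.array([], int))
    _require(records_in_cell, [c["species"], c["observer"], c["date"]])
    if cell_id is None:
        if "cell_id" in records_in_cell.columns:
            ids = records_in_cell["cell_id"].unique()
            if len(ids) > 1:
                raise SchemaError(f"records span multiple cells: {sorted(ids)[:5]}...")
            cell_id = int(ids[0])
        else:
            cell_id = -1

    obs = records_in_cell[c["observer"]].astype(str)
    if unit == "observer-day":
        unit_key = obs + "\x1f" + records_in_cell[c["date"]].astype(str)
    else:
        unit_key = obs
    sp = records_in_cell[c["species"]].astype(str)

    pairs = pd.DataFrame({"unit": unit_key.to_numpy(), "sp": sp.to_numpy()}).drop_duplicates()
    T = int(pairs["unit"].nunique())
    counts = pairs.groupby("sp", sort=True).size()
    return IncidenceData(
        cell_id=cell_id,
        T=T,
        Y=counts.to_numpy(),
        species=counts.index.to_numpy(),
        n_observers=int(obs.nunique()),
    )


def build_incidence_by_cell(
    records: pd.DataFrame,
    unit: UnitRule = "observer-day",
    columns: Mapping[str, str] | None = None,
) -> list[IncidenceData]:
    """Incidence data for every populated cell, ordered by cell_id."""
    _require(records, ["cell_id"])
    out = []
    for cid, grp in records.groupby("cell_id", sort=True):
        out.append(build_incidence(grp, unit=unit, columns=columns, cell_id=int(cid)))
    return out


def apply_effort_filter(
    cells: Sequence[IncidenceData], min_observers: int = 40
) -> tuple[list[IncidenceData], list[IncidenceData]]:
    """Split cells into (eligible, ineligible) by unique-observer count.

    A cell is eligible for coverage analysis when at least ``min_observers``
    distinct observers reported records in it (default 40). Ineligible cells
    are still mapped later by extrapolation.
    """
    eligible = [c for c in cells if c.n_observers >= min_observers]
    ineligible = [c for c in cells if c.n_observers < min_observers]
    logger.info(
        "effort filter (>=%d observers): %d eligible, %d ineligible",
        min_observers,
        len(eligible),
        len(ineligible),
    )
    return eligible, ineligible


def cell_summary(cells: Sequence[IncidenceData]) -> pd.DataFrame:
    """Wide summary table (cell_id, T, S_obs, U, Q1, Q2, n_observers)."""
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "T": c.T,
                "S_obs": c.S_obs,
                "U": c.U,
                "Q1": c.Q1,
                "Q2": c.Q2,
                "n_observers": c.n_observers,
            }
            for c in cells
        ]
    )


def incidence_long(cells: Sequence[IncidenceData]) -> pd.DataFrame:
    """Sparse long-format incidence table (cell_id, species_id, Y)."""
    frames = []
    for c in cells:
        if c.S_obs == 0:
            continue
        sp = c.species if c.species is not None else np.arange(c.S_obs).astype(str)
        frames.append(pd.DataFrame({"cell_id": c.cell_id, "species_id": sp, "Y": c.Y}))
    if not frames:
        return pd.DataFrame(columns=["cell_id", "species_id", "Y"])
    return pd.concat(frames, ignore_index=True)


def incidence_from_long(table: pd.DataFrame, summary: pd.DataFrame) -> list[IncidenceData]:
    """Rebuild IncidenceData objects from the long + summary CSV round trip."""
    _require(table, ["cell_id", "species_id", "Y"])
    _require(summary, ["cell_id", "T", "n_observers"])
    meta = summary.set_index("cell_id")
    out = []
    for cid in meta.index:
        sub = table[table["cell_id"] == cid].sort_values("species_id")
        out.append(
            IncidenceData(
                cell_id=int(cid),
                T=int(meta.at[cid, "T"]),
                Y=sub["Y"].to_numpy(int),
                species=sub["species_id"].to_numpy(),
                n_observers=int(meta.at[cid, "n_observers"]),
            )
        )
    return out
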