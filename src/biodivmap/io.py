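"""Readers and writers for the pipeline's plain-text artifact formats.

Occurrences travel as Darwin-Core-style CSV, covariates as wide CSV keyed by
cell_id, grid specifications as JSON, tracts as GeoJSON (rectangular polygons
with attribute properties). Writers are deterministic (sorted keys, stable
column order) so that identically-seeded runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from biodivmap.errors import SchemaError
from biodivmap.ingest import GridSpec


def write_occurrences(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_covariates(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["cell_id"] + sorted(c for c in table.columns if c != "cell_id")
    table[cols].to_csv(path, index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    if "cell_id" not in tab.columns:
        raise SchemaError("covariate CSV must have a cell_id column")
    return tab


def write_grid(grid: GridSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(grid), sort_keys=True, indent=1) + "\n")


def read_grid(path: str | Path) -> GridSpec:
    d = json.loads(Path(path).read_text())
    d["origin"] = tuple(d["origin"])
    return GridSpec(**d)


def write_tracts_geojson(tracts: pd.DataFrame, path: str | Path) -> None:
    """Rectangular tracts (xmin/ymin/xmax/ymax) as a GeoJSON FeatureCollection."""
    features = []
    attr_cols = [
        c for c in tracts.columns if c not in ("xmin", "ymin", "xmax", "ymax", "geometry")
    ]
    for _, r in tracts.iterrows():
        ring = [
            [r["xmin"], r["ymin"]],
            [r["xmax"], r["ymin"]],
            [r["xmax"], r["ymax"]],
            [r["xmin"], r["ymax"]],
            [r["xmin"], r["ymin"]],
        ]
        props = {}
        for c in attr_cols:
            v = r[c]
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, (np.bool_,)):
                v = bool(v)
            props[c] = v
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def read_tracts_geojson(path: str | Path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    rows = []
    for feat in doc["features"]:
        coords = np.asarray(feat["geometry"]["coordinates"][0])
        row = dict(feat["properties"])
        row["xmin"], row["ymin"] = coords.min(axis=0)
        row["xmax"], row["ymax"] = coords.max(axis=0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1, default=_coerce) + "\n")


def _coerce(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON-serializable: {type(v)}")
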