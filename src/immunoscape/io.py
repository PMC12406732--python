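"""Readers/writers for cell tables, region geometry and configuration.

Cell tables are CSV (cell_id, x_um, y_um, per-marker columns; unknown
columns pass through).  Region maps serialize to GeoJSON with one feature
per region and labels/attributes in properties.  Configuration is YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .regions import NestRegion, RegionMap

REQUIRED_COLUMNS = ("cell_id", "x_um", "y_um")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cell table CSV.

    Requires cell_id, x_um, y_um; coordinates must be numeric (errors name
    the first offending row).  Boolean-like call/positivity columns are
    restored to bool; unknown columns are preserved.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cell table {path} missing required column {col!r}")
    for col in ("x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & df[col].notna())
        if len(bad):
            raise ValueError(
                f"non-numeric {col} at row {int(bad[0])} of {path}")
        df[col] = coerced.astype(float)
    for col in df.columns:
        if col.endswith(("_pos", "_call")) or col in (
                "is_tumor", "is_leukocyte", "nos2s", "tumor_cox2",
                "tumor_pdl1", "mac_pdl1", "mac_cox2"):
            if df[col].dtype == object:
                df[col] = df[col].map({"True": True, "False": False}).astype(bool)
            else:
                df[col] = df[col].astype(bool)
    for col in ("true_nos2_grade", "nos2_grade"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, index=False)


# --------------------------------------------------------------------------
# geometry

def region_map_to_geojson(region_map: RegionMap) -> dict:
    """One feature per region; label and attributes in properties."""
    feats = []

    def feat(geom, props):
        feats.append({"type": "Feature", "geometry": mapping(geom),
                      "properties": props})

    for nest in region_map.nests:
        feat(nest.polygon, {"label": "nest", "nest_id": nest.nest_id,
                            "area_mm2": nest.area_mm2,
                            "nos2_status": nest.nos2_status,
                            "nos2_fraction": _jsonable(nest.nos2_fraction),
                            "thin": nest.thin})
        feat(nest.edge, {"label": "edge", "nest_id": nest.nest_id,
                         "nos2_status": nest.nos2_status})
        if not nest.core.is_empty:
            feat(nest.core, {"label": "core", "nest_id": nest.nest_id})
    for i, p in enumerate(region_map.satellites):
        feat(p, {"label": "satellite", "satellite_id": i,
                 "area_mm2": p.area * 1e-6})
    for i, p in enumerate(region_map.aggregates):
        feat(p, {"label": "lymphoid_aggregate", "aggregate_id": i})
    return {"type": "FeatureCollection", "features": feats,
            "properties": {"log": _jsonable(region_map.log)}}


def region_map_from_geojson(doc: dict) -> RegionMap:
    rm = RegionMap(log=doc.get("properties", {}).get("log", {}))
    nests: dict[int, dict] = {}
    for f in doc["features"]:
        props = f["properties"]
        geom = shape(f["geometry"])
        label = props["label"]
        if label in ("nest", "edge", "core"):
            nests.setdefault(props["nest_id"], {})[label] = (geom, props)
        elif label == "satellite":
            rm.satellites.append(geom)
        elif label == "lymphoid_aggregate":
            rm.aggregates.append(geom)
    for nid in sorted(nests):
        parts = nests[nid]
        poly, props = parts["nest"]
        edge = parts.get("edge", (shapely.Polygon(), {}))[0]
        core = parts.get("core", (shapely.Polygon(), {}))[0]
        rm.nests.append(NestRegion(
            nest_id=nid, polygon=poly, area_mm2=props["area_mm2"],
            edge=edge, core=core, nos2_status=props["nos2_status"],
            nos2_fraction=(props["nos2_fraction"]
                           if props["nos2_fraction"] is not None
                           else float("nan")),
            thin=props["thin"]))
    return rm


def write_geojson(doc: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_geojson(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# --------------------------------------------------------------------------
# config / JSON helpers

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))


def load_config(path: str | Path) -> dict:
    import yaml
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path: str | Path) -> None:
    import yaml
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(cfg), fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(_jsonable(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
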