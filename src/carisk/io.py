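"""Readers and writers for region tables: CSV and GeoJSON point features.

Areas and providers round-trip through either CSV or GeoJSON (a
FeatureCollection of Point features whose properties carry the non-spatial
columns); person records round-trip through CSV with ISO-8601 dates. NaN is
serialized as null/empty so files stay standards-compliant.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_table_csv", "read_areas_csv", "read_providers_csv",
    "write_points_geojson", "read_points_geojson",
    "write_records_csv", "read_records_csv",
]

_FLOAT_FMT = "%.12g"


def write_table_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_areas_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str})
    for col in ("irsd", "access"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def read_providers_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    if "ratio" not in df.columns:
        df["ratio"] = np.nan
    return df


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating, float)):
        f = float(v)
        return None if math.isnan(f) else f
    return v


def write_points_geojson(df: pd.DataFrame, path) -> None:
    """Write a table with x_km/y_km columns as GeoJSON point features."""
    props_cols = [c for c in df.columns if c not in ("x_km", "y_km")]
    features = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(d["x_km"]), float(d["y_km"])]},
            "properties": {c: _jsonable(d[c]) for c in props_cols},
        })
    obj = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def read_points_geojson(path) -> pd.DataFrame:
    obj = json.loads(Path(path).read_text())
    if obj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    for feat in obj["features"]:
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"{path}: only Point features are supported")
        x, y = geom["coordinates"][:2]
        row = {"x_km": float(x), "y_km": float(y)}
        row.update({k: (np.nan if v is None else v)
                    for k, v in (feat.get("properties") or {}).items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_records_csv(records: pd.DataFrame, path) -> None:
    df = records.copy()
    if "test_date" in df.columns:
        df["test_date"] = pd.to_datetime(df["test_date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str})
    if "test_date" in df.columns:
        df["test_date"] = pd.to_datetime(df["test_date"], format="%Y-%m-%d")
    return df
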