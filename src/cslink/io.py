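"""File I/O helpers: CSV tables, GeoJSON point layers, YAML/JSON configs.

GeoJSON output follows RFC 7946 (Point FeatureCollections, [x, y]
coordinate order in the planar projected frame used throughout).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def points_to_geojson(frame: pd.DataFrame, x_col: str = "x", y_col: str = "y", properties: list | None = None) -> dict:
    """A DataFrame of points as a GeoJSON FeatureCollection dict."""
    if properties is None:
        properties = [c for c in frame.columns if c not in (x_col, y_col)]
    features = []
    for _, row in frame.iterrows():
        props = {}
        for key in properties:
            value = row[key]
            if isinstance(value, (np.integer,)):
                value = int(value)
            elif isinstance(value, (np.floating,)):
                value = float(value)
            elif isinstance(value, (np.bool_,)):
                value = bool(value)
            props[key] = value
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row[x_col]), float(row[y_col])]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def geojson_to_points(collection: dict) -> pd.DataFrame:
    """Inverse of :func:`points_to_geojson` for Point FeatureCollections."""
    rows = []
    for feat in collection["features"]:
        if feat["geometry"]["type"] != "Point":
            raise ValueError("only Point features are supported")
        x, y = feat["geometry"]["coordinates"]
        rows.append({"x": x, "y": y, **feat.get("properties", {})})
    return pd.DataFrame(rows)


def write_geojson(collection: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(collection, indent=1))


def read_geojson(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """RFC-4180 CSV with a header row, UTF-8."""
    frame.to_csv(path, index=False, lineterminator="\r\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serialisable: {type(value)}")
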