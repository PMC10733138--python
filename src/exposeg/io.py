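"""Delimited tables, GeoJSON layers, and config round-tripping.

Coordinates are WGS84 decimal degrees written with 10 decimals (round trips
are identity to well under 1e-9 deg ~ 0.1 mm); timestamps are integer epoch
seconds UTC.  Schema violations raise with the offending column and row.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

logger = logging.getLogger(__name__)

__all__ = ["read_pings", "write_pings", "read_individuals", "write_individuals",
           "read_edges", "write_edges", "read_registry", "write_registry",
           "write_table", "read_table", "features_to_geojson",
           "geojson_to_features", "write_geojson", "read_geojson"]

_FLOAT_FMT = "%.10f"
KNOWN_KINDS = ("tract", "poi", "hub", "road")

PING_SCHEMA = {"user_id": str, "timestamp_s": "int64", "lat": float,
               "lon": float, "accuracy_m": float}


def _validate(df: pd.DataFrame, schema: dict, what: str,
              checks: dict | None = None) -> pd.DataFrame:
    for col, dtype in schema.items():
        if col not in df.columns:
            raise ValueError(f"{what}: missing required column {col!r}")
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as err:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:1]
            row = int(bad[0]) if len(bad) else "?"
            raise ValueError(
                f"{what}: column {col!r} row {row}: {err}") from None
    for col, pred in (checks or {}).items():
        ok = pred(df[col].to_numpy())
        if not ok.all():
            row = int(df.index[~ok][0])
            raise ValueError(f"{what}: column {col!r} row {row} "
                             f"violates schema constraint")
    return df


def read_pings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str})
    return _validate(df, PING_SCHEMA, f"ping table {path}", checks={
        "lat": np.isfinite, "lon": np.isfinite,
        "accuracy_m": lambda a: np.isfinite(a) & (a > 0),
    })


def write_pings(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_individuals(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str})
    if "user_id" not in df.columns:
        raise ValueError(f"individual table {path}: missing column 'user_id'")
    return df.set_index("user_id")


def write_individuals(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, float_format=_FLOAT_FMT)


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_i": str, "user_j": str},
                     keep_default_na=False, na_values=[""])
    for col in ("poi_id", "poi_category", "hub_id", "component"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return _validate(df, {"user_i": str, "user_j": str, "k": "int64",
                          "t": "int64", "lat": float, "lon": float},
                     f"edge table {path}")


def write_edges(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_registry(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"property_id": str})
    return _validate(df, {"property_id": str, "lat": float, "lon": float,
                          "rent_usd_month": float}, f"registry {path}",
                     checks={"rent_usd_month":
                             lambda r: np.isfinite(r) & (r > 0)})


def write_registry(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.8g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def features_to_geojson(features) -> dict:
    """Package-internal feature dicts -> GeoJSON FeatureCollection."""
    out = []
    for f in features:
        props = {"id": f["id"], "kind": f["kind"], **f.get("props", {})}
        out.append({"type": "Feature", "properties": props,
                    "geometry": mapping(f["geometry"])})
    return {"type": "FeatureCollection", "features": out}


def geojson_to_features(obj: dict) -> list:
    """GeoJSON FeatureCollection -> feature dicts; unknown kinds are skipped
    with a warning, never an error."""
    feats = []
    for i, f in enumerate(obj.get("features", [])):
        props = dict(f.get("properties") or {})
        kind = props.pop("kind", None)
        fid = props.pop("id", f"feature{i}")
        if kind not in KNOWN_KINDS:
            logger.warning("skipping feature %r with unknown kind %r", fid, kind)
            continue
        feats.append({"id": str(fid), "kind": kind,
                      "geometry": shape(f["geometry"]), "props": props})
    return feats


def write_geojson(features, path) -> None:
    Path(path).write_text(
        json.dumps(features_to_geojson(features), sort_keys=True) + "\n")


def read_geojson(path) -> list:
    return geojson_to_features(json.loads(Path(path).read_text()))
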