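"""Spatial context for exposures: homes, tracts, POIs, hubs, linear features.

Every rule operates on the exposure's own point (the midpoint of the two
contributing pings, which is what the edge carries): at-home within 50 m of
an endpoint's home; home-tract membership of both/one/neither endpoint;
point-in-polygon against POI and hub layers with a smallest-area tie-break
for overlaps; and proximity (<= 20 m) to road/rail polylines.  Polygon
containment is closed — boundary points count as inside.

All annotators are pure column-adders: order-invariant and idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .geometry import LocalProjection, geometry_anchor, haversine_m

logger = logging.getLogger(__name__)

__all__ = ["SpatialLayer", "load_layer", "locate_points", "annotate_home",
           "classify_component", "annotate_poi", "annotate_hub",
           "annotate_linear", "hub_coverage_stats", "annotate_edges",
           "COMPONENT_LABELS"]

COMPONENT_LABELS = ("both_in_home_tract", "one_in_home_tract",
                    "neither_in_home_tract")


@dataclass
class SpatialLayer:
    """A validated feature layer with a spatial index.

    ``features`` are dicts {'id', 'kind', 'geometry' (lon/lat shapely),
    'props'}; geometries are additionally kept projected to local metres for
    metric queries.
    """

    kind: str
    ids: np.ndarray
    geoms: np.ndarray          # lon/lat shapely geometries
    props: list
    projection: LocalProjection
    geoms_m: np.ndarray        # locally projected (metres)
    tree: STRtree              # over geoms_m
    areas_m2: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def prop(self, key, default=None) -> np.ndarray:
        return np.array([p.get(key, default) for p in self.props], dtype=object)


def load_layer(features, kind: str) -> SpatialLayer:
    """Validate features of one kind and build the spatial index.

    Polygons must be valid (non-self-intersecting); an invalid feature is a
    load error naming the feature id.  Ids must be unique within the layer.
    """
    feats = [f for f in features if f.get("kind") == kind]
    ids = [str(f["id"]) for f in feats]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate feature ids in layer {kind!r}")
    geoms = []
    for f in feats:
        g = f["geometry"]
        if g.geom_type in ("Polygon", "MultiPolygon") and not g.is_valid:
            raise ValueError(
                f"invalid polygon for feature {f['id']!r} in layer {kind!r}: "
                f"{shapely.is_valid_reason(g)}")
        geoms.append(g)
    geoms = np.array(geoms, dtype=object)
    proj = (geometry_anchor(geoms) if len(geoms)
            else LocalProjection(0.0, 0.0))
    geoms_m = np.array([proj.project_geometry(g) for g in geoms], dtype=object)
    areas = np.array([g.area for g in geoms_m], dtype=float)
    return SpatialLayer(kind=kind, ids=np.array(ids, dtype=object),
                        geoms=geoms, props=[f.get("props", {}) for f in feats],
                        projection=proj, geoms_m=geoms_m,
                        tree=STRtree(list(geoms_m)), areas_m2=areas)


def locate_points(lats, lons, layer: SpatialLayer) -> np.ndarray:
    """Id of the containing feature per point, or '' if none.

    Containment is closed (boundary points are inside); when several
    features contain a point, the smallest-area feature wins.
    """
    lats = np.asarray(lats, dtype=float)
    out = np.full(lats.size, "", dtype=object)
    if len(layer) == 0 or lats.size == 0:
        return out
    x, y = layer.projection.to_xy(lats, np.asarray(lons, dtype=float))
    pts = shapely.points(x, y)
    pi, gi = layer.tree.query(pts, predicate="intersects")
    if pi.size == 0:
        return out
    # smallest containing area wins: sort by area descending so the smallest
    # is written last
    order = np.argsort(-layer.areas_m2[gi], kind="stable")
    out[pi[order]] = layer.ids[gi[order]]
    return out


def _homes_of(edges: pd.DataFrame, individuals: pd.DataFrame, side: str):
    ids = edges[f"user_{side}"]
    lat = individuals["home_lat"].reindex(ids).to_numpy()
    lon = individuals["home_lon"].reindex(ids).to_numpy()
    return lat, lon


def annotate_home(edges: pd.DataFrame, individuals: pd.DataFrame,
                  radius_m: float = 50.0) -> pd.DataFrame:
    """Flag exposures within ``radius_m`` of either endpoint's home.

    Endpoints without an inferred home keep the flag unset (False) and are
    counted in a log entry.
    """
    out = edges.copy()
    missing = 0
    for side in ("i", "j"):
        hlat, hlon = _homes_of(edges, individuals, side)
        known = np.isfinite(hlat)
        missing += int((~known).sum())
        d = np.full(len(edges), np.inf)
        d[known] = haversine_m(edges["lat"].to_numpy()[known],
                               edges["lon"].to_numpy()[known],
                               hlat[known], hlon[known])
        out[f"at_home_{side}"] = d <= radius_m
    if missing:
        logger.info("annotate_home: %d edge endpoints without a home", missing)
    return out


def classify_component(edges: pd.DataFrame, individuals: pd.DataFrame,
                       tract_layer: SpatialLayer) -> pd.DataFrame:
    """Label each exposure by how many endpoints are inside their own home
    tract at the exposure point: both / one / neither."""
    out = edges.copy()
    loc_tract = locate_points(edges["lat"].to_numpy(), edges["lon"].to_numpy(),
                              tract_layer)
    n_out = int((loc_tract == "").sum())
    if n_out:
        logger.info("classify_component: %d exposures outside all tracts", n_out)
    in_home = np.zeros(len(edges), dtype=int)
    if "home_tract_id" not in individuals.columns:
        raise ValueError("individuals need a home_tract_id column")
    for side in ("i", "j"):
        home_tract = individuals["home_tract_id"].reindex(
            edges[f"user_{side}"]).to_numpy(dtype=object)
        in_home += (loc_tract == home_tract) & (loc_tract != "")
    out["component"] = np.array(COMPONENT_LABELS, dtype=object)[2 - in_home]
    return out


def _annotate_polygon_layer(edges: pd.DataFrame, layer: SpatialLayer,
                            id_col: str) -> pd.DataFrame:
    out = edges.copy()
    out[id_col] = locate_points(edges["lat"].to_numpy(),
                                edges["lon"].to_numpy(), layer)
    return out


def annotate_poi(edges: pd.DataFrame, poi_layer: SpatialLayer) -> pd.DataFrame:
    """Attach poi_id and its category code where the exposure point lies
    inside a POI polygon (smallest polygon wins for overlaps)."""
    out = _annotate_polygon_layer(edges, poi_layer, "poi_id")
    naics = pd.Series(poi_layer.prop("naics", ""), index=poi_layer.ids)
    out["poi_category"] = out["poi_id"].map(naics).fillna("").to_numpy()
    return out


def annotate_hub(edges: pd.DataFrame, hub_layer: SpatialLayer) -> pd.DataFrame:
    """Attach hub_id where the exposure point lies inside a hub polygon.
    A POI nested inside a hub yields both poi_id and hub_id."""
    return _annotate_polygon_layer(edges, hub_layer, "hub_id")


def annotate_linear(edges: pd.DataFrame, line_layer: SpatialLayer,
                    buffer_m: float = 20.0, col: str = "near_road") -> pd.DataFrame:
    """Flag exposures within ``buffer_m`` of any polyline in the layer."""
    out = edges.copy()
    flag = np.zeros(len(edges), dtype=bool)
    if len(line_layer) and len(edges):
        x, y = line_layer.projection.to_xy(edges["lat"].to_numpy(),
                                           edges["lon"].to_numpy())
        pts = shapely.points(x, y)
        pi, _ = line_layer.tree.query(pts, predicate="dwithin",
                                      distance=buffer_m)
        flag[np.unique(pi)] = True
    out[col] = flag
    return out


def hub_coverage_stats(edges: pd.DataFrame, hub_layer: SpatialLayer,
                       region_polygon, radius_m: float = 1000.0) -> tuple[float, float]:
    """(share of exposures within ``radius_m`` of a hub, share of land area
    within ``radius_m`` of a hub).

    The land share is exact polygon arithmetic: area(union of hub buffers
    intersected with the region) / area(region), in local metres.
    """
    if len(hub_layer) == 0:
        return 0.0, 0.0
    proj = hub_layer.projection
    region_m = proj.project_geometry(region_polygon)
    buffered = shapely.union_all([shapely.buffer(g, radius_m)
                                  for g in hub_layer.geoms_m])
    land_frac = buffered.intersection(region_m).area / region_m.area
    if len(edges) == 0:
        return 0.0, float(land_frac)
    x, y = proj.to_xy(edges["lat"].to_numpy(), edges["lon"].to_numpy())
    pts = shapely.points(x, y)
    near = np.zeros(len(edges), dtype=bool)
    pi, _ = hub_layer.tree.query(pts, predicate="dwithin", distance=radius_m)
    near[np.unique(pi)] = True
    return float(near.mean()), float(land_frac)


def annotate_edges(edges: pd.DataFrame, individuals: pd.DataFrame,
                   tract_layer: SpatialLayer | None = None,
                   poi_layer: SpatialLayer | None = None,
                   hub_layer: SpatialLayer | None = None,
                   road_layer: SpatialLayer | None = None,
                   home_radius_m: float = 50.0,
                   road_buffer_m: float = 20.0) -> pd.DataFrame:
    """Run every configured annotator over an edge table."""
    out = annotate_home(edges, individuals, home_radius_m)
    if tract_layer is not None:
        out = classify_component(out, individuals, tract_layer)
    if poi_layer is not None:
        out = annotate_poi(out, poi_layer)
    if hub_layer is not None:
        out = annotate_hub(out, hub_layer)
    if road_layer is not None:
        out = annotate_linear(out, road_layer, road_buffer_m)
    return out
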