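"""Synthetic cities and GPS-like traces with known ground truth.

The generator emulates the raw inputs of the exposure-segregation pipeline —
device pings, census-tract polygons, POI and hub polygons, a property
registry with monthly rents — for a flat rectangular city laid out in metric
coordinates and anchored at a declared WGS84 reference point.  Everything a
downstream stage infers (home locations, SES, path crossings) has a recorded
true value here, so the pipeline can be tested end to end without any
external data.

Model sketch
------------
* Tracts tile the city (grid or clipped Voronoi).  Each tract carries a
  latent SES level u_t ~ N(0,1); an individual's log-rent is
  ``mu + sigma * (sqrt(rho) * u_t + sqrt(1-rho) * z_i)`` where ``rho`` is the
  share of rent variance explained by the tract
  (``tract_ses_autocorrelation``).
* Individuals live at a fixed home point inside their tract, emit night-time
  pings at home and day-time pings at venues.  Venue choice is a softmax over
  ``-distance/distance_scale - venue_homophily * |z_venue - z_i|``: the
  homophily knob controls how strongly people sort into venues matching
  their own SES.  The paper documents the sorting phenomenon, not a
  generative model; this choice model is the package's own.
* Hubs are larger polygons holding most POIs.  ``bridging`` placement puts
  hubs on boundaries between SES-dissimilar tracts, ``embedded`` at tract
  centres, ``random`` anywhere.
* Observed pings add Gaussian positional noise whose per-ping scale is the
  reported horizontal accuracy rescaled so its median equals
  ``accuracy_noise_sd``; a configurable fraction of "duplicate devices"
  replicate ~90% of a host device's pings exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .geometry import LocalProjection, haversine_m

__all__ = ["CityConfig", "CityConfigError", "SyntheticCity", "GroundTruth",
           "generate_city", "generate_traces", "true_colocation_events"]

_EPOCH_BASE = 1_700_000_000 - (1_700_000_000 % 86400)  # a UTC midnight
_ACCURACY_MEDIAN_M = 15.0
_POI_NAICS = ["722511", "722513", "722515", "813110", "711211", "445110"]
_POI_NAICS_W = [0.30, 0.20, 0.15, 0.15, 0.05, 0.15]


class CityConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class CityConfig:
    """Study conditions for one synthetic city.

    Defaults describe a mid-sized city: 2,000 devices observed for 30 days,
    25 one-km^2 tracts, rents log-normal around exp(7.3) ~ $1,480/month with
    half the log-rent variance at the tract level, and a moderate SES
    homophily in venue choice.
    """

    n_individuals: int = 2000
    n_tracts: int = 25
    tract_layout: str = "grid"  # or "voronoi"
    rent_lognormal_mu: float = 7.3     # log USD/month
    rent_lognormal_sigma: float = 0.5
    tract_ses_autocorrelation: float = 0.5  # share of rent variance at tract level
    n_pois: int = 120
    n_hubs: int = 6
    hub_placement: str = "embedded"  # "bridging" | "embedded" | "random"
    venue_homophily: float = 1.0     # >= 0; strength of SES matching in venue choice
    pings_per_day: float = 24.0
    n_days: int = 30
    accuracy_noise_sd: float = 15.0  # metres; 0 disables positional noise
    night_window: tuple = (18, 9)    # local clock hours [start, end)
    timezone_offset: float = -6.0    # hours relative to UTC
    seed: int = 0
    # geometry and schedule plumbing
    duplicate_device_frac: float = 0.02
    tract_side_m: float = 1000.0
    hub_size_m: float = 300.0
    poi_size_m: float = 40.0
    poi_in_hub_frac: float = 0.8
    visits_per_day: int = 2
    pings_per_visit: int = 3
    visit_duration_min: float = 60.0
    distance_scale_m: float = 1500.0  # softmax distance scale in venue choice
    vacant_property_frac: float = 0.15
    anchor_lat: float = 38.0
    anchor_lon: float = -95.0

    def __post_init__(self):
        for name in ("n_individuals", "n_tracts", "n_pois", "n_hubs",
                     "n_days", "visits_per_day", "pings_per_visit"):
            if int(getattr(self, name)) < 1:
                raise CityConfigError(f"{name} must be >= 1")
        for name in ("tract_ses_autocorrelation", "poi_in_hub_frac",
                     "duplicate_device_frac", "vacant_property_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CityConfigError(f"{name} must be in [0, 1]")
        for name in ("venue_homophily", "accuracy_noise_sd"):
            if getattr(self, name) < 0:
                raise CityConfigError(f"{name} must be >= 0")
        for name in ("rent_lognormal_sigma", "pings_per_day", "tract_side_m",
                     "hub_size_m", "poi_size_m", "visit_duration_min",
                     "distance_scale_m"):
            if getattr(self, name) <= 0:
                raise CityConfigError(f"{name} must be > 0")
        if self.tract_layout not in ("grid", "voronoi"):
            raise CityConfigError(f"tract_layout must be 'grid' or 'voronoi'")
        if self.hub_placement not in ("bridging", "embedded", "random"):
            raise CityConfigError(
                "hub_placement must be 'bridging', 'embedded' or 'random'")
        s, e = self.night_window
        if not (0 <= s < 24 and 0 <= e < 24 and s != e):
            raise CityConfigError("night_window hours must be distinct and in [0, 24)")

    def with_(self, **kw) -> "CityConfig":
        return replace(self, **kw)

    @property
    def epoch_base(self) -> int:
        """Epoch second of local midnight preceding day 0."""
        return int(_EPOCH_BASE - self.timezone_offset * 3600)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must infer."""

    individuals: pd.DataFrame      # user_id, home_lat, home_lon, ses, ses_z, tract_id
    venues: pd.DataFrame           # poi_id, lat, lon, ses_z, target_ses, naics, hub_id
    duplicates: dict               # clone user_id -> host user_id
    true_pings: pd.DataFrame | None = None  # noiseless positions per emitted ping
    events: pd.DataFrame | None = None      # true co-location events (real devices)


@dataclass
class SyntheticCity:
    config: CityConfig
    projection: LocalProjection
    boundary: shapely.Geometry              # city rectangle, lon/lat
    individuals: pd.DataFrame               # ground-truth individual table
    tracts: list                            # [{'id', 'kind', 'geometry', 'props'}]
    pois: list
    hubs: list
    roads: list
    registry: pd.DataFrame
    ground_truth: GroundTruth

    def layer_frames(self):
        """Hub/POI centroid tables used by bridging and annotation."""
        hub_df = pd.DataFrame(
            [{"hub_id": h["id"], "lat": h["geometry"].centroid.y,
              "lon": h["geometry"].centroid.x} for h in self.hubs])
        return hub_df


def _tract_polygons(cfg: CityConfig, rng) -> tuple[list, float, float]:
    """Tract polygons in local metres; returns (polys, width, height)."""
    n = cfg.n_tracts
    if cfg.tract_layout == "grid":
        rows = max(1, int(math.floor(math.sqrt(n))))
        while n % rows:
            rows -= 1
        cols = n // rows
        w, h = cols * cfg.tract_side_m, rows * cfg.tract_side_m
        polys = [box(c * cfg.tract_side_m, r * cfg.tract_side_m,
                     (c + 1) * cfg.tract_side_m, (r + 1) * cfg.tract_side_m)
                 for r in range(rows) for c in range(cols)]
        return polys, w, h
    side = math.sqrt(n) * cfg.tract_side_m
    rect = box(0, 0, side, side)
    pts = MultiPoint([Point(rng.uniform(0, side), rng.uniform(0, side))
                      for _ in range(n)])
    cells = voronoi_diagram(pts, envelope=rect)
    polys = [cell.intersection(rect) for cell in cells.geoms]
    # voronoi_diagram returns cells in arbitrary order; sort by seed match
    order = []
    for p in pts.geoms:
        for i, cell in enumerate(polys):
            if cell.covers(p):
                order.append(i)
                break
    polys = [polys[i] for i in order]
    return polys, side, side


def _sample_in_polygon(poly, rng, size):
    """Uniform points inside a polygon by bounding-box rejection."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((size, 2))
    got = 0
    while got < size:
        m = max(32, 2 * (size - got))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(poly, xs, ys)
        take = min(int(ok.sum()), size - got)
        out[got:got + take, 0] = xs[ok][:take]
        out[got:got + take, 1] = ys[ok][:take]
        got += take
    return out


def _place_hubs(cfg: CityConfig, tract_polys, tract_z, width, height, rng):
    """Hub centre points (local metres) under the configured placement."""
    K = cfg.n_hubs
    if cfg.hub_placement == "random":
        return np.column_stack([rng.uniform(0, width, K), rng.uniform(0, height, K)])
    if cfg.hub_placement == "embedded":
        # centre hubs inside tracts, spread evenly over the tract list
        idx = np.linspace(0, len(tract_polys) - 1, K).round().astype(int)
        idx = np.unique(idx)
        while idx.size < K:  # more hubs than tracts: wrap around
            idx = np.r_[idx, idx[: K - idx.size]]
        return np.array([[tract_polys[i].centroid.x, tract_polys[i].centroid.y]
                         for i in idx[:K]])
    # bridging: midpoints of shared boundaries between SES-dissimilar tracts
    pairs = []
    for a in range(len(tract_polys)):
        for b in range(a + 1, len(tract_polys)):
            inter = tract_polys[a].intersection(tract_polys[b])
            if inter.length > 0:  # shared edge, not just a corner
                pairs.append((abs(tract_z[a] - tract_z[b]), a, b, inter))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    centres, used = [], set()
    for gap, a, b, inter in pairs:
        if len(centres) == K:
            break
        if a in used and b in used:
            continue
        c = inter.centroid
        centres.append([c.x, c.y])
        used.update((a, b))
    i = 0
    while len(centres) < K and pairs:  # few tracts: reuse best boundaries
        c = pairs[i % len(pairs)][3].centroid
        centres.append([c.x + 10.0 * (i + 1), c.y])
        i += 1
    return np.asarray(centres)


def generate_city(config: CityConfig) -> SyntheticCity:
    """Build the static city: tracts, homes, rents, POIs, hubs, registry.

    All randomness flows from ``config.seed``; repeated calls with the same
    config are byte-identical.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    proj = LocalProjection(cfg.anchor_lat, cfg.anchor_lon)

    tract_polys, width, height = _tract_polygons(cfg, rng)
    tract_z = rng.standard_normal(cfg.n_tracts)

    # individuals: tract assignment, home point, rent
    tract_of = rng.integers(0, cfg.n_tracts, cfg.n_individuals)
    homes_xy = np.empty((cfg.n_individuals, 2))
    for t in range(cfg.n_tracts):
        members = np.flatnonzero(tract_of == t)
        if members.size:
            homes_xy[members] = _sample_in_polygon(tract_polys[t], rng, members.size)
    rho = cfg.tract_ses_autocorrelation
    z_ind = (np.sqrt(rho) * tract_z[tract_of]
             + np.sqrt(1.0 - rho) * rng.standard_normal(cfg.n_individuals))
    rent = np.exp(cfg.rent_lognormal_mu + cfg.rent_lognormal_sigma * z_ind)
    home_lat, home_lon = proj.to_latlon(homes_xy[:, 0], homes_xy[:, 1])
    user_ids = np.array([f"u{i:06d}" for i in range(cfg.n_individuals)])
    tract_ids = np.array([f"t{t:04d}" for t in range(cfg.n_tracts)])

    individuals = pd.DataFrame({
        "user_id": user_ids,
        "home_lat": home_lat,
        "home_lon": home_lon,
        "ses": rent,
        "ses_z": z_ind,
        "tract_id": tract_ids[tract_of],
    }).set_index("user_id")

    # hubs and POIs
    hub_xy = _place_hubs(cfg, tract_polys, tract_z, width, height, rng)
    half_h = cfg.hub_size_m / 2.0
    city_rect = box(0, 0, width, height)
    hub_polys = [box(x - half_h, y - half_h, x + half_h, y + half_h)
                 .intersection(city_rect) for x, y in hub_xy]

    n_in_hub = int(round(cfg.poi_in_hub_frac * cfg.n_pois))
    poi_xy = np.empty((cfg.n_pois, 2))
    poi_hub = np.full(cfg.n_pois, "", dtype=object)
    for i in range(n_in_hub):
        h = i % cfg.n_hubs
        inset = shapely.buffer(hub_polys[h], -cfg.poi_size_m)
        target = inset if not inset.is_empty else hub_polys[h]
        poi_xy[i] = _sample_in_polygon(target, rng, 1)[0]
        poi_hub[i] = f"h{h:03d}"
    if cfg.n_pois > n_in_hub:
        poi_xy[n_in_hub:, 0] = rng.uniform(0, width, cfg.n_pois - n_in_hub)
        poi_xy[n_in_hub:, 1] = rng.uniform(0, height, cfg.n_pois - n_in_hub)
    poi_z = rng.standard_normal(cfg.n_pois)
    poi_naics = rng.choice(_POI_NAICS, size=cfg.n_pois, p=_POI_NAICS_W)
    half_p = cfg.poi_size_m / 2.0
    poi_polys = [box(x - half_p, y - half_p, x + half_p, y + half_p)
                 for x, y in poi_xy]
    poi_lat, poi_lon = proj.to_latlon(poi_xy[:, 0], poi_xy[:, 1])

    venues = pd.DataFrame({
        "poi_id": [f"p{i:04d}" for i in range(cfg.n_pois)],
        "lat": poi_lat,
        "lon": poi_lon,
        "ses_z": poi_z,
        "target_ses": np.exp(cfg.rent_lognormal_mu + cfg.rent_lognormal_sigma * poi_z),
        "naics": poi_naics,
        "hub_id": poi_hub,
    }).set_index("poi_id")

    # property registry: each home is a property, plus vacant properties
    n_vac = int(round(cfg.vacant_property_frac * cfg.n_individuals))
    vac_xy = np.column_stack([rng.uniform(0, width, n_vac),
                              rng.uniform(0, height, n_vac)])
    vac_lat, vac_lon = proj.to_latlon(vac_xy[:, 0], vac_xy[:, 1])
    vac_rent = np.exp(cfg.rent_lognormal_mu
                      + cfg.rent_lognormal_sigma * rng.standard_normal(n_vac))
    vac_tract = np.full(n_vac, -1)
    for t in range(cfg.n_tracts):
        inside = shapely.contains_xy(tract_polys[t], vac_xy[:, 0], vac_xy[:, 1])
        vac_tract[inside & (vac_tract < 0)] = t
    vac_tract[vac_tract < 0] = 0  # boundary rounding: assign to tract 0
    # CBGs are identified with tracts synthetically; income ~ 40x tract-level rent
    tract_income = 40.0 * np.exp(cfg.rent_lognormal_mu
                                 + cfg.rent_lognormal_sigma * np.sqrt(rho) * tract_z)
    registry = pd.DataFrame({
        "property_id": ([f"r{i:06d}" for i in range(cfg.n_individuals)]
                        + [f"v{i:06d}" for i in range(n_vac)]),
        "lat": np.r_[home_lat, vac_lat],
        "lon": np.r_[home_lon, vac_lon],
        "rent_usd_month": np.r_[rent, vac_rent],
        "cbg_id": np.r_[tract_ids[tract_of], tract_ids[vac_tract]],
        "cbg_median_income_usd": np.r_[tract_income[tract_of],
                                       tract_income[vac_tract]],
    })

    def feat(fid, kind, geom_m, **props):
        return {"id": fid, "kind": kind,
                "geometry": proj.unproject_geometry(geom_m), "props": props}

    tracts = [feat(tract_ids[t], "tract", tract_polys[t], ses_level=float(tract_z[t]))
              for t in range(cfg.n_tracts)]
    pois = [feat(pid, "poi", poi_polys[i], naics=str(poi_naics[i]),
                 target_ses=float(venues["target_ses"].iloc[i]))
            for i, pid in enumerate(venues.index)]
    hubs = [feat(f"h{h:03d}", "hub", hub_polys[h], naics="531120")
            for h in range(cfg.n_hubs)]
    road_lines = shapely.union_all([p.boundary for p in tract_polys])
    road_geoms = (list(road_lines.geoms)
                  if road_lines.geom_type == "MultiLineString" else [road_lines])
    roads = [feat(f"rd{i:04d}", "road", g, mtfcc="S1400")
             for i, g in enumerate(road_geoms)]

    gt = GroundTruth(individuals=individuals.copy(), venues=venues, duplicates={})
    return SyntheticCity(config=cfg, projection=proj,
                         boundary=proj.unproject_geometry(city_rect),
                         individuals=individuals, tracts=tracts, pois=pois,
                         hubs=hubs, roads=roads, registry=registry,
                         ground_truth=gt)


def _night_hours(window) -> np.ndarray:
    s, e = window
    if s < e:
        return np.arange(s, e)
    return np.r_[np.arange(s, 24), np.arange(0, e)]


def generate_traces(city: SyntheticCity, config: CityConfig | None = None,
                    compute_truth: bool = True,
                    truth_thresholds=(50.0, 5.0)) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Emit the observed ping table (and, optionally, true co-location events).

    Returns ``(pings, events)``.  ``pings`` has columns user_id, timestamp_s,
    lat, lon, accuracy_m, sorted by (timestamp_s, user_id).  ``events`` are
    the ground-truth path crossings among real (non-duplicate) devices
    computed from noiseless positions with distance/time thresholds
    ``truth_thresholds`` (metres, minutes) and the episode-collapse rule.
    The generator stores both on ``city.ground_truth``.
    """
    cfg = config or city.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    proj = city.projection
    n = cfg.n_individuals
    ind = city.individuals
    home_xy = np.column_stack(proj.to_xy(ind["home_lat"].to_numpy(),
                                         ind["home_lon"].to_numpy()))
    venues = city.ground_truth.venues
    poi_xy = np.column_stack(proj.to_xy(venues["lat"].to_numpy(),
                                        venues["lon"].to_numpy()))
    z_i = ind["ses_z"].to_numpy()
    z_v = venues["ses_z"].to_numpy()

    # static softmax utilities: - distance/scale - homophily * |z_v - z_i|
    d_iv = np.sqrt(((home_xy[:, None, :] - poi_xy[None, :, :]) ** 2).sum(-1))
    util = (-d_iv / cfg.distance_scale_m
            - cfg.venue_homophily * np.abs(z_v[None, :] - z_i[:, None]))

    night_h = _night_hours(cfg.night_window)
    n_night = night_h.size
    n_day_pings = cfg.visits_per_day * cfg.pings_per_visit
    keep_p = min(1.0, cfg.pings_per_day / (n_night + n_day_pings))
    dur_s = cfg.visit_duration_min * 60.0
    day_lo, day_hi = 9.0 * 3600, 18.0 * 3600 - dur_s

    rows_t, rows_user, rows_x, rows_y, rows_kind, rows_venue = [], [], [], [], [], []
    for d in range(cfg.n_days):
        base = d * 86400.0
        # night pings: one candidate per whole night hour, jittered in-hour
        t_night = (base + night_h[None, :] * 3600.0
                   + rng.uniform(0, 3600.0, (n, n_night)))
        rows_t.append(t_night.ravel())
        rows_user.append(np.repeat(np.arange(n), n_night))
        rows_x.append(np.repeat(home_xy[:, 0], n_night))
        rows_y.append(np.repeat(home_xy[:, 1], n_night))
        rows_kind.append(np.zeros(n * n_night, dtype=np.int8))
        rows_venue.append(np.full(n * n_night, -1, dtype=np.int32))
        # day visits: softmax venue choice via the Gumbel-max trick
        for v in range(cfg.visits_per_day):
            g = rng.gumbel(size=(n, cfg.n_pois))
            choice = np.argmax(util + g, axis=1)
            start = base + rng.uniform(day_lo, max(day_lo + 1.0, day_hi), n)
            offs = (np.arange(cfg.pings_per_visit) + 0.5) * dur_s / cfg.pings_per_visit
            t_vis = start[:, None] + offs[None, :]
            rows_t.append(t_vis.ravel())
            rows_user.append(np.repeat(np.arange(n), cfg.pings_per_visit))
            rows_x.append(np.repeat(poi_xy[choice, 0], cfg.pings_per_visit))
            rows_y.append(np.repeat(poi_xy[choice, 1], cfg.pings_per_visit))
            rows_kind.append(np.ones(n * cfg.pings_per_visit, dtype=np.int8))
            rows_venue.append(np.repeat(choice.astype(np.int32), cfg.pings_per_visit))

    t_local = np.concatenate(rows_t)
    user_ix = np.concatenate(rows_user)
    true_x = np.concatenate(rows_x)
    true_y = np.concatenate(rows_y)
    kind = np.concatenate(rows_kind)
    venue_ix = np.concatenate(rows_venue)

    if keep_p < 1.0:
        keep = rng.random(t_local.size) < keep_p
        t_local, user_ix, true_x, true_y, kind, venue_ix = (
            a[keep] for a in (t_local, user_ix, true_x, true_y, kind, venue_ix))

    t_epoch = np.floor(t_local).astype(np.int64) + cfg.epoch_base

    # reported accuracy and matched positional noise
    acc = np.exp(np.log(_ACCURACY_MEDIAN_M) + 0.8 * rng.standard_normal(t_local.size))
    noise_sd = cfg.accuracy_noise_sd * (acc / _ACCURACY_MEDIAN_M)
    obs_x = true_x + noise_sd * rng.standard_normal(t_local.size)
    obs_y = true_y + noise_sd * rng.standard_normal(t_local.size)
    lat, lon = proj.to_latlon(obs_x, obs_y)
    uid = ind.index.to_numpy()

    pings = pd.DataFrame({
        "user_id": uid[user_ix],
        "timestamp_s": t_epoch,
        "lat": lat,
        "lon": lon,
        "accuracy_m": np.round(acc, 1),
    })

    # duplicate devices: clones replicate ~90% of a host's pings exactly
    duplicates = {}
    n_dup = int(round(cfg.duplicate_device_frac * n))
    if n_dup:
        hosts = rng.choice(n, size=n_dup, replace=False)
        clones = []
        for h in hosts:
            mask = (user_ix == h) & (rng.random(user_ix.size) < 0.9)
            sub = pings.loc[mask].copy()
            clone_id = "d" + uid[h][1:]
            sub["user_id"] = clone_id
            duplicates[clone_id] = uid[h]
            clones.append(sub)
        pings = pd.concat([pings] + clones, ignore_index=True)

    pings = pings.sort_values(["timestamp_s", "user_id"],
                              kind="mergesort").reset_index(drop=True)

    tlat, tlon = proj.to_latlon(true_x, true_y)
    true_pings = pd.DataFrame({
        "user_id": uid[user_ix],
        "timestamp_s": t_epoch,
        "lat": tlat,
        "lon": tlon,
        "kind": np.where(kind == 1, "venue", "home"),
        "poi_id": np.where(venue_ix >= 0,
                           venues.index.to_numpy()[np.maximum(venue_ix, 0)], ""),
    })

    events = None
    if compute_truth:
        events = true_colocation_events(true_pings, d_m=truth_thresholds[0],
                                        t_min=truth_thresholds[1])
    gt = city.ground_truth
    gt.duplicates = duplicates
    gt.true_pings = true_pings
    gt.events = events
    return pings, events


def true_colocation_events(true_pings: pd.DataFrame, d_m: float = 50.0,
                           t_min: float = 5.0) -> pd.DataFrame:
    """Exhaustive ground-truth co-location events from noiseless positions.

    Scans every pair of pings inside a sliding time window (|dt| < t_min and
    haversine < d_m, strict, distinct users), then collapses consecutive
    qualifying pairs of a dyad separated by less than the time threshold
    into single events whose attributes come from the first qualifying pair.
    This is generator-side truth, kept deliberately simple; the network
    module has its own indexed detector and brute-force oracle.
    """
    t_s = t_min * 60.0
    df = true_pings.sort_values(["timestamp_s", "user_id"],
                                kind="mergesort").reset_index(drop=True)
    t = df["timestamp_s"].to_numpy(dtype=np.int64)
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    users = df["user_id"].to_numpy()
    n = t.size
    ii, jj = [], []
    hi = np.searchsorted(t, t + int(np.ceil(t_s)), side="left")
    for i in range(n):
        j0, j1 = i + 1, hi[i]
        if j1 <= j0:
            continue
        js = np.arange(j0, j1)
        ok = (np.abs(t[js] - t[i]) < t_s) & (users[js] != users[i])
        js = js[ok]
        if js.size:
            d = haversine_m(lat[i], lon[i], lat[js], lon[js])
            js = js[d < d_m]
            ii.extend([i] * js.size)
            jj.extend(js.tolist())
    if not ii:
        return pd.DataFrame(columns=["user_i", "user_j", "k", "t", "lat", "lon"])
    ii = np.asarray(ii)
    jj = np.asarray(jj)
    ua, ub = users[ii], users[jj]
    swap = ua > ub
    ua, ub = np.where(swap, ub, ua), np.where(swap, ua, ub)
    pair_t = np.minimum(t[ii], t[jj])
    pair_lat = 0.5 * (lat[ii] + lat[jj])
    pair_lon = 0.5 * (lon[ii] + lon[jj])
    raw = pd.DataFrame({"user_i": ua, "user_j": ub, "t": pair_t,
                        "lat": pair_lat, "lon": pair_lon})
    raw = raw.sort_values(["user_i", "user_j", "t", "lat", "lon"],
                          kind="mergesort").reset_index(drop=True)
    same = (raw["user_i"].shift() == raw["user_i"]) & \
           (raw["user_j"].shift() == raw["user_j"])
    gap_ok = (raw["t"] - raw["t"].shift()) < t_s
    new_episode = ~(same & gap_ok)
    keep = raw[new_episode].reset_index(drop=True)
    keep["k"] = keep.groupby(["user_i", "user_j"], sort=False).cumcount() + 1
    return keep[["user_i", "user_j", "k", "t", "lat", "lon"]]
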