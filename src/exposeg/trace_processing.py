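"""Home-location inference, SES linking, and user-quality filters.

The home of a device is inferred from stationary night-time positions:
pings are linearly interpolated onto hourly boundaries, hours in the local
night window whose displacement to the next hour is below the stationarity
radius are kept, and the home is the coordinate-wise median of those
positions after requiring stationary hours on enough distinct local dates
and enough concentration around their medoid.  SES is the monthly rent of
the nearest registry property, winsorized at a cap, with percentile-rank
and block-group-income alternatives.

Threshold conventions (fixed for reproducibility): the accuracy filter keeps
pings at exactly the threshold; stationarity is strict (< radius); the
registry link keeps distances at exactly the cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import haversine_m, projection_for

logger = logging.getLogger(__name__)

__all__ = [
    "HomeInferenceParams", "filter_pings", "interpolate_hourly", "infer_home",
    "infer_homes", "link_ses", "apply_registry_filters", "winsorize_ses",
    "alternative_ses", "assign_home_tracts", "build_individuals",
]


@dataclass(frozen=True)
class HomeInferenceParams:
    min_pings: int = 500
    night_start: int = 18   # local clock hour, inclusive
    night_end: int = 9      # local clock hour, exclusive
    stationary_radius_m: float = 50.0
    min_stationary_dates: int = 3
    min_within_radius_frac: float = 0.60

    def __post_init__(self):
        if not 0.0 < self.min_within_radius_frac <= 1.0:
            raise ValueError("min_within_radius_frac must be in (0, 1]")
        if self.stationary_radius_m <= 0:
            raise ValueError("stationary_radius_m must be > 0")


def filter_pings(pings: pd.DataFrame, max_accuracy_m: float = 100.0) -> pd.DataFrame:
    """Drop pings whose reported horizontal accuracy exceeds the threshold.

    Pings at exactly the threshold are kept; row order is preserved.
    """
    kept = pings[pings["accuracy_m"] <= max_accuracy_m]
    logger.info("accuracy filter (<= %.0f m): kept %d / %d pings",
                max_accuracy_m, len(kept), len(pings))
    return kept


def interpolate_hourly(user_pings: pd.DataFrame) -> pd.DataFrame:
    """Linearly interpolate one user's latitude/longitude onto hour boundaries.

    Only hours strictly inside the observed span are produced (no
    extrapolation).  Requires >= 2 pings.
    """
    if len(user_pings) < 2:
        raise ValueError("interpolation needs >= 2 pings")
    df = user_pings.sort_values("timestamp_s", kind="mergesort")
    t = df["timestamp_s"].to_numpy(dtype=np.int64)
    first_hour = int(np.ceil(t[0] / 3600.0))
    last_hour = int(np.floor(t[-1] / 3600.0))
    if last_hour < first_hour:
        return pd.DataFrame(columns=["timestamp_s", "lat", "lon"])
    hours = np.arange(first_hour, last_hour + 1, dtype=np.int64) * 3600
    lat = np.interp(hours, t, df["lat"].to_numpy())
    lon = np.interp(hours, t, df["lon"].to_numpy())
    return pd.DataFrame({"timestamp_s": hours, "lat": lat, "lon": lon})


class HomeResult(NamedTuple):
    home_lat: Optional[float]
    home_lon: Optional[float]
    reason: Optional[str]          # None on success, machine-readable on failure
    n_stationary: int


def _local_hours_dates(t: np.ndarray, tz_offset_h: float):
    local = t + tz_offset_h * 3600.0
    hour = (local // 3600.0) % 24
    date = np.floor(local / 86400.0).astype(np.int64)
    return hour.astype(int), date


def infer_home(hourly: pd.DataFrame, params: HomeInferenceParams,
               tz_offset_h: float = 0.0) -> HomeResult:
    """Infer a home location from hourly positions of one user.

    Selects night-window hours whose displacement to the following hour is
    below the stationarity radius, requires such hours on at least
    ``min_stationary_dates`` distinct local dates and at least
    ``min_within_radius_frac`` of them within the radius of their medoid,
    then returns the coordinate-wise median of the in-radius positions.
    Failure is reported through ``reason``, never an exception.
    """
    if len(hourly) < 2:
        return HomeResult(None, None, "too_few_hours", 0)
    t = hourly["timestamp_s"].to_numpy(dtype=np.int64)
    lat = hourly["lat"].to_numpy()
    lon = hourly["lon"].to_numpy()
    hour, date = _local_hours_dates(t, tz_offset_h)

    s, e = params.night_start, params.night_end
    night = (hour >= s) & (hour < e) if s < e else (hour >= s) | (hour < e)
    step = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    stationary = np.zeros(len(hourly), dtype=bool)
    stationary[:-1] = night[:-1] & (step < params.stationary_radius_m)

    idx = np.flatnonzero(stationary)
    if idx.size == 0:
        return HomeResult(None, None, "no_stationary_hours", 0)
    if np.unique(date[idx]).size < params.min_stationary_dates:
        return HomeResult(None, None, "min_stationary_dates", int(idx.size))

    plat, plon = lat[idx], lon[idx]
    # medoid: stationary point minimizing total distance to the others
    d = haversine_m(plat[:, None], plon[:, None], plat[None, :], plon[None, :])
    medoid = int(np.argmin(d.sum(axis=1)))
    within = d[medoid] < params.stationary_radius_m
    if within.mean() < params.min_within_radius_frac:
        return HomeResult(None, None, "min_within_radius_frac", int(idx.size))
    return HomeResult(float(np.median(plat[within])), float(np.median(plon[within])),
                      None, int(idx.size))


def infer_homes(pings: pd.DataFrame, params: HomeInferenceParams = HomeInferenceParams(),
                tz_offset_h: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run home inference for every user in a ping table.

    Returns ``(individuals, failures)``: individuals indexed by user_id with
    home_lat/home_lon/n_pings, and one (user_id, reason) row per rejected
    user.
    """
    rows, fails = [], []
    for user_id, grp in pings.groupby("user_id", sort=True):
        if len(grp) < params.min_pings:
            fails.append((user_id, "min_pings"))
            continue
        try:
            hourly = interpolate_hourly(grp)
        except ValueError:
            fails.append((user_id, "too_few_pings_for_interpolation"))
            continue
        res = infer_home(hourly, params, tz_offset_h)
        if res.reason is None:
            rows.append((user_id, res.home_lat, res.home_lon, len(grp),
                         res.n_stationary))
        else:
            fails.append((user_id, res.reason))
    individuals = pd.DataFrame(
        rows, columns=["user_id", "home_lat", "home_lon", "n_pings",
                       "n_stationary_hours"]).set_index("user_id")
    failures = pd.DataFrame(fails, columns=["user_id", "reason"])
    logger.info("home inference: %d users inferred, %d rejected",
                len(individuals), len(failures))
    return individuals, failures


def link_ses(individuals: pd.DataFrame, registry: pd.DataFrame,
             max_link_distance_m: float = 100.0) -> pd.DataFrame:
    """Link each home to the nearest registry property and take its rent.

    Individuals whose nearest property lies beyond ``max_link_distance_m``
    (strictly; distances exactly at the cap are kept) are dropped.  Adds
    ``ses`` (USD/month), ``property_id``, ``link_distance_m`` and, when the
    registry carries them, ``cbg_id`` / ``cbg_median_income_usd``.
    """
    if len(registry) == 0:
        raise ValueError("property registry is empty")
    proj = projection_for(registry["lat"], registry["lon"])
    rx, ry = proj.to_xy(registry["lat"].to_numpy(), registry["lon"].to_numpy())
    hx, hy = proj.to_xy(individuals["home_lat"].to_numpy(),
                        individuals["home_lon"].to_numpy())
    tree = cKDTree(np.column_stack([rx, ry]))
    _, nearest = tree.query(np.column_stack([hx, hy]), k=1)
    dist = haversine_m(individuals["home_lat"].to_numpy(),
                       individuals["home_lon"].to_numpy(),
                       registry["lat"].to_numpy()[nearest],
                       registry["lon"].to_numpy()[nearest])
    out = individuals.copy()
    out["property_id"] = registry["property_id"].to_numpy()[nearest]
    out["ses"] = registry["rent_usd_month"].to_numpy()[nearest]
    out["link_distance_m"] = dist
    for col in ("cbg_id", "cbg_median_income_usd"):
        if col in registry.columns:
            out[col] = registry[col].to_numpy()[nearest]
    kept = out[out["link_distance_m"] <= max_link_distance_m]
    logger.info("SES link: %d / %d homes within %.0f m of a property",
                len(kept), len(out), max_link_distance_m)
    return kept


def apply_registry_filters(individuals: pd.DataFrame,
                           max_users_per_property: int = 10) -> pd.DataFrame:
    """Remaining user-quality filters on the linked individual table.

    (1) users whose home latitude AND longitude are float-identical to
    another user's are all removed (duplicate-home artifact; identity
    precision is exact float equality, a documented interpretation);
    (6) users linked to a property shared by more than
    ``max_users_per_property`` users are removed (registry data error).
    """
    out = individuals
    dup_home = out.duplicated(["home_lat", "home_lon"], keep=False)
    if dup_home.any():
        logger.info("removed %d users with float-identical home coordinates",
                    int(dup_home.sum()))
        out = out[~dup_home]
    counts = out.groupby("property_id")["ses"].transform("size")
    crowded = counts > max_users_per_property
    if crowded.any():
        logger.info("removed %d users on properties with > %d linked users",
                    int(crowded.sum()), max_users_per_property)
        out = out[~crowded]
    return out


def winsorize_ses(values, cap: float = 20_000.0):
    """Upper-winsorize rents at the cap (no lower winsorization).

    Accepts a Series/array (returns same) or an individual table with an
    ``ses`` column (returns the table with ses capped).
    """
    if isinstance(values, pd.DataFrame):
        out = values.copy()
        out["ses"] = np.minimum(out["ses"].to_numpy(dtype=float), cap)
        return out
    return np.minimum(np.asarray(values, dtype=float), cap)


def alternative_ses(individuals: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Attach an alternative SES measure.

    ``percentile``: average-rank percentiles of rent scaled to [0, 100]
    (ties share the mean rank; percentile = (rank - 0.5) / n * 100).
    ``cbg_income``: the block-group median household income carried over
    from the registry link.
    """
    out = individuals.copy()
    if mode == "percentile":
        ranks = out["ses"].rank(method="average")
        out["ses_alt_percentile"] = (ranks - 0.5) / len(out) * 100.0
    elif mode == "cbg_income":
        if "cbg_median_income_usd" not in out.columns:
            raise ValueError("cbg_income mode needs cbg_median_income_usd "
                             "from the registry link")
        out["ses_alt_cbg_income"] = out["cbg_median_income_usd"]
    else:
        raise ValueError(f"unknown alternative SES mode: {mode!r}")
    return out


def assign_home_tracts(individuals: pd.DataFrame, tract_layer) -> pd.DataFrame:
    """Attach ``home_tract_id`` by point-in-polygon of the home location."""
    from .annotation import locate_points  # late import: avoids cycle at module load
    ids = locate_points(individuals["home_lat"].to_numpy(),
                        individuals["home_lon"].to_numpy(), tract_layer)
    out = individuals.copy()
    out["home_tract_id"] = ids
    return out


def build_individuals(pings: pd.DataFrame, registry: pd.DataFrame,
                      tract_layer=None,
                      params: HomeInferenceParams = HomeInferenceParams(),
                      tz_offset_h: float = 0.0,
                      max_accuracy_m: float = 100.0,
                      max_link_distance_m: float = 100.0,
                      winsor_cap: float = 20_000.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full trace-processing cascade: accuracy filter, home inference, SES
    link, registry filters, winsorization, alternatives, tract assignment.

    Returns ``(individuals, failures)``.
    """
    pings = filter_pings(pings, max_accuracy_m)
    homes, failures = infer_homes(pings, params, tz_offset_h)
    ind = link_ses(homes, registry, max_link_distance_m)
    ind = apply_registry_filters(ind)
    ind = winsorize_ses(ind, winsor_cap)
    ind = alternative_ses(ind, "percentile")
    if "cbg_median_income_usd" in ind.columns:
        ind = alternative_ses(ind, "cbg_income")
    if tract_layer is not None:
        ind = assign_home_tracts(ind, tract_layer)
    return ind, failures
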