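"""Space-time path-crossing detection and the exposure multigraph.

Two devices cross paths when a ping of each lies within D metres
(great-circle, strict <) and T minutes (strict <) of the other.  Each edge
carries the minimum of the two ping timestamps and the average of the two
ping coordinates.  Consecutive qualifying ping pairs of the same dyad whose
inter-pair gaps are below T collapse into a single exposure event (attributes
from the first qualifying pair); the raw ping-pair multigraph is available
with ``collapse=False``.

The production detector buckets pings into windows of width T and runs a k-d
tree radius query on locally projected coordinates per adjacent bucket pair,
then refines every candidate with the exact haversine/time predicate: worst
case O(n^2) when all pings share one place-time, O(n log n + candidates)
otherwise.  ``find_path_crossings_bruteforce`` evaluates the identical
predicate over all pairs and is the test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import haversine_m, projection_for

logger = logging.getLogger(__name__)

__all__ = ["Thresholds", "dedupe_duplicate_users", "find_path_crossings",
           "find_path_crossings_bruteforce", "tie_strength",
           "tie_strength_bins", "stratify_by_tie_strength", "TIE_BINS"]

EDGE_COLUMNS = ["user_i", "user_j", "k", "t", "lat", "lon"]
TIE_BINS = ("1", "2", "3", "4", "5+")


@dataclass(frozen=True)
class Thresholds:
    """Path-crossing thresholds: D metres, T minutes (both strict)."""

    D: float = 50.0
    T: float = 5.0

    def __post_init__(self):
        if self.D <= 0 or self.T <= 0:
            raise ValueError("thresholds D and T must be > 0")

    @property
    def t_seconds(self) -> float:
        return self.T * 60.0


def dedupe_duplicate_users(pings: pd.DataFrame,
                           match_frac: float = 0.8) -> tuple[pd.DataFrame, list]:
    """Remove duplicate devices.

    For each ordered user pair (u, v), u is removed when strictly more than
    ``match_frac`` of u's pings have latitude, longitude and timestamp exactly
    identical to some ping of v.  When u and v flag each other, the user with
    fewer pings is removed; at equal counts, the lexicographically larger id.
    Comparisons are a single pass over the original table (no cascading).
    """
    n_pings = pings.groupby("user_id").size()
    key = pings[["user_id", "timestamp_s", "lat", "lon"]].drop_duplicates()
    merged = key.merge(key, on=["timestamp_s", "lat", "lon"])
    merged = merged[merged["user_id_x"] != merged["user_id_y"]]
    shared = (merged.groupby(["user_id_x", "user_id_y"]).size()
              if len(merged) else pd.Series(dtype=int))
    removed = set()
    flagged = {}
    for (u, v), c in shared.items():
        if c > match_frac * n_pings[u]:
            flagged[(u, v)] = True
    for (u, v) in flagged:
        if (v, u) in flagged:
            if n_pings[u] != n_pings[v]:
                removed.add(u if n_pings[u] < n_pings[v] else v)
            else:
                removed.add(max(u, v))
        else:
            removed.add(u)
    removed_ids = sorted(removed)
    out = pings[~pings["user_id"].isin(removed)]
    logger.info("de-duplication: removed %d of %d users",
                len(removed_ids), n_pings.size)
    return out, removed_ids


def _clean_pings(pings: pd.DataFrame) -> pd.DataFrame:
    finite = (np.isfinite(pings["lat"].to_numpy(dtype=float))
              & np.isfinite(pings["lon"].to_numpy(dtype=float)))
    if not finite.all():
        logger.warning("rejected %d pings with non-finite coordinates",
                       int((~finite).sum()))
    out = pings[finite]
    # canonical order makes detection invariant to input row order
    return out.sort_values(["timestamp_s", "user_id", "lat", "lon"],
                           kind="mergesort").reset_index(drop=True)


def _pairs_to_edges(users, t, lat, lon, ii, jj, thresholds: Thresholds,
                    collapse: bool) -> pd.DataFrame:
    """Shared edge assembly: orient dyads, timestamp/locate pairs, collapse."""
    if len(ii) == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    ii = np.asarray(ii)
    jj = np.asarray(jj)
    ua, ub = users[ii], users[jj]
    swap = ua > ub
    ua, ub = np.where(swap, ub, ua), np.where(swap, ua, ub)
    raw = pd.DataFrame({
        "user_i": ua,
        "user_j": ub,
        "t": np.minimum(t[ii], t[jj]),
        "lat": 0.5 * (lat[ii] + lat[jj]),
        "lon": 0.5 * (lon[ii] + lon[jj]),
    })
    raw = raw.sort_values(["user_i", "user_j", "t", "lat", "lon"],
                          kind="mergesort").reset_index(drop=True)
    if collapse:
        same = (raw["user_i"].shift() == raw["user_i"]) & \
               (raw["user_j"].shift() == raw["user_j"])
        gap_ok = (raw["t"] - raw["t"].shift()) < thresholds.t_seconds
        raw = raw[~(same & gap_ok)].reset_index(drop=True)
    raw["k"] = raw.groupby(["user_i", "user_j"], sort=False).cumcount() + 1
    return raw[EDGE_COLUMNS]


def find_path_crossings(pings: pd.DataFrame,
                        thresholds: Thresholds = Thresholds(),
                        collapse: bool = True) -> pd.DataFrame:
    """All path-crossing events, via time buckets + k-d tree radius queries.

    Pings are sorted internally; rows with non-finite coordinates are
    rejected with a log entry.  Candidate pairs come from a projected-metre
    k-d tree with a conservatively inflated radius and are then refined with
    the exact strict haversine-distance and time predicate, so the result is
    identical to the brute-force oracle.
    """
    df = _clean_pings(pings)
    n = len(df)
    if n < 2:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    users = df["user_id"].to_numpy()
    t = df["timestamp_s"].to_numpy(dtype=np.int64)
    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    proj = projection_for(lat, lon)
    x, y = proj.to_xy(lat, lon)
    xy = np.column_stack([x, y])

    t_s = thresholds.t_seconds
    bucket = ((t - t[0]) // int(t_s)).astype(np.int64)
    # 2% radius inflation + 1 m covers equirectangular distortion at the
    # city extents this package targets (< ~100 km, mid latitudes)
    r = thresholds.D * 1.02 + 1.0

    cand_i, cand_j = [], []
    uniq = np.unique(bucket)
    starts = np.searchsorted(bucket, uniq, side="left")
    ends = np.searchsorted(bucket, uniq, side="right")
    span = dict(zip(uniq.tolist(), zip(starts.tolist(), ends.tolist())))
    for b in uniq.tolist():
        a0, a1 = span[b]
        idx_a = np.arange(a0, a1)
        tree_a = cKDTree(xy[a0:a1])
        within = tree_a.query_pairs(r, output_type="ndarray")
        if within.size:
            cand_i.append(idx_a[within[:, 0]])
            cand_j.append(idx_a[within[:, 1]])
        if b + 1 in span:
            b0, b1 = span[b + 1]
            idx_b = np.arange(b0, b1)
            hits = tree_a.query_ball_point(xy[b0:b1], r)
            lens = np.fromiter((len(h) for h in hits), dtype=np.int64,
                               count=len(hits))
            if lens.sum():
                cand_j.append(np.repeat(idx_b, lens))
                cand_i.append(idx_a[np.concatenate(
                    [np.asarray(h, dtype=np.int64) for h in hits if h])])
    if not cand_i:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    ii = np.concatenate(cand_i)
    jj = np.concatenate(cand_j)
    keep = ((np.abs(t[ii] - t[jj]) < t_s)
            & (users[ii] != users[jj])
            & (haversine_m(lat[ii], lon[ii], lat[jj], lon[jj]) < thresholds.D))
    edges = _pairs_to_edges(users, t, lat, lon, ii[keep], jj[keep],
                            thresholds, collapse)
    logger.info("path crossings: %d events from %d pings (D=%.0f m, T=%.0f min)",
                len(edges), n, thresholds.D, thresholds.T)
    return edges


def find_path_crossings_bruteforce(pings: pd.DataFrame,
                                   thresholds: Thresholds = Thresholds(),
                                   collapse: bool = True,
                                   cap: int = 50_000) -> pd.DataFrame:
    """Exhaustive all-pairs detector: the reference oracle.

    Evaluates the strict |dt| < T, haversine < D, distinct-user predicate on
    every ping pair (chunked to bound memory) and applies the identical
    episode-collapse rule.  Refuses inputs above ``cap`` pings.
    """
    df = _clean_pings(pings)
    n = len(df)
    if n > cap:
        raise ValueError(f"brute-force oracle capped at {cap} pings, got {n}")
    if n < 2:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    users = df["user_id"].to_numpy()
    t = df["timestamp_s"].to_numpy(dtype=np.int64)
    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    t_s = thresholds.t_seconds

    ii_all, jj_all = [], []
    chunk = 512
    for a0 in range(0, n - 1, chunk):
        a1 = min(a0 + chunk, n)
        rows = np.arange(a0, a1)
        cols = np.arange(n)
        pair_ok = cols[None, :] > rows[:, None]
        pair_ok &= np.abs(t[cols][None, :] - t[rows][:, None]) < t_s
        pair_ok &= users[cols][None, :] != users[rows][:, None]
        ri, ci = np.nonzero(pair_ok)
        gi, gj = rows[ri], cols[ci]
        if gi.size:
            d = haversine_m(lat[gi], lon[gi], lat[gj], lon[gj])
            sel = d < thresholds.D
            ii_all.append(gi[sel])
            jj_all.append(gj[sel])
    ii = np.concatenate(ii_all) if ii_all else np.array([], dtype=np.int64)
    jj = np.concatenate(jj_all) if jj_all else np.array([], dtype=np.int64)
    return _pairs_to_edges(users, t, lat, lon, ii, jj, thresholds, collapse)


def tie_strength(edges: pd.DataFrame, dyad: tuple) -> int:
    """Number of exposure events between an unordered pair of users."""
    a, b = sorted(map(str, dyad))
    return int(((edges["user_i"] == a) & (edges["user_j"] == b)).sum())


def tie_strength_bins(edges: pd.DataFrame) -> pd.Series:
    """Tie-strength bin ('1'...'4', '5+') of each edge's dyad."""
    counts = edges.groupby(["user_i", "user_j"])["t"].transform("size")
    labels = counts.astype(str).where(counts < 5, "5+")
    return labels.rename("tie_bin")


def stratify_by_tie_strength(edges: pd.DataFrame,
                             bins=TIE_BINS) -> dict[str, pd.DataFrame]:
    """Partition the edge table by the dyad's total exposure count."""
    lab = tie_strength_bins(edges)
    return {b: edges[lab == b] for b in bins}
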