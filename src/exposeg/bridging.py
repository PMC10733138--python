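"""Bridging index: within-nearest-hub-cluster economic diversity.

Residents are clustered by the hub nearest to their home; the index is the
size-weighted average within-cluster Gini of SES divided by the region-wide
Gini:

    index = sum_k |H_k| * Gini(H_k) / (|V_A| * Gini(V_A))

0 means every hub catchment is SES-uniform (no bridging); 1 means every
catchment mirrors the whole region's SES distribution (perfect bridging).
Values slightly above 1 are possible in principle and are not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import haversine_m

__all__ = [
    "gini",
    "assign_nearest_hub",
    "bridging_index",
    "diversity_variant",
    "BridgingResult",
    "HubCluster",
]


def gini(values) -> float:
    """Population Gini index of non-negative values.

    Computed with the sorted identity
    ``G = (2 * sum_i i*x_(i) / (n * sum x)) - (n + 1) / n`` (i = 1..n),
    which equals mean |x_i - x_j| / (2 * mean x) over all ordered pairs
    including self-pairs (the population, uncorrected form).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("gini of an empty set is undefined")
    if np.any(v < 0) or np.any(~np.isfinite(v)):
        raise ValueError("gini requires finite, non-negative values")
    total = v.sum()
    if total == 0.0:
        raise ValueError("gini of an all-zero set is undefined")
    s = np.sort(v)
    n = s.size
    ranks = np.arange(1, n + 1, dtype=float)
    return float(2.0 * np.dot(ranks, s) / (n * total) - (n + 1.0) / n)


def _variance(values) -> float:
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("variance of an empty set is undefined")
    return float(np.var(v))


@dataclass(frozen=True)
class HubCluster:
    hub_id: str
    member_ids: tuple
    diversity: float  # Gini (or variance) of member SES; 0.0 for size < 2

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class BridgingResult:
    index: float
    clusters: list = field(repr=False)
    overall_diversity: float
    n_residents: int
    measure: str = "gini"


def assign_nearest_hub(individuals: pd.DataFrame, hubs: pd.DataFrame) -> pd.Series:
    """Assign each resident the hub with the smallest great-circle distance
    from their home; distance ties break toward the smaller hub id.

    ``individuals`` needs columns ``home_lat``/``home_lon`` (index = user id);
    ``hubs`` needs columns ``hub_id``, ``lat``, ``lon`` (polygon centroids).
    """
    if len(hubs) == 0:
        raise ValueError("no hubs: nearest-hub clustering is undefined")
    hubs = hubs.sort_values("hub_id").reset_index(drop=True)
    d = haversine_m(
        individuals["home_lat"].to_numpy()[:, None],
        individuals["home_lon"].to_numpy()[:, None],
        hubs["lat"].to_numpy()[None, :],
        hubs["lon"].to_numpy()[None, :],
    )
    # argmin takes the first minimum; hubs are sorted by id, so ties resolve
    # to the smaller hub id
    nearest = np.argmin(d, axis=1)
    return pd.Series(hubs["hub_id"].to_numpy()[nearest],
                     index=individuals.index, name="hub_id")


def bridging_index(individuals: pd.DataFrame, hubs: pd.DataFrame,
                   ses_col: str = "ses", measure: str = "gini") -> BridgingResult:
    """Bridging index of a region's residents for a set of hubs.

    Raises if fewer than two residents carry positive SES or if the overall
    diversity is zero (all SES equal), in which case the ratio is undefined.
    """
    if measure not in ("gini", "variance"):
        raise ValueError(f"unknown diversity measure: {measure!r}")
    fn = gini if measure == "gini" else _variance
    ses = individuals[ses_col].to_numpy(dtype=float)
    if len(individuals) < 2:
        raise ValueError("bridging index needs at least 2 residents")
    if measure == "gini" and np.any(ses <= 0):
        raise ValueError("bridging index with Gini requires strictly positive SES")
    overall = fn(ses)
    if overall == 0.0:
        raise ValueError("overall diversity is 0 (all SES equal): "
                         "bridging index undefined")
    assignment = assign_nearest_hub(individuals, hubs)
    clusters = []
    weighted = 0.0
    for hub_id, members in individuals.groupby(assignment, sort=True):
        vals = members[ses_col].to_numpy(dtype=float)
        div = fn(vals) if vals.size >= 2 else 0.0
        clusters.append(HubCluster(str(hub_id), tuple(members.index), div))
        weighted += vals.size * div
    index = weighted / (len(individuals) * overall)
    return BridgingResult(index=float(index), clusters=clusters,
                          overall_diversity=float(overall),
                          n_residents=len(individuals), measure=measure)


def diversity_variant(individuals: pd.DataFrame, hubs: pd.DataFrame,
                      measure: str = "variance",
                      ses_col: str = "ses") -> BridgingResult:
    """Bridging index with an alternative within-cluster diversity measure."""
    return bridging_index(individuals, hubs, ses_col=ses_col, measure=measure)
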