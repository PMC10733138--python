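"""Exposure segregation: naive and attenuation-corrected estimators,
the neighbourhood sorting index, and decompositions.

Exposure segregation of a region is the Pearson correlation between a
resident's SES ``x_i`` (standardized to mean 0, variance 1 within the
region) and the mean SES of their exposure partners.  The naive sample
correlation against observed partner means is downward-biased when partner
sets are small: the observed mean is a noisy estimate of the latent mean.
The corrected estimator fits the random-intercept model

    y_ij = a x_i + b + eps1_i + eps2_ij        (REML)

and reports  a / sqrt(a^2 + Var(eps1)),  the correlation between x_i and
the latent partner mean, which is free of that attenuation.

Partner lists are deduplicated per ego (repeated exposures to the same
person are not upweighted) and an ego never appears in their own partner
list.  Partner SES values are used raw (winsorized rent); only x is
standardized — the correlation is scale-invariant in y.

The neighbourhood sorting index (NSI) is the special case in which everyone
is "exposed" uniformly to their home-tract co-residents: the correlation
between SES and home-tract mean SES (ego included in the tract mean, the
census convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exposure_network import tie_strength_bins
from .inference import BootstrapSpec
from .mixed_model import MixedModelFit, reml_random_intercept

logger = logging.getLogger(__name__)

__all__ = ["EgoRecords", "SegregationEstimate", "build_ego_records",
           "naive_exposure_segregation", "fit_mixed_model",
           "corrected_exposure_segregation", "estimate_exposure_segregation",
           "neighbourhood_sorting_index", "synthetic_tract_network",
           "decompose"]


@dataclass(frozen=True)
class SegregationEstimate:
    value: float
    method: str                      # "naive" | "mixed" | "nsi"
    n_egos: int
    n_obs: int = 0
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    stratum: Optional[str] = None
    note: Optional[str] = None

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.value)


@dataclass
class EgoRecords:
    """Deduplicated ego-partner data for one region (and stratum).

    ``x`` is the standardized ego SES (one per ego); ``y`` holds partner SES
    values concatenated ego by ego with ``sizes`` giving each ego's partner
    count.  ``x_raw`` keeps the unstandardized ego SES for diagnostics.
    """

    ego_ids: np.ndarray
    x: np.ndarray
    x_raw: np.ndarray
    y: np.ndarray
    sizes: np.ndarray
    stratum: Optional[str] = None

    @property
    def n_egos(self) -> int:
        return self.ego_ids.size

    @property
    def n_obs(self) -> int:
        return int(self.sizes.sum())

    def partner_means(self) -> np.ndarray:
        starts = np.r_[0, np.cumsum(self.sizes)[:-1]]
        return np.add.reduceat(self.y, starts) / self.sizes

    def subset(self, ego_idx) -> "EgoRecords":
        """Egos by positional index, with repetition (bootstrap support).
        x is NOT re-standardized: resamples keep the original scaling."""
        starts = np.r_[0, np.cumsum(self.sizes)[:-1]]
        parts = [self.y[starts[i]:starts[i] + self.sizes[i]] for i in ego_idx]
        return EgoRecords(ego_ids=self.ego_ids[ego_idx], x=self.x[ego_idx],
                          x_raw=self.x_raw[ego_idx],
                          y=np.concatenate(parts) if parts else np.empty(0),
                          sizes=self.sizes[ego_idx], stratum=self.stratum)


def build_ego_records(edges: pd.DataFrame, individuals: pd.DataFrame,
                      region_egos=None, ses_col: str = "ses",
                      stratum: Optional[str] = None) -> EgoRecords:
    """Assemble deduplicated ego-partner records from an edge table.

    ``region_egos``: user ids of the region's residents (egos are restricted
    to the region; partners are not — a partner outside the region still
    contributes their SES).  Defaults to everyone in ``individuals``.
    Partners without a known SES are dropped with a log entry.  x is
    standardized to mean 0, variance 1 (ddof 0) over the egos that remain.
    """
    if region_egos is None:
        region_egos = individuals.index
    region_egos = pd.Index(region_egos)
    fwd = edges[["user_i", "user_j"]].to_numpy()
    long = pd.DataFrame({
        "ego": np.r_[fwd[:, 0], fwd[:, 1]],
        "partner": np.r_[fwd[:, 1], fwd[:, 0]],
    })
    long = long[long["ego"].isin(region_egos)]
    long = long.drop_duplicates(["ego", "partner"])
    ses = individuals[ses_col]
    long["y"] = ses.reindex(long["partner"]).to_numpy()
    n_unknown = int(long["y"].isna().sum())
    if n_unknown:
        logger.info("dropped %d partner links without SES", n_unknown)
        long = long.dropna(subset=["y"])
    long = long[long["ego"].isin(ses.dropna().index)]
    if long["ego"].nunique() < 2:
        raise ValueError(
            "fewer than 2 egos with exposures and SES in this region: "
            "segregation is not estimable")
    long = long.sort_values(["ego", "partner"], kind="mergesort")
    sizes = long.groupby("ego", sort=True).size()
    ego_ids = sizes.index.to_numpy()
    x_raw = ses.reindex(ego_ids).to_numpy(dtype=float)
    sd = x_raw.std()
    if sd == 0:
        raise ValueError("ego SES has zero variance: segregation undefined")
    x = (x_raw - x_raw.mean()) / sd
    return EgoRecords(ego_ids=ego_ids, x=x, x_raw=x_raw,
                      y=long["y"].to_numpy(dtype=float),
                      sizes=sizes.to_numpy(), stratum=stratum)


def naive_exposure_segregation(records: EgoRecords) -> SegregationEstimate:
    """Sample Pearson correlation between ego SES and observed partner mean."""
    if records.n_egos < 2:
        return SegregationEstimate(np.nan, "naive", records.n_egos,
                                   records.n_obs, stratum=records.stratum,
                                   note="fewer than 2 egos")
    ymean = records.partner_means()
    if np.ptp(records.x) == 0 or np.ptp(ymean) == 0:
        return SegregationEstimate(np.nan, "naive", records.n_egos,
                                   records.n_obs, stratum=records.stratum,
                                   note="zero variance in x or partner means")
    r = float(np.corrcoef(records.x, ymean)[0, 1])
    return SegregationEstimate(r, "naive", records.n_egos, records.n_obs,
                               stratum=records.stratum)


def fit_mixed_model(records: EgoRecords) -> MixedModelFit:
    """REML fit of the ego-partner random-intercept model."""
    return reml_random_intercept(records.x, records.y, records.sizes)


def corrected_exposure_segregation(fit: MixedModelFit,
                                   stratum: Optional[str] = None) -> SegregationEstimate:
    """Attenuation-corrected exposure segregation  a / sqrt(a^2 + var1).

    The sign follows the slope.  The fully degenerate fit (a = 0 and
    var1 = 0: every latent partner mean identical) returns 0 with a note.
    A non-converged fit withholds the value.
    """
    if not fit.converged or not np.isfinite(fit.a):
        return SegregationEstimate(np.nan, "mixed", fit.n_egos, fit.n_obs,
                                   stratum=stratum, note="REML did not converge")
    if fit.a == 0.0 and fit.var1 == 0.0:
        return SegregationEstimate(0.0, "mixed", fit.n_egos, fit.n_obs,
                                   stratum=stratum,
                                   note="degenerate: a = 0 and Var(eps1) = 0")
    value = fit.a / np.sqrt(fit.a ** 2 + fit.var1)
    note = "Var(eps1) at the 0 boundary" if fit.boundary else None
    return SegregationEstimate(float(value), "mixed", fit.n_egos, fit.n_obs,
                               stratum=stratum, note=note)


def estimate_exposure_segregation(records: EgoRecords, method: str = "mixed",
                                  bootstrap_spec: Optional[BootstrapSpec] = None,
                                  ) -> SegregationEstimate:
    """Point estimate (naive or mixed), optionally with a percentile
    bootstrap CI over egos (the resampling unit is the individual ego)."""
    if method == "naive":
        est = naive_exposure_segregation(records)
    elif method == "mixed":
        est = corrected_exposure_segregation(fit_mixed_model(records),
                                             stratum=records.stratum)
    else:
        raise ValueError(f"unknown method: {method!r}")
    if bootstrap_spec is None or not est.estimable:
        return est
    rng = np.random.default_rng(bootstrap_spec.seed)
    reps = np.empty(bootstrap_spec.n_reps)
    for r in range(bootstrap_spec.n_reps):
        idx = rng.integers(0, records.n_egos, records.n_egos)
        sub = records.subset(idx)
        try:
            if method == "naive":
                reps[r] = naive_exposure_segregation(sub).value
            else:
                reps[r] = corrected_exposure_segregation(
                    fit_mixed_model(sub)).value
        except (ValueError, np.linalg.LinAlgError):
            reps[r] = np.nan
    good = reps[np.isfinite(reps)]
    if good.size < 0.99 * bootstrap_spec.n_reps:
        logger.warning("bootstrap: %d / %d resamples failed",
                       bootstrap_spec.n_reps - good.size, bootstrap_spec.n_reps)
    alpha = 1.0 - bootstrap_spec.ci_level
    lo, hi = np.quantile(good, [alpha / 2, 1 - alpha / 2])
    return SegregationEstimate(est.value, est.method, est.n_egos, est.n_obs,
                               ci_low=float(min(lo, est.value)),
                               ci_high=float(max(hi, est.value)),
                               stratum=est.stratum, note=est.note)


def neighbourhood_sorting_index(individuals: pd.DataFrame,
                                tract_col: str = "home_tract_id",
                                ses_col: str = "ses") -> SegregationEstimate:
    """Correlation between SES and home-tract mean SES (ego included)."""
    df = individuals.dropna(subset=[ses_col])
    if df[tract_col].nunique() < 2:
        return SegregationEstimate(np.nan, "nsi", len(df),
                                   note="fewer than 2 tracts: NSI undefined")
    if len(df) < 2:
        return SegregationEstimate(np.nan, "nsi", len(df),
                                   note="fewer than 2 residents")
    x = df[ses_col].to_numpy(dtype=float)
    tract_mean = df.groupby(tract_col)[ses_col].transform("mean").to_numpy()
    if np.ptp(x) == 0 or np.ptp(tract_mean) == 0:
        return SegregationEstimate(np.nan, "nsi", len(df),
                                   note="zero variance in SES or tract means")
    r = float(np.corrcoef(x, tract_mean)[0, 1])
    return SegregationEstimate(r, "nsi", len(df))


def synthetic_tract_network(individuals: pd.DataFrame,
                            partners_per_ego: Optional[int] = None,
                            seed: int = 0,
                            tract_col: str = "home_tract_id") -> pd.DataFrame:
    """Edges of the synthetic within-tract exposure network.

    Every ego is exposed to partners drawn uniformly at random without
    replacement from their home-tract co-residents
    (``partners_per_ego=None`` takes all co-residents, making exposure
    segregation on this network the neighbourhood sorting index up to the
    ego-inclusion convention).  Residents of single-member tracts receive no
    partners (logged).  Returns an edge table consumable by
    :func:`build_ego_records`; timestamps/locations are placeholders.
    """
    rng = np.random.default_rng(seed)
    rows_i, rows_j = [], []
    lonely = 0
    for _, members in individuals.groupby(tract_col, sort=True):
        ids = members.index.to_numpy()
        if ids.size < 2:
            lonely += ids.size
            continue
        for a, ego in enumerate(ids):
            others = np.delete(ids, a)
            if partners_per_ego is not None and partners_per_ego < others.size:
                others = rng.choice(others, size=partners_per_ego, replace=False)
            rows_i.extend([ego] * others.size)
            rows_j.extend(others.tolist())
    if lonely:
        logger.info("synthetic tract network: %d single-member-tract "
                    "residents have no partners", lonely)
    edges = pd.DataFrame({"user_i": rows_i, "user_j": rows_j})
    edges["k"] = 1
    edges["t"] = 0
    edges["lat"] = np.nan
    edges["lon"] = np.nan
    return edges


def _stratum_frames(edges: pd.DataFrame, by: str,
                    tz_offset_h: float) -> dict[str, pd.DataFrame]:
    if by == "component":
        return {str(c): g for c, g in edges.groupby("component", sort=True)}
    if by == "tie_bin":
        lab = tie_strength_bins(edges)
        return {str(b): edges[lab == b]
                for b in ("1", "2", "3", "4", "5+") if (lab == b).any()}
    if by == "poi_category":
        at_poi = edges[edges["poi_category"] != ""]
        return {str(c): g for c, g in at_poi.groupby("poi_category", sort=True)}
    if by == "time_window":
        local_h = ((edges["t"].to_numpy() + tz_offset_h * 3600) // 3600) % 24
        w0 = (local_h // 3).astype(int) * 3
        labels = pd.Series([f"{a:02d}-{a + 3:02d}" for a in w0], index=edges.index)
        return {str(w): g for w, g in edges.groupby(labels, sort=True)}
    if by == "hub":
        in_hub = edges["hub_id"] != ""
        return {"hub": edges[in_hub], "non_hub": edges[~in_hub]}
    raise ValueError(f"unknown stratifier: {by!r}")


def decompose(edges: pd.DataFrame, individuals: pd.DataFrame, by: str,
              region_egos=None, method: str = "mixed",
              tz_offset_h: float = 0.0) -> list[SegregationEstimate]:
    """Per-stratum segregation estimates.

    Filters the edge table per stratum, rebuilds ego records (partner
    deduplication is per stratum) and re-estimates.  Strata that fail the
    estimator's preconditions are reported with a NaN value and a note,
    never silently dropped.
    """
    out = []
    for label, sub in _stratum_frames(edges, by, tz_offset_h).items():
        try:
            rec = build_ego_records(sub, individuals, region_egos,
                                    stratum=label)
            out.append(estimate_exposure_segregation(rec, method=method))
        except (ValueError, np.linalg.LinAlgError) as err:
            out.append(SegregationEstimate(np.nan, method, 0, 0,
                                           stratum=label,
                                           note=f"not estimable: {err}"))
    return out
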