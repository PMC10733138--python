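"""Inferential toolkit: percentile bootstrap, Spearman t-test, Steiger's Z.

No multiple-testing adjustment is applied anywhere; every stochastic routine
takes an explicit seed and is deterministic under it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional

import numpy as np
from scipy import stats as sps

__all__ = ["BootstrapSpec", "BootstrapResult", "bootstrap",
           "spearman_test", "steiger_z"]


@dataclass(frozen=True)
class BootstrapSpec:
    n_reps: int = 10_000
    resampling_unit: str = "individual"  # or "region"
    seed: int = 0
    ci_level: float = 0.95
    two_sided: bool = True

    def __post_init__(self):
        if self.n_reps < 100:
            raise ValueError("bootstrap CIs need n_reps >= 100")
        if self.resampling_unit not in ("individual", "region"):
            raise ValueError(f"unknown resampling unit: {self.resampling_unit!r}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


class BootstrapResult(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    n_reps: int
    n_failed: int


def bootstrap(statistic: Callable, data, spec: BootstrapSpec,
              groups=None, null_value: float = 0.0) -> BootstrapResult:
    """Percentile bootstrap of ``statistic(data)``.

    ``data`` is indexed positionally (numpy array or pandas object); rows are
    resampled with replacement.  When ``groups`` (a label per row) is given,
    whole groups are resampled instead of rows — this is the region-unit
    bootstrap for between-region contrasts.  The two-sided p-value against
    ``null_value`` is computed from the resample distribution with the
    (count + 1) / (B + 1) convention, so p is always in (0, 1].

    Resamples on which the statistic raises or returns a non-finite value are
    dropped; more than 1% of failures aborts with an error.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(data)
    take = (lambda idx: data.iloc[idx]) if hasattr(data, "iloc") else (lambda idx: data[idx])

    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        members = {g: np.flatnonzero(groups == g) for g in uniq}

    estimate = float(statistic(data))
    reps = np.empty(spec.n_reps)
    n_failed = 0
    for r in range(spec.n_reps):
        if groups is None:
            idx = rng.integers(0, n, size=n)
        else:
            picked = rng.integers(0, len(uniq), size=len(uniq))
            idx = np.concatenate([members[uniq[g]] for g in picked])
        try:
            v = float(statistic(take(idx)))
        except (ValueError, ZeroDivisionError, np.linalg.LinAlgError):
            v = np.nan
        if not np.isfinite(v):
            n_failed += 1
            v = np.nan
        reps[r] = v
    if n_failed > 0.01 * spec.n_reps:
        raise RuntimeError(
            f"statistic failed on {n_failed}/{spec.n_reps} bootstrap resamples")
    good = reps[np.isfinite(reps)]
    alpha = 1.0 - spec.ci_level
    ci_low, ci_high = np.quantile(good, [alpha / 2.0, 1.0 - alpha / 2.0])
    b = good.size
    p_lo = (np.sum(good <= null_value) + 1.0) / (b + 1.0)
    p_hi = (np.sum(good >= null_value) + 1.0) / (b + 1.0)
    p = min(1.0, 2.0 * min(p_lo, p_hi)) if spec.two_sided else min(1.0, p_hi)
    return BootstrapResult(estimate, float(ci_low), float(ci_high), float(p),
                           spec.n_reps, n_failed)


class SpearmanResult(NamedTuple):
    rho: float
    t: float
    p_two_sided: float
    exact_monotone: bool  # |rho| == 1: p is below the floor and reported as tiny


def spearman_test(x, y) -> SpearmanResult:
    """Spearman rank correlation with the Student-t test.

    Ranks use average ties; the statistic is ``t = rho * sqrt((n-2)/(1-rho^2))``
    referred to a t distribution with n-2 degrees of freedom.  A perfectly
    monotone sample (|rho| = 1) has a p-value below the machine floor; it is
    reported as the smallest positive normal float with ``exact_monotone`` set.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("spearman_test needs n >= 4")
    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        rho = float(np.sign(rho))
        return SpearmanResult(rho, np.inf * rho, float(np.finfo(float).tiny), True)
    t = rho * np.sqrt((n - 2.0) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(t), float(max(p, np.finfo(float).tiny)), False)


class SteigerResult(NamedTuple):
    z: float
    p_two_sided: float


def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> SteigerResult:
    """Steiger's Z for H0: rho_jk = rho_jh, two dependent correlations
    sharing variable j (Steiger 1980, the Fisher-z statistic with the
    shared-variable covariance term).

    Raises if the correlation triple is not a valid 3x3 correlation matrix
    (determinant < 0) or n <= 3.
    """
    if n <= 3:
        raise ValueError("steiger_z needs n > 3")
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    det = (1.0 - r_jk ** 2 - r_jh ** 2 - r_kh ** 2
           + 2.0 * r_jk * r_jh * r_kh)
    if det < -1e-12:
        raise ValueError(
            "infeasible correlation triple: the 3x3 correlation matrix has "
            f"negative determinant {det:.3g} (not positive semidefinite)")
    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    rbar = 0.5 * (r_jk + r_jh)
    psi = (r_kh * (1.0 - 2.0 * rbar ** 2)
           - 0.5 * rbar ** 2 * (1.0 - 2.0 * rbar ** 2 - r_kh ** 2))
    sbar = psi / (1.0 - rbar ** 2) ** 2
    z = (z_jk - z_jh) * np.sqrt((n - 3.0) / (2.0 - 2.0 * sbar))
    p = 2.0 * sps.norm.sf(abs(z))
    return SteigerResult(float(z), float(max(p, np.finfo(float).tiny)))
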