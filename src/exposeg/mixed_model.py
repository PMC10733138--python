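"""Random-intercept mixed model fitted by restricted maximum likelihood.

The model for partner SES values within ego groups is

    y_ij = a * x_i + b + eps1_i + eps2_ij,
    eps1_i ~ N(0, var1),  eps2_ij ~ N(0, var2),

where ``x_i`` is constant within group *i* (the ego's standardized SES) and
``y_ij`` are the SES values of the ego's exposure partners.  The ego-level
deviation ``eps1_i`` captures heterogeneity in the latent mean partner SES
beyond the linear trend; ``eps2_ij`` is per-partner sampling noise.  The
attenuation-free exposure-segregation correlation is then
``a / sqrt(a**2 + var1)`` (see :mod:`exposeg.segregation`).

Because the only covariate is group-constant, the restricted likelihood
reduces to per-group sufficient statistics (n_i, sum y, sum y^2), and the
marginal covariance per group is ``var2 * (I + lambda * J)`` with
``lambda = var1 / var2``.  We profile beta and var2 out analytically and
minimize the restricted criterion over lambda with a bounded scalar search
(lambda >= 0; tolerance 1e-8 on the log-ratio scale), explicitly comparing
the boundary lambda = 0 against the interior optimum.  This makes a fit on
thousands of egos a few milliseconds, which the simulation studies rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["MixedModelFit", "reml_random_intercept"]

_LAMBDA_MAX = 1e6


@dataclass(frozen=True)
class MixedModelFit:
    """REML point estimates for the ego-partner random-intercept model."""

    a: float
    b: float
    var1: float  # ego-level variance Var(eps1), >= 0 (may sit on the boundary)
    var2: float  # residual variance Var(eps2)
    converged: bool
    n_egos: int
    n_obs: int

    @property
    def boundary(self) -> bool:
        """True when the ego-level variance was estimated at the 0 boundary."""
        return self.var1 == 0.0


class _Sufficient:
    """Per-group sufficient statistics for the profiled REML criterion."""

    def __init__(self, x: np.ndarray, y: np.ndarray, sizes: np.ndarray):
        sizes = np.asarray(sizes, dtype=np.int64)
        if sizes.sum() != y.size:
            raise ValueError("group sizes do not sum to the number of observations")
        starts = np.r_[0, np.cumsum(sizes)[:-1]]
        self.n = sizes.astype(float)
        self.S = np.add.reduceat(y, starts)
        self.SS = np.add.reduceat(y * y, starts)
        self.X = np.column_stack([np.ones(x.size), x])
        self.N = float(y.size)
        self.p = 2

    def criterion(self, lam: float):
        """Restricted -2 log-likelihood (up to a constant) profiled over
        beta and var2, with per-group GLS weights w = n / (1 + n*lam)."""
        n, S, SS, X = self.n, self.S, self.SS, self.X
        shrink = 1.0 + n * lam
        w = n / shrink
        XtWX = (X * w[:, None]).T @ X
        XtWy = X.T @ (S / shrink)
        beta = np.linalg.solve(XtWX, XtWy)
        c = X @ beta  # fitted group-level mean
        rWr = (SS - 2.0 * c * S + n * c * c) - (lam / shrink) * (S - n * c) ** 2
        sigma2 = float(np.sum(rWr)) / (self.N - self.p)
        # a perfect fit drives the profiled residual variance to 0 (possibly
        # a hair below, numerically); floor it so the criterion stays finite
        sigma2 = max(sigma2, 1e-300)
        logdet_w = float(np.sum(np.log(shrink)))
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'WX not positive definite")
        crit = (self.N - self.p) * np.log(sigma2) + logdet_w + logdet_x
        return crit, beta, sigma2


def reml_random_intercept(x, y, group_sizes) -> MixedModelFit:
    """Fit ``y_ij = a x_i + b + eps1_i + eps2_ij`` by REML.

    Parameters
    ----------
    x : array of shape (m,)
        Group-level covariate (ego SES), one value per group.
    y : array of shape (N,)
        Observations, concatenated group by group.
    group_sizes : int array of shape (m,)
        Number of observations in each group, in the same order as ``x``.

    Raises
    ------
    ValueError
        If fewer than two groups are present, if no group has two or more
        observations (the two variance components are then unidentifiable),
        or if ``x`` is constant.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    sizes = np.asarray(group_sizes, dtype=np.int64).ravel()
    if x.size != sizes.size:
        raise ValueError("x and group_sizes must have one entry per group")
    if x.size < 2:
        raise ValueError("need at least 2 egos to fit the mixed model")
    if not np.any(sizes >= 2):
        raise ValueError(
            "need at least one ego with >= 2 partners: the ego-level and "
            "residual variances are otherwise unidentifiable"
        )
    if np.ptp(x) == 0.0:
        raise ValueError("ego SES x is constant; the slope is unidentifiable")

    stats = _Sufficient(x, y, sizes)

    def objective(t: float) -> float:
        # t parameterizes lambda = expm1(t) so the search is well scaled
        # near the boundary while still reaching very large ratios.
        return stats.criterion(np.expm1(t))[0]

    converged = True
    try:
        res = minimize_scalar(
            objective,
            bounds=(0.0, np.log1p(_LAMBDA_MAX)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(np.expm1(res.x))
        # the bounded search cannot land exactly on 0; accept the boundary
        # whenever it is at least as good as the interior optimum
        crit0 = stats.criterion(0.0)[0]
        if crit0 <= res.fun:
            lam = 0.0
        converged = bool(res.success)
    except np.linalg.LinAlgError:
        return MixedModelFit(np.nan, np.nan, np.nan, np.nan, False,
                             int(x.size), int(y.size))

    _, beta, sigma2 = stats.criterion(lam)
    return MixedModelFit(
        a=float(beta[1]),
        b=float(beta[0]),
        var1=float(lam * sigma2),
        var2=float(sigma2),
        converged=converged,
        n_egos=int(x.size),
        n_obs=int(y.size),
    )
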