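"""Shared nonparametric statistics.

Kendall partial rank correlation (tau-b based), one- and two-sample
proportion z-tests, and the Mann-Whitney U test.  These are the only
hypothesis tests the downstream severity / coadaptation analyses need, so
the module stays deliberately small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PartialCorrelation",
    "kendall_partial",
    "prop_ztest",
    "mann_whitney",
]


@dataclass(frozen=True)
class PartialCorrelation:
    """Kendall partial rank correlation between two variables.

    ``tau`` is tau-b (tie adjusted).  With covariates, the partial tau is
    obtained from the precision matrix of the pairwise tau-b matrix; the
    two-sided p-value uses the normal approximation with the sample size
    reduced by the number of covariates.
    """

    tau: float
    p: float
    n: int
    n_covariates: int


def _as_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.ptp(arr) == 0:
        raise ValueError(f"{name} is constant; rank correlation undefined")
    return arr


def kendall_partial(x, y, covariates: Sequence = ()) -> PartialCorrelation:
    """Kendall tau-b between ``x`` and ``y``, partialling out ``covariates``.

    With no covariates this is the plain tie-adjusted Kendall tau with its
    two-sided p-value.  With covariates, the partial tau is computed from
    the inverse of the matrix of pairwise tau-b coefficients over
    ``[x, y, *covariates]`` (for a single covariate z this reduces to the
    textbook recursion ``(t_xy - t_xz t_yz) / sqrt((1-t_xz^2)(1-t_yz^2))``).
    """
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    covs = [_as_vector(c, f"covariate {i}") for i, c in enumerate(covariates)]
    for c in covs:
        if len(c) != n:
            raise ValueError("covariates must match the length of x and y")

    if not covs:
        tau, p = sps.kendalltau(x, y)
        return PartialCorrelation(float(tau), float(p), n, 0)

    variables = [x, y, *covs]
    k = len(variables)
    taumat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            t, _ = sps.kendalltau(variables[i], variables[j])
            taumat[i, j] = taumat[j, i] = t
    try:
        prec = np.linalg.inv(taumat)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(taumat)
    ptau = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    ptau = float(np.clip(ptau, -1.0, 1.0))

    # Normal approximation for tau, with the effective sample size reduced
    # by the number of conditioning variables.
    n_eff = n - len(covs)
    z = 3.0 * ptau * np.sqrt(n_eff * (n_eff - 1)) / np.sqrt(2.0 * (2 * n_eff + 5))
    p = 2.0 * sps.norm.sf(abs(z))
    return PartialCorrelation(ptau, float(p), n, len(covs))


def prop_ztest(k1: int, n1: int, k2: int | None = None,
               n2: int | None = None, p0: float | None = None
               ) -> tuple[float, float]:
    """Two-sided z-test for one proportion against ``p0`` or two proportions.

    One-sample form uses the null variance ``p0 (1 - p0) / n``; the
    two-sample form uses the pooled-variance statistic.  Returns ``(z, p)``.
    """
    if n1 is None or n1 <= 0:
        raise ValueError("n1 must be positive")
    if not 0 <= k1 <= n1:
        raise ValueError("k1 must lie in [0, n1]")
    p1 = k1 / n1
    if p0 is not None:
        if not 0 < p0 < 1:
            raise ValueError("p0 must be in (0, 1)")
        z = (p1 - p0) / np.sqrt(p0 * (1 - p0) / n1)
    else:
        if k2 is None or n2 is None or n2 <= 0:
            raise ValueError("supply either p0 or (k2, n2)")
        if not 0 <= k2 <= n2:
            raise ValueError("k2 must lie in [0, n2]")
        p2 = k2 / n2
        pooled = (k1 + k2) / (n1 + n2)
        denom = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        if denom == 0:
            return 0.0, 1.0
        z = (p1 - p2) / denom
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Uses exact enumeration when the smaller sample has at most 8
    observations and the pooled data are tie free; otherwise the
    tie-corrected normal approximation.  Returns ``(U, p)`` where U is the
    statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
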