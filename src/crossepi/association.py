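"""Case-control QTL scans, permutation thresholds, mixed models, heritability.

Two scan flavours match the two cross designs:

- F2 binary-trait scan: per marker, the 2-df likelihood-ratio statistic of
  the saturated three-genotype-class binomial model against the null
  (equivalently the G-statistic of the 2x3 case/control-by-genotype
  table), reported as LOD = LRT / (2 ln 10).  Genome-wide significance
  comes from phenotype permutations of the maximum LOD.
- Combined F2 + advanced intercross scan: a univariate linear mixed model
  y = mu + x beta + u + eps with cov(u) = v_g K for a genetic relatedness
  matrix K, fit by maximum likelihood via one eigendecomposition of K
  reused across markers; the per-marker likelihood-ratio test is referred
  to chi-square (1 df) and multiplicity is handled with the effective
  number of tests from the marker correlation spectrum (Li-Ji).

Variance components for heritability reporting use REML; case-control
ascertainment is corrected with the liability-scale transformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .relatedness import Grm
from .simulate import MISSING, MarkerMap

__all__ = [
    "ScanResult",
    "VarianceComponents",
    "LogisticMixedResult",
    "binary_scan_f2",
    "permutation_thresholds",
    "lmm_scan",
    "reml_pve",
    "liability_transform",
    "pve_snp",
    "effective_tests",
    "logistic_mixed_or",
]

LOD_SCALE = 2.0 * np.log(10.0)


@dataclass
class ScanResult:
    """Per-marker association statistics plus the thresholds applied."""

    table: pd.DataFrame
    thresholds: dict


# ---------------------------------------------------------------------------
# F2 binary scan

def _class_indicators(genotypes: np.ndarray) -> tuple[np.ndarray, ...]:
    return tuple((genotypes == g).astype(float) for g in (0, 1, 2))


def _g_statistics(case_counts: np.ndarray, class_totals: np.ndarray
                  ) -> np.ndarray:
    """Vectorized G-statistic of 2x3 tables.

    ``case_counts``: (..., 3) cases per genotype class; ``class_totals``:
    (..., 3) individuals per class.  Empty cells follow the 0 log 0 = 0
    convention.
    """
    C = np.asarray(case_counts, dtype=float)
    N = np.asarray(class_totals, dtype=float)
    ncase = C.sum(axis=-1, keepdims=True)
    ntot = N.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_case = ncase / ntot
        e_case = N * p_case
        e_ctrl = N * (1.0 - p_case)
        K = N - C
        term = (np.where(C > 0, C * np.log(C / e_case), 0.0)
                + np.where(K > 0, K * np.log(K / e_ctrl), 0.0))
    term = np.where(N > 0, term, 0.0)
    return 2.0 * np.nan_to_num(term.sum(axis=-1))


def _additive_logistic(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Additive-coded logistic fit, returning (beta, se); NaN on failure."""
    import statsmodels.api as sm
    X = sm.add_constant(g.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        beta, se = float(fit.params[1]), float(fit.bse[1])
        if abs(beta) > 15:  # quasi-separation
            return np.nan, np.nan
        return beta, se
    except Exception:
        return np.nan, np.nan


def allele_odds_ratio(case_counts: np.ndarray, control_counts: np.ndarray
                      ) -> float:
    """Cross-product odds ratio of the 2x2 allele-count table."""
    c = np.asarray(case_counts, dtype=float)
    k = np.asarray(control_counts, dtype=float)
    case_risk = c[1] + 2 * c[2]
    case_ref = 2 * c[0] + c[1]
    ctrl_risk = k[1] + 2 * k[2]
    ctrl_ref = 2 * k[0] + k[1]
    if min(case_risk, case_ref, ctrl_risk, ctrl_ref) == 0:
        return np.nan
    return float((case_risk * ctrl_ref) / (case_ref * ctrl_risk))


def binary_scan_f2(genotypes: np.ndarray, y: np.ndarray,
                   marker_map: MarkerMap | None = None,
                   marker_ids: list[str] | None = None,
                   fit_logistic: bool = True) -> ScanResult:
    """Per-marker 2-df binary-trait scan with LOD scores.

    ``genotypes`` is (n, m) with -1 for missing (individuals missing a
    marker are dropped for that marker); ``y`` the binary phenotype.  The
    2-df statistic is the G-test of the 2x3 table; an additive logistic
    fit supplies beta, SE, and the per-allele odds ratio; the allele-table
    cross-product OR is reported alongside.  Monomorphic markers are
    flagged with LOD 0 and p = 1.
    """
    G = np.atleast_2d(np.asarray(genotypes))
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("phenotype must be binary 0/1")
    n, m = G.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match genotypes")

    ind = _class_indicators(G)  # missing contributes to no class
    class_totals = np.stack([M.sum(axis=0) for M in ind], axis=1)      # (m, 3)
    case_counts = np.stack([y @ M for M in ind], axis=1)               # (m, 3)
    lrt = _g_statistics(case_counts, class_totals)
    lod = lrt / LOD_SCALE
    monomorphic = (class_totals > 0).sum(axis=1) <= 1
    df = 2
    p = sps.chi2.sf(lrt, df)
    p = np.where(monomorphic, 1.0, p)
    lod = np.where(monomorphic, 0.0, lod)

    betas = np.full(m, np.nan)
    ses = np.full(m, np.nan)
    ors = np.full(m, np.nan)
    allele_ors = np.full(m, np.nan)
    for j in range(m):
        ctrl_counts = class_totals[j] - case_counts[j]
        allele_ors[j] = allele_odds_ratio(case_counts[j], ctrl_counts)
        if fit_logistic and not monomorphic[j]:
            obs = G[:, j] != MISSING
            betas[j], ses[j] = _additive_logistic(G[obs, j], y[obs])
            ors[j] = np.exp(betas[j])

    table = pd.DataFrame({
        "marker": marker_ids or (marker_map.ids if marker_map is not None
                                 else [f"marker{j}" for j in range(m)]),
        "lrt": lrt, "lod": lod, "p": p, "beta": betas, "se": ses,
        "odds_ratio": ors, "allele_or": allele_ors, "flagged": monomorphic,
    })
    if marker_map is not None:
        table.insert(1, "chrom", marker_map.chrom)
        table.insert(2, "bp", marker_map.bp)
    return ScanResult(table=table, thresholds={})


def permutation_thresholds(genotypes: np.ndarray, y: np.ndarray,
                           n_perm: int = 1000,
                           alphas=(0.05, 0.2), seed: int = 0,
                           batch: int = 250) -> dict[float, float]:
    """Genome-wide LOD thresholds by phenotype permutation.

    Each permutation shuffles case/control labels and records the
    genome-wide maximum LOD of the 2-df scan; the threshold at level
    ``alpha`` is the empirical (1 - alpha) quantile of those maxima.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    G = np.atleast_2d(np.asarray(genotypes))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    ind = _class_indicators(G)
    class_totals = np.stack([M.sum(axis=0) for M in ind], axis=1)  # (m, 3)

    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        Y = np.stack([rng.permutation(y) for _ in range(b)])       # (b, n)
        counts = np.stack([Y @ M for M in ind], axis=2)            # (b, m, 3)
        lrt = _g_statistics(counts, class_totals[None, :, :])
        maxima[done:done + b] = lrt.max(axis=1) / LOD_SCALE
        done += b
    return {float(a): float(np.quantile(maxima, 1.0 - a)) for a in alphas}


# ---------------------------------------------------------------------------
# linear mixed model on the GRM eigenbasis

def _ml_profile(yt: np.ndarray, Xt: np.ndarray, S: np.ndarray, log_delta: float
                ) -> float:
    """Negative profile ML log-likelihood at variance ratio delta = v_e/v_g."""
    d = S + np.exp(log_delta)
    w = 1.0 / d
    XtW = Xt * w[:, None]
    xx = Xt.T @ XtW
    xy = XtW.T @ yt
    try:
        bhat = np.linalg.solve(xx, xy)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yt - Xt @ bhat
    n = len(yt)
    rss = float(resid @ (resid * w))
    if rss <= 0:
        return np.inf
    ll = -0.5 * (n * np.log(2 * np.pi * rss / n) + np.log(d).sum() + n)
    return -ll


def _fit_ml(yt: np.ndarray, Xt: np.ndarray, S: np.ndarray) -> tuple[float, float]:
    """Maximize the profile ML over log delta; returns (loglik, delta)."""
    res = optimize.minimize_scalar(
        lambda ld: _ml_profile(yt, Xt, S, ld),
        bounds=(-10.0, 12.0), method="bounded",
        options={"xatol": 1e-6})
    return -res.fun, float(np.exp(res.x))


def lmm_scan(genotypes: np.ndarray, y: np.ndarray, grm: Grm,
             marker_map: MarkerMap | None = None,
             marker_ids: list[str] | None = None) -> ScanResult:
    """Mixed-model association scan with per-marker likelihood-ratio tests.

    Variance components are profiled by maximum likelihood on the GRM
    eigenbasis, computed once and reused for every marker; the null
    (intercept-only) model is fit once.  Missing marker genotypes are
    mean-imputed for the scan (the pipeline imputes genotypes upstream, so
    this is a numerical fallback, not an analysis choice).  Constant
    markers are flagged with p = 1.
    """
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if grm.n != n:
        raise ValueError("GRM size does not match individuals")
    S, U = np.linalg.eigh(grm.values)
    S = np.maximum(S, 0.0)
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)

    ll0, _ = _fit_ml(yt, ones_t[:, None], S)

    miss = G == MISSING
    if miss.any():
        means = np.where(miss, np.nan, G)
        col_means = np.nanmean(means, axis=0)
        G = np.where(miss, col_means, G)

    lrts = np.empty(m)
    betas = np.full(m, np.nan)
    flagged = np.zeros(m, dtype=bool)
    Gt = U.T @ G
    for j in range(m):
        if np.ptp(G[:, j]) == 0:
            lrts[j] = 0.0
            flagged[j] = True
            continue
        Xt = np.column_stack([ones_t, Gt[:, j]])
        ll1, delta = _fit_ml(yt, Xt, S)
        lrts[j] = max(0.0, 2.0 * (ll1 - ll0))
        # report the GLS effect at the fitted delta
        w = 1.0 / (S + delta)
        xx = Xt.T @ (Xt * w[:, None])
        xy = (Xt * w[:, None]).T @ yt
        try:
            betas[j] = float(np.linalg.solve(xx, xy)[1])
        except np.linalg.LinAlgError:
            flagged[j] = True
    p = sps.chi2.sf(lrts, 1)
    p = np.where(flagged, 1.0, p)

    table = pd.DataFrame({
        "marker": marker_ids or (marker_map.ids if marker_map is not None
                                 else [f"marker{j}" for j in range(m)]),
        "lrt": lrts, "p": p, "beta": betas, "flagged": flagged,
    })
    if marker_map is not None:
        table.insert(1, "chrom", marker_map.chrom)
        table.insert(2, "bp", marker_map.bp)
    return ScanResult(table=table, thresholds={})


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components and the variance explained by the GRM."""

    v_g: float
    v_e: float
    pve: float
    pve_se: float
    converged: bool


def reml_pve(y: np.ndarray, grm: Grm) -> VarianceComponents:
    """REML estimate of the genetic and residual variance on a GRM.

    One-dimensional optimization over the heritability on the GRM
    eigenbasis; the PVE standard error comes from the curvature of the
    profile restricted likelihood.  Non-convergence to an interior optimum
    returns the boundary estimate with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if grm.n != n:
        raise ValueError("GRM size does not match phenotype length")
    S, U = np.linalg.eigh(grm.values)
    S = np.maximum(S, 0.0)
    yt = U.T @ y
    Xt = (U.T @ np.ones(n))[:, None]
    q = 1

    def neg_reml(log_delta: float) -> float:
        d = S + np.exp(log_delta)
        w = 1.0 / d
        xx = Xt.T @ (Xt * w[:, None])
        xy = (Xt * w[:, None]).T @ yt
        bhat = np.linalg.solve(xx, xy)
        resid = yt - Xt @ bhat
        rss = float(resid @ (resid * w))
        if rss <= 0:
            return np.inf
        sigma2 = rss / (n - q)
        ll = -0.5 * ((n - q) * np.log(2 * np.pi * sigma2) + np.log(d).sum()
                     + np.linalg.slogdet(xx)[1] + (n - q))
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 12.0),
                                   method="bounded", options={"xatol": 1e-8})
    log_delta = float(res.x)
    delta = np.exp(log_delta)
    converged = bool(res.success) and -11.5 < log_delta < 11.5

    d = S + delta
    w = 1.0 / d
    xx = Xt.T @ (Xt * w[:, None])
    xy = (Xt * w[:, None]).T @ yt
    bhat = np.linalg.solve(xx, xy)
    resid = yt - Xt @ bhat
    v_g = float(resid @ (resid * w)) / (n - q)
    v_e = v_g * delta
    pve = v_g / (v_g + v_e)

    # delta-method SE from the numeric curvature of the profile REML in pve
    def nll_of_pve(h: float) -> float:
        h = min(max(h, 1e-9), 1 - 1e-9)
        return neg_reml(np.log((1 - h) / h))

    eps = 1e-4
    h0 = min(max(pve, 2 * eps), 1 - 2 * eps)
    second = (nll_of_pve(h0 + eps) - 2 * nll_of_pve(h0) + nll_of_pve(h0 - eps)) / eps ** 2
    pve_se = float(1.0 / np.sqrt(second)) if second > 0 else np.nan
    return VarianceComponents(v_g=v_g, v_e=v_e, pve=float(pve),
                              pve_se=pve_se, converged=converged)


# ---------------------------------------------------------------------------
# scalar transforms

def liability_transform(pve: float, P: float, A: float) -> float:
    """Ascertainment-corrected liability-scale variance explained.

    PVE_l = PVE * P^2 (1-P)^2 / (A (1-A) z^2) where P is the population
    incidence, A the ascertained-cohort incidence, and z the standard
    normal density at the population liability threshold.
    """
    if not (0.0 < P < 1.0) or not (0.0 < A < 1.0):
        raise ValueError("P and A must be in (0, 1)")
    if pve < 0:
        raise ValueError("PVE must be non-negative")
    z = sps.norm.pdf(sps.norm.ppf(1.0 - P))
    return float(pve * P ** 2 * (1 - P) ** 2 / (A * (1 - A) * z ** 2))


def pve_snp(maf: float, beta: float, pv: float,
            conventional: bool = False) -> float:
    """Variance explained by a single marker: MAF (1-MAF) beta^2 / PV.

    The default follows the formula as printed in the source framework;
    ``conventional=True`` applies the factor-2 additive-variance version
    (2 MAF (1-MAF) beta^2 / PV).
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError("MAF must be in (0, 0.5]")
    if pv <= 0:
        raise ValueError("phenotypic variance must be positive")
    factor = 2.0 if conventional else 1.0
    return float(factor * maf * (1.0 - maf) * beta ** 2 / pv)


def effective_tests(genotypes: np.ndarray) -> tuple[float, dict[str, float]]:
    """Effective number of tests from the marker correlation spectrum (Li-Ji).

    M_eff = sum over eigenvalues of I(lambda >= 1) + (lambda - floor(lambda));
    thresholds are 0.05 / M_eff (significant) and 1 / M_eff (suggestive).
    Missing genotypes are mean-imputed; zero-variance markers are excluded
    with a warning.
    """
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    if G.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    miss = G == MISSING
    if miss.any():
        col_means = np.nanmean(np.where(miss, np.nan, G), axis=0)
        if np.isnan(col_means).any():
            warnings.warn("markers with only missing genotypes excluded")
            keep = ~np.isnan(col_means)
            G, miss, col_means = G[:, keep], miss[:, keep], col_means[keep]
        G = np.where(miss, col_means, G)
    sd = G.std(axis=0)
    if (sd == 0).any():
        warnings.warn("zero-variance markers excluded from M_eff")
        G = G[:, sd > 0]
    corr = np.corrcoef(G, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.maximum(lam, 0.0)
    m_eff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return m_eff, {"significant": 0.05 / m_eff, "suggestive": 1.0 / m_eff}


# ---------------------------------------------------------------------------
# logistic mixed model (PQL)

@dataclass(frozen=True)
class LogisticMixedResult:
    beta: float
    se: float
    odds_ratio: float
    v_g: float
    converged: bool
    flagged: bool = False
    note: str = ""


def logistic_mixed_or(x: np.ndarray, y: np.ndarray, grm: Grm,
                      n_outer: int = 4, vg_bounds=(1e-6, 5.0)
                      ) -> LogisticMixedResult:
    """Odds ratio from a penalized quasi-likelihood logistic mixed model.

    logit P(y=1) = mu + x beta + u with cov(u) = v_g K.  Each outer
    iteration re-linearizes the model at the current fit, estimates v_g by
    REML on the working response, and updates the fixed and random effects
    by GLS.  Complete separation (detected on the initial plain logistic
    fit) is flagged and no estimate is returned.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if grm.n != n:
        raise ValueError("GRM size does not match individuals")
    if np.ptp(x) == 0:
        return LogisticMixedResult(np.nan, np.nan, np.nan, np.nan, False,
                                   flagged=True, note="constant marker")
    X = np.column_stack([np.ones(n), x])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not glm.mle_retvals.get("converged", True) or abs(glm.params[1]) > 12:
            return LogisticMixedResult(np.nan, np.nan, np.nan, np.nan, False,
                                       flagged=True, note="separation")
        eta = np.clip(X @ glm.params, -10, 10)
    except Exception:
        return LogisticMixedResult(np.nan, np.nan, np.nan, np.nan, False,
                                   flagged=True, note="separation")

    K = grm.values
    v_g = 0.1
    beta = np.array(glm.params, dtype=float)
    se = float(glm.bse[1])
    for _ in range(n_outer):
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = np.clip(mu * (1.0 - mu), 1e-6, None)
        z = eta + (y - mu) / W
        Dinv = 1.0 / W

        def neg_reml(log_vg: float) -> float:
            vg = np.exp(log_vg)
            V = vg * K + np.diag(Dinv)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return np.inf
            logdet = 2.0 * np.log(np.diag(L)).sum()
            Vi_z = np.linalg.solve(V, z)
            Vi_X = np.linalg.solve(V, X)
            xx = X.T @ Vi_X
            b = np.linalg.solve(xx, X.T @ Vi_z)
            r = z - X @ b
            quad = float(r @ np.linalg.solve(V, r))
            return 0.5 * (logdet + np.linalg.slogdet(xx)[1] + quad)

        res = optimize.minimize_scalar(neg_reml,
                                       bounds=(np.log(vg_bounds[0]),
                                               np.log(vg_bounds[1])),
                                       method="bounded",
                                       options={"xatol": 1e-3})
        v_g = float(np.exp(res.x))
        V = v_g * K + np.diag(Dinv)
        Vi_X = np.linalg.solve(V, X)
        xx = X.T @ Vi_X
        beta = np.linalg.solve(xx, Vi_X.T @ z)
        cov = np.linalg.inv(xx)
        se = float(np.sqrt(cov[1, 1]))
        u = v_g * (K @ np.linalg.solve(V, z - X @ beta))
        eta = np.clip(X @ beta + u, -10, 10)

    return LogisticMixedResult(beta=float(beta[1]), se=se,
                               odds_ratio=float(np.exp(beta[1])),
                               v_g=v_g, converged=True)
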