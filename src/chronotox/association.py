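"""Resampling-based association inference.

Small-cohort inference layer: Spearman correlations with bootstrap percentile
confidence intervals and permutation p-values, case-resampling bootstrap OLS
(25,000 resamples by default) with percentile CIs and two-tailed sign-based
bootstrap p-values, standardized regression slopes, Hedges' g effect sizes,
and the usual two-sample tests (Wilcoxon rank-sum, Fisher exact, two-sample
Kolmogorov-Smirnov) with Benjamini-Hochberg adjustment across declared test
families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "AssociationResult",
    "EffectSizeResult",
    "OLSBootstrapResult",
    "spearman_bootstrap",
    "ols_bootstrap",
    "standardized_slope",
    "hedges_g",
    "basic_tests",
    "fisher_exact_2xk",
]


@dataclass
class AssociationResult:
    """Effect estimate with resampling-based uncertainty."""

    estimate: float
    ci_low: float
    ci_high: float
    p_classical: float
    p_resampled: float
    method: str
    n: int
    n_boot: int = 0
    n_perm: int = 0
    seed: int | None = None
    ci_violated: bool = False  # percentile CI excludes the point estimate


@dataclass
class EffectSizeResult:
    hedges_g: float
    cohen_d: float
    correction_j: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int


@dataclass
class OLSBootstrapResult:
    """Per-coefficient bootstrap OLS inference plus model-level metadata."""

    coef_names: list
    estimates: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_boot: np.ndarray
    adj_r_squared: float
    n: int
    n_boot: int
    seed: int | None
    diagnostics: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_names,
                "estimate": self.estimates,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_boot": self.p_boot,
            }
        )


def spearman_bootstrap(
    x,
    y,
    n_boot: int = 2000,
    n_perm: int = 10000,
    seed: int | None = None,
) -> AssociationResult:
    """Spearman rho with bootstrap percentile CI and permutation p-value.

    rho uses average ranks for ties.  The permutation p-value carries add-one
    smoothing: ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + P)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    if x.size < 4:
        raise ValueError("need n >= 4 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("observations must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant variable")

    rho, p_classical = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    n = x.size

    idx = rng.integers(0, n, size=(n_boot, n))
    rx = _rank_rows(x[idx])
    ry = _rank_rows(y[idx])
    boot = _row_pearson(rx, ry)
    boot = boot[np.isfinite(boot)]  # degenerate resamples (constant) dropped
    if boot.size:
        ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    else:
        ci_low = ci_high = rho

    perm_rho = np.empty(n_perm)
    ry_obs = stats.rankdata(y)
    rx_obs = stats.rankdata(x)
    for i in range(n_perm):
        perm_rho[i] = _row_pearson(
            rx_obs[None, :], ry_obs[rng.permutation(n)][None, :]
        )[0]
    p_perm = (1.0 + np.sum(np.abs(perm_rho) >= abs(rho) - 1e-12)) / (1.0 + n_perm)

    return AssociationResult(
        estimate=float(rho),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_classical=float(p_classical),
        p_resampled=float(p_perm),
        method="spearman",
        n=n,
        n_boot=n_boot,
        n_perm=n_perm,
        seed=seed,
        ci_violated=not (ci_low - 1e-12 <= rho <= ci_high + 1e-12),
    )


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=1)


def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def ols_bootstrap(
    y,
    X,
    n_boot: int = 25000,
    seed: int | None = None,
    add_intercept: bool = True,
    coef_names: list | None = None,
) -> OLSBootstrapResult:
    """Case-resampling bootstrap around an OLS fit.

    Point estimates come from the normal equations on the full sample.  Each
    of ``n_boot`` resamples redraws rows with replacement and refits; the
    2.5th/97.5th percentiles give the 95% CI and the two-tailed bootstrap
    p-value compares the share of resampled coefficients on either side of
    zero (add-one smoothed, so its floor is 2/(B+1)).  Residual-normality,
    collinearity (VIF) and fit diagnostics are attached as metadata.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.size != n:
        raise ValueError("y and X must have the same number of rows")
    names = list(coef_names) if coef_names is not None else [f"x{j}" for j in range(k)]
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + names
    p = X.shape[1]
    if n <= p:
        raise ValueError("need n > number of predictors (plus intercept)")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            f"design is rank deficient (rank {rank} < {p}); drop collinear columns"
        )

    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else float("nan")

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, p))
    chunk = max(1, int(5e6 // (n * p)))  # bound memory of the batched solve
    filled = 0
    while filled < n_boot:
        m = min(chunk, n_boot - filled)
        idx = rng.integers(0, n, size=(m, n))
        Xb = X[idx]  # (m, n, p)
        yb = y[idx]  # (m, n)
        xtx = np.einsum("mni,mnj->mij", Xb, Xb)
        xty = np.einsum("mni,mn->mi", Xb, yb)
        try:
            boot[filled : filled + m] = np.linalg.solve(xtx, xty[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for r in range(m):
                boot[filled + r] = np.linalg.lstsq(Xb[r], yb[r], rcond=None)[0]
        filled += m

    ci_low, ci_high = np.percentile(boot, [2.5, 97.5], axis=0)
    n_le = (boot <= 0).sum(axis=0)
    n_ge = (boot >= 0).sum(axis=0)
    p_boot = 2.0 * np.minimum((1 + n_le) / (n_boot + 1), (1 + n_ge) / (n_boot + 1))
    p_boot = np.minimum(p_boot, 1.0)

    diagnostics = _ols_diagnostics(y, X, beta, resid, names)
    return OLSBootstrapResult(
        coef_names=names,
        estimates=beta,
        ci_low=ci_low,
        ci_high=ci_high,
        p_boot=p_boot,
        adj_r_squared=float(adj_r2),
        n=n,
        n_boot=n_boot,
        seed=seed,
        diagnostics=diagnostics,
    )


def _ols_diagnostics(y, X, beta, resid, names) -> dict:
    out: dict = {}
    try:
        out["shapiro_p_resid"] = float(stats.shapiro(resid).pvalue)
    except Exception:  # tiny n or constant residuals
        out["shapiro_p_resid"] = float("nan")
    fitted = X @ beta
    out["resid_vs_fitted_corr"] = (
        float(np.corrcoef(fitted, resid)[0, 1]) if np.ptp(fitted) > 0 else 0.0
    )
    vif = {}
    if X.shape[1] > 2:
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            bj = np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            rj = X[:, j] - others @ bj
            ssj = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
            r2j = 1.0 - float(rj @ rj) / ssj if ssj > 0 else 0.0
            vif[names[j]] = 1.0 / (1.0 - r2j) if r2j < 1 else float("inf")
    out["vif"] = vif
    return out


def standardized_slope(x, y) -> AssociationResult:
    """Slope of z-scored y on z-scored x (population-sd convention).

    Algebraically this equals the Pearson correlation; the classical 95% CI
    comes from the OLS fit on the standardized variables.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("standardized slope undefined for zero-variance input")
    zx = stats.zscore(x)  # population (n) denominator
    zy = stats.zscore(y)
    fit = sm.OLS(zy, sm.add_constant(zx)).fit()
    slope = float(fit.params[1])
    ci = fit.conf_int(alpha=0.05)
    return AssociationResult(
        estimate=slope,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p_classical=float(fit.pvalues[1]),
        p_resampled=float("nan"),
        method="standardized_slope",
        n=x.size,
    )


def hedges_g(group1, group2) -> EffectSizeResult:
    """Bias-corrected standardized mean difference between two groups.

    ``d = (mean1 - mean2)/s_pooled`` with the (n-1)-pooled SD,
    ``J = 1 - 3/(4(n1+n2) - 9)`` and ``g = J*d``; the CI uses the standard
    large-sample variance of g.
    """
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per group")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    diff = g1.mean() - g2.mean()
    if sp2 == 0:
        if diff == 0:
            j0 = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
            return EffectSizeResult(0.0, 0.0, j0, 0.0, 0.0, n1, n2)
        raise ValueError("zero pooled SD with unequal means: effect size undefined")
    d = diff / math.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = j * d
    var_g = j**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2 - 2)))
    half = 1.959963984540054 * math.sqrt(var_g)
    return EffectSizeResult(
        hedges_g=float(g),
        cohen_d=float(d),
        correction_j=float(j),
        ci_low=float(g - half),
        ci_high=float(g + half),
        n1=n1,
        n2=n2,
    )


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2 x k contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more likely than the observed table
    (the conventional two-sided rule).  Intended for the small tables this
    package produces (cohort-scale counts).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("contingency table must be 2 x k")
    if (t < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    col = t.sum(axis=0)
    r1 = int(t.sum(axis=1)[0])
    k = t.shape[1]

    def log_comb(n, r):
        return (
            math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)
        )

    log_denom = log_comb(int(col.sum()), r1)

    def table_logp(row1):
        return sum(log_comb(int(col[j]), row1[j]) for j in range(k)) - log_denom

    obs_logp = table_logp(t[0])
    total = 0.0
    stack = [((), r1)]
    while stack:
        prefix, remaining = stack.pop()
        j = len(prefix)
        if j == k - 1:
            if 0 <= remaining <= col[j]:
                lp = table_logp(prefix + (remaining,))
                if lp <= obs_logp + 1e-9:
                    total += math.exp(lp)
            continue
        for v in range(0, min(int(col[j]), remaining) + 1):
            stack.append((prefix + (v,), remaining - v))
    return min(total, 1.0)


def basic_tests(data, kind: str) -> tuple[float, float]:
    """Standard two-sided two-sample tests, returned as (statistic, p).

    ``kind`` is one of ``wilcoxon_rank_sum`` (Mann-Whitney U, exact for small
    tie-free samples, normal approximation with tie correction otherwise),
    ``fisher_exact`` (2 x k contingency table) or ``ks_two_sample``.
    """
    if kind == "wilcoxon_rank_sum":
        a, b = (np.asarray(d, float) for d in data)
        small = a.size <= 25 and b.size <= 25
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (small and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if kind == "fisher_exact":
        t = np.asarray(data, dtype=int)
        if t.shape == (2, 2):
            return float(stats.fisher_exact(t)[0]), float(stats.fisher_exact(t)[1])
        return float("nan"), fisher_exact_2xk(t)
    if kind == "ks_two_sample":
        a, b = (np.asarray(d, float) for d in data)
        res = stats.ks_2samp(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind: {kind!r}")


def adjust_family(results: pd.DataFrame, p_col: str = "p", family_col: str | None = None) -> pd.DataFrame:
    """Attach BH q-values, optionally within declared test families."""
    out = results.copy()
    if family_col is None:
        out["q"] = bh_adjust(out[p_col].to_numpy())
    else:
        out["q"] = np.nan
        for _, idx in out.groupby(family_col).groups.items():
            out.loc[idx, "q"] = bh_adjust(out.loc[idx, p_col].to_numpy())
    return out
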