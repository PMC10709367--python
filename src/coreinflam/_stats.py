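"""Shared statistical primitives used across the pipeline modules.

Everything here is deliberately small and heavily exercised by the module
test suites: Benjamini-Hochberg adjustment, and a profiled maximum-likelihood
fitter for the one-factor random-intercept linear mixed model that backs
``study_de.lmm_lrt`` and everything delegating to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} p_(j) * m / j, capped at 1.  NaNs are carried
    through untouched and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# One-factor random-intercept LMM by profiled ML
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """Result of a linear mixed model fit and its LRT against a null.

    beta / se are the fixed-effect estimates of the *full* model.  The
    random-intercept variance(s) are in ``re_var``.  ``lrt_stat`` is
    2*(loglik_full - loglik_null), ``df`` the number of fixed-effect columns
    added by the full model.
    """

    beta: np.ndarray
    se: np.ndarray
    re_var: dict = field(default_factory=dict)
    sigma2: float = np.nan
    loglik_full: float = np.nan
    loglik_null: float = np.nan
    lrt_stat: float = np.nan
    df: int = 0
    p: float = np.nan
    converged: bool = True
    boundary: bool = False


def _profile_loglik(log_theta, y, X, starts, counts):
    """Profiled ML log-likelihood of y = X b + u_g + e at variance ratio
    theta = var(u)/var(e).  Group structure given by contiguous blocks
    (starts/counts after sorting by group)."""
    theta = np.exp(log_theta)
    n, k = X.shape
    # V^-1 = I - theta/(1+theta*n_g) J within each group (Woodbury)
    # accumulate X'V^-1X, X'V^-1y, y'V^-1y via per-group sums
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    logdet = 0.0
    for s, c in zip(starts, counts):
        sl = slice(s, s + c)
        xs = X[sl].sum(axis=0)
        ys = y[sl].sum()
        w = theta / (1.0 + theta * c)
        XtX -= w * np.outer(xs, xs)
        Xty -= w * xs * ys
        yty -= w * ys * ys
        logdet += np.log1p(theta * c)
    beta = np.linalg.solve(XtX, Xty)
    rss = yty - beta @ Xty
    rss = max(rss, 1e-300)
    sigma2 = rss / n
    ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    return ll, beta, sigma2, XtX


def fit_lmm_ml(y, X, groups):
    """ML fit of a one-factor random-intercept LMM.

    Returns (beta, se, loglik, sigma2_e, sigma2_b, boundary).  The
    variance ratio is profiled out and optimized on the log scale, with the
    theta -> 0 boundary (pure OLS) always evaluated as a candidate.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n = y.size
    order = np.argsort(groups, kind="stable")
    ys, Xs, gs = y[order], X[order], groups[order]
    _, starts, counts = np.unique(gs, return_index=True, return_counts=True)

    def neg(lt):
        return -_profile_loglik(lt, ys, Xs, starts, counts)[0]

    res = minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    ll_opt, beta, sigma2, XtX = _profile_loglik(res.x, ys, Xs, starts, counts)
    # boundary candidate: no random effect (theta -> 0)
    ll0, beta0, sigma20, XtX0 = _profile_loglik(-np.inf, ys, Xs, starts, counts)
    if ll0 >= ll_opt - 1e-10:
        beta, sigma2, XtX, theta, ll = beta0, sigma20, XtX0, 0.0, ll0
        boundary = True
    else:
        theta, ll = np.exp(res.x), ll_opt
        boundary = False
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    sigma2_b = theta * sigma2
    return beta, se, ll, sigma2, sigma2_b, boundary


def ecdf_ks_uniform(p: np.ndarray) -> float:
    """Kolmogorov-Smirnov p-value against Uniform(0,1); convenience for the
    null-calibration tests."""
    from scipy.stats import kstest

    return kstest(p, "uniform").pvalue
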