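"""Per-study negative-binomial differential expression and the generic
per-gene linear-mixed-model likelihood-ratio engine.

The NB engine is a reference Wald test: median-of-ratios size factors,
method-of-moments dispersions moderated toward a parametric 1/mean trend,
a vectorized IRLS fit of log mu = log s_j + b0 + b1 * x_inflamed, optional
ridge shrinkage of the fold change, independent filtering and a
Pearson-residual count-outlier rule.  Downstream stages also accept
precomputed DE tables with the same columns, so the engine is pluggable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import LmmFit, bh_adjust, fit_lmm_ml
from .core_io import StudyBundle

log = logging.getLogger("coreinflam")

DE_COLUMNS = ["log2fc", "se", "stat", "p", "padj", "base_mean", "tested"]


@dataclass
class DEResult:
    """Per-gene DE table: log2fc, se, stat, p, padj, base_mean, tested.

    padj is defined only for tested genes.  ``shrunk`` records whether the
    reported log2fc went through ridge shrinkage.
    """

    table: pd.DataFrame
    shrunk: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in DE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"DE table lacks columns {missing}")

    @property
    def tested(self) -> pd.Series:
        return self.table["tested"].astype(bool)

    def significant(self, alpha: float = 0.05) -> pd.Index:
        t = self.table
        return t.index[self.tested & (t["padj"] <= alpha)]


# ---------------------------------------------------------------------------
# Filtering and size factors
# ---------------------------------------------------------------------------

def prefilter(bundle: StudyBundle, min_count: int = 2,
              min_samples: int = 1) -> StudyBundle:
    """Keep genes with count >= min_count in at least min_samples samples
    (defaults reproduce the counts>1-in-at-least-1-sample rule)."""
    keep = (bundle.counts.to_numpy() >= min_count).sum(axis=1) >= min_samples
    return StudyBundle(bundle.counts.loc[keep], bundle.meta.copy())


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors rescaled to geometric mean 1.

    Falls back to library-size factors (with a warning) when no gene is
    positive in every sample.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    mat = df.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if allpos.sum() == 0:
        warnings.warn("no all-positive gene; using library-size factors",
                      stacklevel=2)
        f = mat.sum(axis=0)
    else:
        sub = mat[allpos]
        geo = np.exp(np.mean(np.log(sub), axis=1))
        f = np.median(sub / geo[:, None], axis=0)
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=df.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Dispersion model
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    raw: np.ndarray
    trended: np.ndarray
    final: np.ndarray
    trend_params: tuple

    def __post_init__(self):
        lo = np.minimum(self.raw, self.trended)
        hi = np.maximum(self.raw, self.trended)
        assert np.all(self.final >= lo - 1e-12)
        assert np.all(self.final <= hi + 1e-12)


_ALPHA_MIN, _ALPHA_MAX = 1e-8, 10.0


def estimate_dispersions(norm_counts: np.ndarray, sf: np.ndarray,
                         groups: np.ndarray | None = None) -> DispersionModel:
    """Method-of-moments gene dispersions moderated toward a parametric
    a0 + a1/mean trend (geometric-mean shrinkage in log space, weight 0.5).

    When a group vector is given, the variance is the within-group pooled
    variance so that a real condition effect does not inflate dispersion.
    """
    mu = norm_counts.mean(axis=1)
    if groups is None:
        v = norm_counts.var(axis=1, ddof=1)
    else:
        groups = np.asarray(groups)
        rss = np.zeros(norm_counts.shape[0])
        df_tot = 0
        for g in np.unique(groups):
            sub = norm_counts[:, groups == g]
            if sub.shape[1] < 2:
                continue
            rss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df_tot += sub.shape[1] - 1
        v = rss / max(df_tot, 1)
    # E var(y/s) ~ mu * mean(1/s) + alpha * mu^2
    xim = np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - xim * mu) / mu**2
    raw = np.clip(np.nan_to_num(raw, nan=_ALPHA_MIN), _ALPHA_MIN, _ALPHA_MAX)
    # trend alpha(mu) = a0 + a1/mu on genes with an informative raw estimate
    use = (mu > 1) & (raw > 2 * _ALPHA_MIN)
    if use.sum() >= 10:
        A = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(A, raw[use], rcond=None)
        a0, a1 = float(max(coef[0], 1e-6)), float(max(coef[1], 0.0))
    else:
        a0, a1 = float(np.median(raw)), 0.0
    trended = np.clip(a0 + a1 / np.maximum(mu, 1e-8), _ALPHA_MIN, _ALPHA_MAX)
    final = np.exp(0.5 * np.log(raw) + 0.5 * np.log(trended))
    return DispersionModel(raw, trended, final, (a0, a1))


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def _nb_irls(y: np.ndarray, x: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray, max_iter: int = 60, tol: float = 1e-8):
    """Vectorized IRLS for per-gene NB GLMs with design [1, x] and a known
    offset (log size factors).  Returns beta0, beta1, se1, converged, mu."""
    G, n = y.shape
    # start from group means on the normalized scale
    s = np.exp(offset)
    q = y / s
    m1 = q[:, x == 1].mean(axis=1)
    m0 = q[:, x == 0].mean(axis=1)
    eps = 0.5 / n
    b1 = np.log((m1 + eps) / (m0 + eps))
    b0 = np.log(m0 + eps)
    conv = np.zeros(G, dtype=bool)
    a = alpha[:, None]
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + a * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        step0 = np.nan_to_num(nb0 - b0)
        step1 = np.nan_to_num(nb1 - b1)
        # damp huge steps for stability
        scale = np.maximum(1.0, np.maximum(np.abs(step0), np.abs(step1)) / 5.0)
        b0 = b0 + step0 / scale
        b1 = b1 + step1 / scale
        conv = (np.abs(step0) < tol) & (np.abs(step1) < tol)
        if conv.all():
            break
    eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + a * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    det = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det
    se1 = np.sqrt(np.maximum(var_b1, 0.0))
    return b0, b1, se1, conv, mu


def nb_wald(bundle: StudyBundle, contrast=("inflamed", "resting"),
            shrink_lfc: bool = True, outlier_mult: float = 10.0,
            condition_col: str = "condition",
            dispersions: np.ndarray | None = None) -> DEResult:
    """NB GLM Wald test of inflamed vs resting, on the log2 scale.

    Genes whose IRLS fit fails to converge, or that contain a count outlier
    (squared Pearson residual above outlier_mult x the matrix-wide median),
    are flagged untested.  Ridge shrinkage of the fold change uses a normal
    prior whose sd matches the 99th percentile of the raw |log2FC|.
    """
    cond = bundle.meta[condition_col]
    hi, lo = contrast
    x = np.where(cond.to_numpy() == hi, 1.0,
                 np.where(cond.to_numpy() == lo, 0.0, np.nan))
    if np.isnan(x).any():
        keep = ~np.isnan(x)
        bundle = StudyBundle(bundle.counts.loc[:, bundle.samples[keep]],
                             bundle.meta.loc[bundle.samples[keep]])
        x = x[keep]
    if (x == 1).sum() < 2 or (x == 0).sum() < 2:
        raise ValueError("need >=2 samples on each side of the contrast")
    y = bundle.counts.to_numpy(dtype=float)
    sf = size_factors(bundle.counts).to_numpy()
    offset = np.log(sf)
    norm = y / sf[None, :]
    if dispersions is None:
        disp = estimate_dispersions(norm, sf, groups=x)
        alpha_final = disp.final
    else:
        alpha_final = np.broadcast_to(
            np.asarray(dispersions, dtype=float), (y.shape[0],)).copy()
        disp = DispersionModel(alpha_final, alpha_final, alpha_final, (0, 0))
    b0, b1, se1, conv, mu = _nb_irls(y, x, offset, alpha_final)

    # count-outlier rule: a gene is masked when its worst squared Pearson
    # residual exceeds outlier_mult x the median worst-residual across
    # genes; comparing extremes to the typical extreme keeps the flag rate
    # at the rare-outlier level (a matrix-wide median would mask ~20%)
    pearson2 = (y - mu) ** 2 / (mu * (1.0 + alpha_final[:, None] * mu))
    worst = pearson2.max(axis=1)
    cut = outlier_mult * np.median(worst)
    outlier = worst > cut
    tested = conv & ~outlier & np.isfinite(se1) & (se1 > 0)
    n_bad = int((~conv).sum())
    if n_bad:
        log.info("nb_wald: %d genes failed to converge; flagged untested",
                 n_bad)

    ln2 = np.log(2.0)
    lfc = b1 / ln2
    se = se1 / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = b1 / se1
    # t reference with ~2(n-2) df: the moderated dispersion blends the
    # per-gene estimate (n-2 df) with the trend at equal weight, so the
    # plug-in uncertainty corresponds to roughly twice the per-gene df.
    # A plain normal tail is anti-conservative at these sample sizes.
    df_t = 2 * (len(x) - 2)
    p = 2.0 * stats.t.sf(np.abs(wald), df=df_t)
    p = np.where(tested, p, np.nan)
    padj = np.full_like(p, np.nan)
    padj[tested] = bh_adjust(p[tested])

    lfc_out = lfc.copy()
    if shrink_lfc:
        # prior scale from the upper tail of the raw effects: on a mostly
        # null genome a central quantile would collapse real fold changes
        ok = tested & np.isfinite(lfc)
        prior_sd = np.quantile(np.abs(lfc[ok]), 0.99) if ok.any() else 1.0
        prior_sd = max(prior_sd, 1e-3)
        shrunk = lfc * prior_sd**2 / (prior_sd**2 + se**2)
        lfc_out = np.where(tested, shrunk, lfc)

    table = pd.DataFrame({
        "log2fc": lfc_out, "log2fc_raw": lfc, "se": se, "stat": wald,
        "p": p, "padj": padj, "base_mean": norm.mean(axis=1),
        "tested": tested}, index=bundle.genes)
    return DEResult(table, shrunk=shrink_lfc,
                    extras={"dispersion": disp, "size_factors": sf})


def independent_filter(de: DEResult, alpha: float = 0.05,
                       quantile_grid=None) -> DEResult:
    """Choose a base-mean lower-quantile cut maximizing discoveries
    (padj <= alpha after re-adjusting on the retained genes); genes below
    the cut become untested.

    The threshold is the smallest quantile whose discovery count reaches a
    lowess-smoothed maximum minus one residual SD (the reference
    convention): a noisy flat discovery curve leaves the data unfiltered,
    while a genuine gain from removing low-count noise is taken.
    """
    if quantile_grid is None:
        quantile_grid = np.linspace(0.0, 0.95, 20)
    quantile_grid = np.asarray(quantile_grid, dtype=float)
    t = de.table
    tested = t["tested"].to_numpy(dtype=bool)
    bm = t["base_mean"].to_numpy()
    p = t["p"].to_numpy()
    n_disc, keeps = [], []
    for q in quantile_grid:
        thr = np.quantile(bm[tested], q) if tested.any() else 0.0
        keep = tested & (bm >= thr)
        if keep.sum() == 0:
            continue
        padj = bh_adjust(p[keep])
        n_disc.append(int((padj <= alpha).sum()))
        keeps.append(keep)
    if not keeps:
        best_keep = tested
    elif len(keeps) == 1:
        best_keep = keeps[0]
    else:
        import statsmodels.api as sm
        nd = np.asarray(n_disc, dtype=float)
        grid = quantile_grid[: len(nd)]
        smooth = sm.nonparametric.lowess(nd, grid, frac=0.5,
                                         return_sorted=False)
        resid_sd = float(np.sqrt(np.mean((nd - smooth) ** 2)))
        if smooth.max() - nd[0] <= max(1.0, resid_sd):
            best_keep = keeps[0]  # no meaningful gain: leave unfiltered
        else:
            thresh = min(smooth.max() - resid_sd, nd.max())
            best_keep = keeps[int(np.nonzero(nd >= thresh)[0][0])]
    out = t.copy()
    out["tested"] = best_keep
    padj = np.full(len(out), np.nan)
    if best_keep.any():
        padj[best_keep] = bh_adjust(p[best_keep])
    out["padj"] = padj
    return DEResult(out, shrunk=de.shrunk, extras=dict(de.extras))


# ---------------------------------------------------------------------------
# Linear mixed model LRT
# ---------------------------------------------------------------------------

def lmm_lrt(values, fixed, random, random2=None) -> LmmFit:
    """Likelihood-ratio test of a fixed factor in a random-intercept LMM.

    Fits full (values ~ fixed + (1|random) [+ (1|random2)]) and null
    (same without the fixed factor) by maximum likelihood; the LRT p comes
    from chi^2 with df = added fixed-effect columns.  ``fixed`` may be a
    binary/str factor or a numeric covariate.  The crossed two-factor case
    delegates to statsmodels MixedLM variance components.
    """
    y = np.asarray(values, dtype=float)
    fixed = np.asarray(fixed)
    if fixed.dtype.kind in "OUSb":
        levels = pd.unique(fixed)
        if len(levels) < 2:
            raise ValueError("fixed factor needs >=2 levels")
        dummies = pd.get_dummies(pd.Categorical(fixed), drop_first=True)
        Xf = dummies.to_numpy(dtype=float)
    else:
        Xf = fixed.reshape(len(fixed), -1).astype(float)
    X_full = np.column_stack([np.ones(len(y)), Xf])
    X_null = np.ones((len(y), 1))
    df = X_full.shape[1] - X_null.shape[1]

    if random2 is None:
        beta, se, ll_full, s2, s2b, bd = fit_lmm_ml(y, X_full, random)
        beta0, se0, ll_null, *_ = fit_lmm_ml(y, X_null, random)
        re_var = {"random": s2b}
        boundary = bd
    else:
        beta, se, ll_full, s2, re_var, boundary = _crossed_lmm(
            y, X_full, random, random2)
        _, _, ll_null, _, _, _ = _crossed_lmm(y, X_null, random, random2)
    stat = 2.0 * (ll_full - ll_null)
    if stat < -1e-6:
        warnings.warn(f"negative LRT statistic {stat:.3g}; clipped to 0",
                      stacklevel=2)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=df))
    return LmmFit(beta=np.asarray(beta), se=np.asarray(se), re_var=re_var
                  if isinstance(re_var, dict) else {"random": re_var},
                  sigma2=s2, loglik_full=ll_full, loglik_null=ll_null,
                  lrt_stat=stat, df=df, p=p, boundary=boundary)


def _crossed_lmm(y, X, g1, g2):
    """Two crossed random intercepts via statsmodels variance components."""
    import statsmodels.api as sm
    n = len(y)
    df = pd.DataFrame({"y": y, "g1": np.asarray(g1).astype(str),
                       "g2": np.asarray(g2).astype(str),
                       "one": np.ones(n)})
    for j in range(1, X.shape[1]):
        df[f"x{j}"] = X[:, j]
    exog = df[["one"] + [f"x{j}" for j in range(1, X.shape[1])]].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df["y"].to_numpy(), exog,
                           groups=np.zeros(n, dtype=int),
                           exog_vc=_vc_design(df),
                           use_sqrt=True)
        model.exog_vc_names = ["g1", "g2"]
        fit = model.fit(reml=False, method="lbfgs", maxiter=200)
    beta = fit.fe_params
    se = fit.bse_fe
    re_var = {"g1": float(fit.vcomp[0] * fit.scale),
              "g2": float(fit.vcomp[1] * fit.scale)}
    return (np.asarray(beta), np.asarray(se), float(fit.llf),
            float(fit.scale), re_var, not fit.converged)


def _vc_design(df):
    from statsmodels.regression.mixed_linear_model import VCSpec
    d1 = pd.get_dummies(df["g1"]).to_numpy(dtype=float)
    d2 = pd.get_dummies(df["g2"]).to_numpy(dtype=float)
    names = ["g1", "g2"]
    colnames = [[list(pd.get_dummies(df["g1"]).columns)],
                [list(pd.get_dummies(df["g2"]).columns)]]
    mats = [[d1], [d2]]
    return VCSpec(names, colnames, mats)


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix):
    """Force every column to the common distribution given by the row-wise
    mean of the sorted columns; ties share the mean of their quantiles."""
    from .orthology import NormalizedMatrix
    if isinstance(matrix, NormalizedMatrix):
        vals, wrap, unit = matrix.values, True, matrix.unit
    else:
        vals, wrap, unit = pd.DataFrame(matrix), False, None
    arr = vals.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("quantile normalization requires complete data")
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    ref = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    ranks = np.empty_like(order)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = np.arange(n)
        out[:, j] = ref[ranks[:, j]]
        # ties share the mean of their would-be quantiles
        col = arr[:, j]
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=out[:, j])
            cnts = np.bincount(inv)
            out[:, j] = (sums / cnts)[inv]
    res = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    if wrap:
        return NormalizedMatrix(res, unit)
    return res
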