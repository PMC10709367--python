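"""Expression-matched background machinery.

Everything that compares a gene program against "random genes of similar
expression": equal-frequency expression binning, matched sampling without
replacement, single-cell module scores with mixed-model condition tests,
probability-weighting-function (PWF) + Wallenius noncentral hypergeometric
overrepresentation, the accessibility studentized bootstrap, and pairwise
Fisher exact tests on per-comparison hit counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import betaln
from sklearn.isotonic import IsotonicRegression

from ._stats import LmmFit, bh_adjust
from .study_de import DEResult, lmm_lrt

log = logging.getLogger("coreinflam")


# ---------------------------------------------------------------------------
# Binning and matched sampling
# ---------------------------------------------------------------------------

@dataclass
class BinAssignment:
    """Equal-frequency expression bins over a gene universe.

    ``bins`` maps gene -> bin index in {0..B-1}; ``members`` lists the genes
    of each bin in stable gene-id order.
    """

    bins: pd.Series
    members: list
    B: int

    def profile(self, genes) -> np.ndarray:
        """Per-bin counts of the given genes."""
        counts = np.zeros(self.B, dtype=int)
        idx = self.bins.reindex([g for g in genes if g in self.bins.index])
        for b in idx.dropna().astype(int):
            counts[b] += 1
        return counts


def bin_by_expression(mean_expr: pd.Series, B: int = 25) -> BinAssignment:
    """Assign genes to B equal-frequency bins by the rank of their mean
    expression; ties broken by stable gene-id order, bin sizes differ by
    at most one."""
    if B < 1:
        raise ValueError("B must be >= 1")
    ser = pd.Series(mean_expr).astype(float)
    if len(ser) < B:
        raise ValueError(f"need at least B={B} genes, got {len(ser)}")
    order = ser.reset_index(drop=True)
    key = np.lexsort((np.asarray(ser.index, dtype=object),
                      order.to_numpy()))
    n = len(ser)
    sizes = np.full(B, n // B)
    sizes[: n % B] += 1
    bin_ids = np.repeat(np.arange(B), sizes)
    bins = pd.Series(index=ser.index[key], data=bin_ids, name="bin")
    bins = bins.reindex(ser.index)
    members = [list(bins.index[bins.to_numpy() == b]) for b in range(B)]
    return BinAssignment(bins, members, B)


def sample_matched(bins: BinAssignment, target, exclude_target: bool = True,
                   rng_seed: int = 0, rng=None) -> list:
    """Draw a random gene set with exactly the target's per-bin profile.

    Sampling is without replacement within each bin (excluding the target
    genes when requested); an exhausted bin falls back to sampling with
    replacement, with a warning.  Deterministic per seed.
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    target = set(target)
    prof = bins.profile(target)
    out = []
    for b, need in enumerate(prof):
        if need == 0:
            continue
        pool = bins.members[b]
        if exclude_target:
            pool = [g for g in pool if g not in target]
        if len(pool) >= need:
            pick = rng.choice(len(pool), size=need, replace=False)
        else:
            warnings.warn(f"bin {b} exhausted ({len(pool)} < {need}); "
                          "sampling with replacement", stacklevel=2)
            if not pool:  # nothing left outside the target: reuse the bin
                pool = bins.members[b]
            pick = rng.choice(len(pool), size=need, replace=True)
        out.extend(pool[i] for i in pick)
    return out


# ---------------------------------------------------------------------------
# Single-cell module score + condition test
# ---------------------------------------------------------------------------

@dataclass
class ModuleScore:
    """Per-cell program score: mean expression over the program genes minus
    the mean over the pooled expression-matched control genes."""

    scores: pd.Series
    scores_capped: pd.Series
    program: list
    controls: list
    seed: int


def module_score(cells: pd.DataFrame, program, B: int = 25,
                 ctrl_size: int = 50, rng_seed: int = 0,
                 cap_quantiles=(0.05, 0.95)) -> ModuleScore:
    """Score each cell for a gene program against matched controls.

    ``cells`` is a cells x genes log-normalized matrix.  Gene means over all
    cells are cut into B equal-frequency bins; for each program gene,
    ctrl_size control genes are drawn from its bin (program genes excluded);
    the score is mean(program) - mean(pooled controls) per cell.  The capped
    copy (for display) clips at the given score quantiles; the raw score is
    retained.
    """
    present = [g for g in program if g in cells.columns]
    dropped = len(list(program)) - len(present)
    if dropped:
        log.info("module_score: %d program genes absent from the matrix",
                 dropped)
    if len(present) < 2:
        raise ValueError("fewer than 2 program genes present in the matrix")
    gene_means = cells.mean(axis=0)
    bins = bin_by_expression(gene_means, B=B)
    rng = np.random.default_rng(rng_seed)
    controls: list = []
    pset = set(present)
    for g in present:
        b = int(bins.bins[g])
        pool = [x for x in bins.members[b] if x not in pset]
        k = min(ctrl_size, len(pool))
        if k < ctrl_size:
            warnings.warn(f"bin {b}: only {k} control genes available",
                          stacklevel=2)
        pick = rng.choice(len(pool), size=k, replace=False)
        controls.extend(pool[i] for i in pick)
    controls = sorted(set(controls))
    score = cells[present].mean(axis=1) - cells[controls].mean(axis=1)
    lo, hi = score.quantile(cap_quantiles[0]), score.quantile(cap_quantiles[1])
    return ModuleScore(score, score.clip(lo, hi), present, controls, rng_seed)


def score_condition_test(scores: ModuleScore, condition, sample_id,
                         extra_random=None, contrast=None) -> LmmFit:
    """Mixed-model test of a condition effect on per-cell module scores.

    Fits score ~ condition + (1|sample) [+ (1|extra_random)] against the
    null without condition, one model per control-vs-condition contrast.
    ``contrast=(control, treated)`` restricts to those two arms.
    """
    cond = pd.Series(np.asarray(condition), index=scores.scores.index)
    samp = pd.Series(np.asarray(sample_id), index=scores.scores.index)
    y = scores.scores
    if contrast is not None:
        keep = cond.isin(contrast)
        y, cond, samp = y[keep], cond[keep], samp[keep]
        if extra_random is not None:
            extra_random = pd.Series(np.asarray(extra_random),
                                     index=scores.scores.index)[keep]
        order = list(contrast)
        cond = pd.Categorical(cond, categories=order)
        cond = pd.Series(cond.astype(str), index=y.index)
    for arm in pd.unique(cond):
        if samp[cond == arm].nunique() < 2:
            raise ValueError(
                f"condition arm {arm!r} has a single sample; the random "
                "intercept is inestimable")
    return lmm_lrt(y.to_numpy(), cond.to_numpy(), samp.to_numpy(),
                   None if extra_random is None else np.asarray(extra_random))


# ---------------------------------------------------------------------------
# PWF + Wallenius overrepresentation
# ---------------------------------------------------------------------------

def pwf_fit(de_flag: pd.Series, bias: pd.Series, eps: float = 1e-4) -> pd.Series:
    """Probability weighting function: isotonic regression of the DE
    indicator on the rank of the bias covariate, clipped to (eps, 1-eps).

    Constant bias degenerates to the constant mean(de_flag)."""
    flag = pd.Series(de_flag).astype(float)
    b = pd.Series(bias).reindex(flag.index).astype(float)
    if flag.nunique() < 2:
        warnings.warn("de_flag has a single class; PWF is constant",
                      stacklevel=2)
    if b.nunique() == 1:
        return pd.Series(np.clip(flag.mean(), eps, 1 - eps),
                         index=flag.index, name="pwf")
    r = b.rank(method="average").to_numpy()
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(r, flag.to_numpy())
    return pd.Series(np.clip(fitted, eps, 1 - eps), index=flag.index,
                     name="pwf")


@dataclass
class WalleniusParams:
    n1: int          # genes in the category
    n2: int          # genes outside it
    k_draw: int      # number of DE genes drawn
    x_obs: int       # DE genes inside the category
    w: float         # odds = mean PWF(category) / mean PWF(complement)

    def __post_init__(self):
        if not (0 <= self.x_obs <= min(self.n1, self.k_draw)):
            raise ValueError("x_obs outside [0, min(n1, k_draw)]")
        if self.w <= 0:
            raise ValueError("odds must be positive")


def wallenius_pmf(params: WalleniusParams) -> np.ndarray:
    """Wallenius noncentral hypergeometric pmf over the full support,
    by the standard single-integral representation (adaptive quadrature),
    renormalized to sum 1."""
    n1, n2, k, w = params.n1, params.n2, params.k_draw, params.w
    lo = max(0, k - n2)
    hi = min(n1, k)
    xs = np.arange(lo, hi + 1)
    pmf = np.empty(len(xs))
    for i, x in enumerate(xs):
        D = w * (n1 - x) + (n2 - (k - x))
        lbin = (-betaln(x + 1, n1 - x + 1) - np.log(n1 + 1)
                - betaln(k - x + 1, n2 - (k - x) + 1) - np.log(n2 + 1))

        # integral_0^1 (1 - t^{w/D})^x (1 - t^{1/D})^{k-x} dt after the
        # substitution t = u^D, which tames the boundary behavior:
        def integrand(u, x=x, D=D):
            with np.errstate(divide="ignore", invalid="ignore"):
                la = x * np.log1p(-np.power(u, w))
                lb = (k - x) * np.log1p(-u)
                lj = np.log(D) + (D - 1.0) * np.log(u)
            return np.exp(la + lb + lj + lbin)

        # the u^(D-1) kernel spikes within ~1/D of u=1; give the adaptive
        # rule explicit breakpoints there
        pts = sorted({1.0 - 10.0 ** (-j) for j in range(1, 9)} | {0.5})
        val, _ = integrate.quad(integrand, 0.0, 1.0, limit=400, points=pts)
        pmf[i] = val
    total = pmf.sum()
    if not np.isfinite(total) or abs(total - 1.0) > 0.2:
        # quadrature trouble; fall back to a normal approximation
        warnings.warn("Wallenius quadrature unstable; using normal "
                      "approximation", stacklevel=2)
        return None
    return pmf / total


def wallenius_test(params: WalleniusParams) -> dict:
    """Over- and under-representation tails of the Wallenius distribution.

    p_over = P(X >= x_obs), p_under = P(X <= x_obs).  Falls back to a
    moment-matched normal approximation if the quadrature fails (flagged).
    """
    pmf = wallenius_pmf(params)
    lo = max(0, params.k_draw - params.n2)
    if pmf is not None:
        idx = params.x_obs - lo
        p_over = float(pmf[idx:].sum())
        p_under = float(pmf[: idx + 1].sum())
        return {"p_over": min(p_over, 1.0), "p_under": min(p_under, 1.0),
                "method": "quadrature"}
    mean, var = _wallenius_moments(params)
    z_over = (params.x_obs - 0.5 - mean) / np.sqrt(var)
    z_under = (params.x_obs + 0.5 - mean) / np.sqrt(var)
    return {"p_over": float(stats.norm.sf(z_over)),
            "p_under": float(stats.norm.cdf(z_under)),
            "method": "normal_approx"}


def _wallenius_moments(params: WalleniusParams):
    n1, n2, k, w = params.n1, params.n2, params.k_draw, params.w
    # solve mean from the implicit Wallenius mean equation by fixed point
    mu = k * n1 * w / (n1 * w + n2)
    for _ in range(200):
        mu_new = n1 * (1 - np.exp(w * np.log1p(-(k - mu) / n2))
                       if n2 > k - mu else 1.0)
        mu = 0.5 * mu + 0.5 * np.clip(mu_new, 0, min(n1, k))
    var = max(mu * (1 - mu / n1) * (1 - mu / k), 1e-8)
    return mu, var


def overrepresentation_analysis(de: DEResult, category, bias=None,
                                fdr: float = 0.05, lfc_min: float = 1.0,
                                direction: str = "up",
                                n_matched: int = 1000,
                                rng_seed: int = 0,
                                n_bins: int = 25) -> dict:
    """PWF-weighted (Wallenius) overrepresentation of a gene category among
    DE genes, plus an empirical expression-matched sampling check.

    DE genes: padj <= fdr and |log2FC| >= lfc_min (restricted to the
    requested direction).  The universe is the tested genes; ``bias``
    defaults to base_mean.  The empirical check redraws the category
    n_matched times with matched expression profile and reports the
    percentile of the observed DE overlap.
    """
    t = de.table[de.tested].copy()
    if bias is None:
        bias = t["base_mean"]
    bias = pd.Series(bias).reindex(t.index)
    lfc = t["log2fc"]
    sig = (t["padj"] <= fdr) & (lfc.abs() >= lfc_min)
    if direction == "up":
        sig &= lfc > 0
    elif direction == "down":
        sig &= lfc < 0
    de_flag = sig.astype(int)
    cat = pd.Index(sorted(set(category) & set(t.index)))
    if len(cat) == 0 or len(cat) == len(t):
        raise ValueError("category must be a non-empty proper subset of "
                         "the tested universe")
    if de_flag.sum() == 0:
        warnings.warn("no DE genes at the stated definition", stacklevel=2)
        return {"params": None, "p_over": 1.0, "p_under": 1.0,
                "x_obs": 0, "empirical_percentile": np.nan}
    pwf = pwf_fit(de_flag, bias)
    in_cat = t.index.isin(cat)
    w = float(pwf[in_cat].mean() / pwf[~in_cat].mean())
    params = WalleniusParams(n1=int(in_cat.sum()),
                             n2=int((~in_cat).sum()),
                             k_draw=int(de_flag.sum()),
                             x_obs=int(de_flag[in_cat].sum()), w=w)
    res = wallenius_test(params)
    # empirical matched-sampling check
    bins = bin_by_expression(bias, B=min(n_bins, max(1, len(t) // 2)))
    rng = np.random.default_rng(rng_seed)
    draws = np.empty(n_matched)
    flag_set = set(t.index[de_flag.astype(bool)])
    for b in range(n_matched):
        samp = sample_matched(bins, cat, exclude_target=False, rng=rng)
        draws[b] = len(flag_set.intersection(samp))
    pct = float(np.mean(draws < params.x_obs)
                + 0.5 * np.mean(draws == params.x_obs))
    return {"params": params, "p_over": res["p_over"],
            "p_under": res["p_under"], "method": res["method"],
            "x_obs": params.x_obs, "odds": w,
            "matched_draws": draws, "empirical_percentile": pct}


# ---------------------------------------------------------------------------
# Accessibility bootstrap + pairwise Fisher
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    s_obs: int
    boot_mean: float
    boot_sd: float
    z: float
    p: float
    n_boot: int
    seed: int
    method: str = "studentized_normal"
    draws: np.ndarray = field(default=None, repr=False)


def accessibility_bootstrap(program, labels: pd.Series, bins: BinAssignment,
                            n_boot: int = 1000, rng_seed: int = 0,
                            count_both: bool = True) -> BootstrapResult:
    """Studentized bootstrap of a program's accessibility-increase count
    against expression-matched random gene sets.

    s_obs counts program genes labeled "increase" (plus "both" when
    count_both); n_boot matched sets give the null mean/sd; the two-sided p
    comes from the normal tail of z = (s_obs - mean)/sd.  sd = 0 falls back
    to the Monte-Carlo percentile (flagged).
    """
    labels = pd.Series(labels)
    hit_labels = {"increase", "both"} if count_both else {"increase"}
    hits = set(labels.index[labels.isin(hit_labels)])
    program = [g for g in program if g in bins.bins.index]
    s_obs = len(hits.intersection(program))
    rng = np.random.default_rng(rng_seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        samp = sample_matched(bins, program, exclude_target=True, rng=rng)
        draws[b] = len(hits.intersection(samp))
    mu, sd = float(draws.mean()), float(draws.std(ddof=1))
    if sd == 0:
        warnings.warn("bootstrap sd is 0; reporting Monte-Carlo percentile",
                      stacklevel=2)
        pct = float(np.mean(draws >= s_obs))
        return BootstrapResult(s_obs, mu, sd, np.nan, max(pct, 1.0 / n_boot),
                               n_boot, rng_seed, "mc_percentile", draws)
    z = (s_obs - mu) / sd
    p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    p = max(p, np.finfo(float).tiny)
    return BootstrapResult(s_obs, mu, sd, float(z), p, n_boot, rng_seed,
                           "studentized_normal", draws)


def pairwise_fisher(counts: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Fisher exact tests between all comparison pairs.

    ``counts`` has one row per comparison with columns x (hits) and n
    (totals); each pair (i, j) is tested on [[x_i, n_i - x_i],
    [x_j, n_j - x_j]].  Returns a long table with OR, p and BH-adjusted p.
    """
    if not {"x", "n"}.issubset(counts.columns):
        raise ValueError("counts needs columns 'x' and 'n'")
    if (counts["x"] > counts["n"]).any():
        raise ValueError("x exceeds n")
    ids = list(counts.index)
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            xi, ni = int(counts.loc[ids[a], "x"]), int(counts.loc[ids[a], "n"])
            xj, nj = int(counts.loc[ids[b], "x"]), int(counts.loc[ids[b], "n"])
            table = np.array([[xi, ni - xi], [xj, nj - xj]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                rows.append({"i": ids[a], "j": ids[b], "odds_ratio": np.nan,
                             "p": 1.0})
                continue
            orr, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append({"i": ids[a], "j": ids[b], "odds_ratio": orr,
                         "p": float(p)})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out
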