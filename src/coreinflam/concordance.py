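"""Replicability and cross-study concordance statistics.

Implements the Storey pi0/pi1 estimator (smoothing-spline variant, with the
truncated-p rescaling used when the input p-values were preselected below a
cutoff), pairwise replicability matrices between DE comparisons, log2FC
correlation matrices, and a preranked gene-set enrichment statistic with a
gene-permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .core_io import GeneSetCollection
from .study_de import DEResult


# ---------------------------------------------------------------------------
# Storey pi1 with natural cubic smoothing spline (effective df = 3)
# ---------------------------------------------------------------------------

def _gs_penalty(knots: np.ndarray):
    """Green-Silverman K = Q R^-1 Q' penalty matrix for a natural cubic
    smoothing spline on the given knots."""
    n = len(knots)
    h = np.diff(knots)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        c = j - 1
        Q[j - 1, c] = 1.0 / h[j - 1]
        Q[j, c] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, c] = 1.0 / h[j]
        R[c, c] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[c, c + 1] = R[c + 1, c] = h[j] / 6.0
    K = Q @ np.linalg.solve(R, Q.T)
    return K


def _smooth_spline_df(x: np.ndarray, y: np.ndarray, target_df: float = 3.0):
    """Fit f = argmin ||y-f||^2 + rho f'Kf with rho chosen so that
    tr((I+rho K)^-1) equals target_df; returns fitted values at the knots."""
    K = _gs_penalty(x)
    eye = np.eye(len(x))

    def df_of(log_rho):
        S = np.linalg.inv(eye + np.exp(log_rho) * K)
        return np.trace(S)

    lo, hi = -20.0, 25.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if df_of(mid) > target_df:
            lo = mid  # more penalty needed to reduce df
        else:
            hi = mid
    rho = np.exp(0.5 * (lo + hi))
    fhat = np.linalg.solve(eye + rho * K, y)
    return fhat


@dataclass
class Pi1Result:
    pi0: float
    pi1: float
    lambdas: np.ndarray
    pi0_curve: np.ndarray
    truncation: float = 1.0
    smoothing: str = "natural cubic smoothing spline, df=3, eval at max lambda"


def storey_pi1(p, lambdas=None, truncation: float = 1.0) -> Pi1Result:
    """Estimate pi1 = 1 - pi0 from a p-value collection.

    With truncation < 1 the p-values are assumed preselected to [0, trunc]
    and rescaled p' = p/trunc first (the truncated-p variant).  pi0(lambda)
    = #{p' > lambda} / (m (1-lambda)) is smoothed over the lambda grid with
    a natural cubic smoothing spline (df 3) and read off at the largest
    lambda, then clamped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    m = p.size
    if m < 100:
        warnings.warn(f"only {m} p-values; pi1 estimate unstable",
                      stacklevel=2)
    if not 0 < truncation <= 1:
        raise ValueError("truncation must lie in (0, 1]")
    if m and p.max() > truncation + 1e-12:
        raise ValueError("p-values exceed the stated truncation point")
    ps = p / truncation
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_curve = np.array([(ps > lam).sum() / (m * (1.0 - lam))
                          for lam in lambdas]) if m else np.full(len(lambdas), np.nan)
    if m == 0:
        return Pi1Result(np.nan, np.nan, lambdas, pi0_curve, truncation)
    fhat = _smooth_spline_df(lambdas, pi0_curve, target_df=3.0)
    pi0 = float(np.clip(fhat[-1], 0.0, 1.0))
    return Pi1Result(pi0, 1.0 - pi0, lambdas, pi0_curve, truncation)


# ---------------------------------------------------------------------------
# Pairwise replicability and LFC correlation
# ---------------------------------------------------------------------------

def _unit_ids(de_list):
    ids = []
    for i, de in enumerate(de_list):
        if "comparison_id" in de.table.columns:
            ids.append(str(de.table["comparison_id"].iloc[0]))
        else:
            ids.append(f"unit{i}")
    return ids


def pairwise_replicability(de_list: list[DEResult], alpha: float = 0.05,
                           min_overlap: int = 100) -> pd.DataFrame:
    """pi1 matrix: entry (i, j) is the estimated fraction of unit i's
    significant genes (padj <= alpha) that are non-null in unit j, from
    their raw p-values in j.  Diagonal and underpowered entries are NaN."""
    if len(de_list) < 2:
        raise ValueError("need at least two comparisons")
    ids = _unit_ids(de_list)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    for i, di in enumerate(de_list):
        sig = di.significant(alpha)
        if len(sig) == 0:
            continue
        for j, dj in enumerate(de_list):
            if i == j:
                continue
            tj = dj.table
            shared = sig.intersection(tj.index[dj.tested])
            if len(shared) < min_overlap:
                warnings.warn(
                    f"pi1({ids[i]},{ids[j]}): only {len(shared)} shared "
                    "genes; entry left missing", stacklevel=2)
                continue
            res = storey_pi1(tj.loc[shared, "p"].to_numpy(), truncation=1.0)
            mat.iloc[i, j] = res.pi1
    return mat


def lfc_correlation(de_list: list[DEResult]) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of log2FC across comparisons."""
    ids = _unit_ids(de_list)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    for i, di in enumerate(de_list):
        ti = di.table
        for j, dj in enumerate(de_list):
            if j < i:
                continue
            tj = dj.table
            shared = ti.index[di.tested].intersection(tj.index[dj.tested])
            if len(shared) < 3:
                continue
            a = ti.loc[shared, "log2fc"].to_numpy()
            b = tj.loc[shared, "log2fc"].to_numpy()
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            mat.iloc[i, j] = mat.iloc[j, i] = r
    return mat


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class GseaResult:
    table: pd.DataFrame
    leading_edge: dict = field(default_factory=dict)
    n_perm: int = 0
    seed: int = 0


def _es_from_positions(pos, absr, w, N):
    """Enrichment score given sorted 0-based hit positions in a ranked list.

    The running sum increments by |r|^w / sum_hits |r|^w at hits and
    decrements by 1/(N - Nh) at misses; candidates for the extremum are the
    values just before and just after each hit.
    """
    h = len(pos)
    if h == 0 or h == N:
        return 0.0, -1
    hitw = absr[pos] ** w
    tot = hitw.sum()
    if tot == 0:
        hitw = np.ones(h)
        tot = float(h)
    cw = np.cumsum(hitw) / tot
    d = 1.0 / (N - h)
    k = np.arange(1, h + 1)
    after = cw - (pos + 1 - k) * d
    before = np.concatenate([[0.0], cw[:-1]]) - (pos - (k - 1)) * d
    cands = np.concatenate([after, before])
    i = int(np.argmax(np.abs(cands)))
    es = float(cands[i])
    peak = int(pos[i % h]) if es > 0 else int(pos[i % h])
    return es, peak


def gsea_preranked(ranks, sets: GeneSetCollection, n_perm: int = 1000,
                   weight_exponent: float = 1.0, seed: int = 0,
                   min_size: int = 15, max_size: int = 500) -> GseaResult:
    """Preranked gene-set enrichment with a random-gene-set null.

    ``ranks`` maps gene -> metric (e.g. log2FC); genes are ranked by
    decreasing metric.  ES is the extremum of the weighted running sum;
    NES = ES / mean(|ES_perm| of matching sign); nominal p from the same
    sign-matched permutation ES values; BH across sets.  Deterministic for
    a given seed.
    """
    ser = pd.Series(ranks).astype(float).dropna()
    ser = ser.sort_values(ascending=False, kind="stable")
    genes = ser.index.to_numpy()
    absr = np.abs(ser.to_numpy())
    N = len(genes)
    index_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows, le = [], {}
    for name, members in sets.items():
        pos = np.array(sorted(index_of[g] for g in members if g in index_of))
        if len(pos) == 0:
            warnings.warn(f"set {name!r} entirely outside the ranked "
                          "universe; skipped", stacklevel=2)
            continue
        h = len(pos)
        if h < min_size or h > max_size:
            continue
        es, peak = _es_from_positions(pos, absr, weight_exponent, N)
        es_perm = np.empty(n_perm)
        for b in range(n_perm):
            rpos = np.sort(rng.choice(N, size=h, replace=False))
            es_perm[b], _ = _es_from_positions(rpos, absr, weight_exponent, N)
        same = es_perm[np.sign(es_perm) == np.sign(es)] if es != 0 else es_perm
        if len(same):
            nes = es / np.mean(np.abs(same))
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
        else:
            nes, p = np.nan, 1.0
        if es >= 0:
            lead = [g for g in genes[: peak + 1] if index_of[g] in set(pos)]
        else:
            lead = [g for g in genes[peak:] if index_of[g] in set(pos)]
        le[name] = lead
        rows.append({"set": name, "size": h, "es": es, "nes": nes, "p": p})
    tab = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p"])
    if len(tab):
        tab["padj"] = bh_adjust(tab["p"].to_numpy())
    return GseaResult(tab, le, n_perm, seed)
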