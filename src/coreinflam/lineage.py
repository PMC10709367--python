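"""One-vs-rest moderated linear-model DE on the merged lineage atlas,
marker selection, and the PCA / correlation / clustering summaries.

The DE engine is ordinary least squares per gene on [intercept, is_target]
with empirical-Bayes variance moderation: a scaled inverse-chi-square prior
(d0, s0^2) is moment-matched to the observed log residual variances (the
Smyth convention, via digamma/trigamma), the moderated t uses the pooled
variance with d + d0 degrees of freedom, and F = t^2 ranks the markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma

from ._stats import bh_adjust
from .core_io import StudyBundle
from .orthology import NormalizedMatrix


@dataclass
class ModeratedStats:
    """Per-gene moderated one-vs-rest statistics."""

    table: pd.DataFrame  # log2fc, s2, df, t, F, p, padj
    d0: float
    s0sq: float


@dataclass
class MarkerTable:
    """Lineage -> ordered marker list with F statistic and rank."""

    table: pd.DataFrame  # lineage, gene, F, rank

    def genes(self, lineage: str) -> list:
        sub = self.table[self.table["lineage"] == lineage]
        return list(sub.sort_values("rank")["gene"])

    def all_genes(self) -> list:
        seen, out = set(), []
        for g in self.table.sort_values(["lineage", "rank"])["gene"]:
            if g not in seen:
                seen.add(g)
                out.append(g)
        return out


# ---------------------------------------------------------------------------

def filter_expressed(bundle: StudyBundle, min_count: int = 10,
                     group_col: str = "lineage",
                     min_total: int = 15) -> StudyBundle:
    """Expression filter in the filterByExpr style: keep genes with
    count >= min_count (scaled by library size relative to the median
    library) in at least (smallest group size) samples, and with a total
    count >= min_total."""
    counts = bundle.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    med = np.median(lib)
    cutoff = min_count * lib / med  # per-sample scaled threshold
    groups = bundle.meta[group_col]
    min_group = int(groups.value_counts().min())
    n_pass = (counts >= cutoff[None, :]).sum(axis=1)
    keep = (n_pass >= min_group) & (counts.sum(axis=1) >= min_total)
    if keep.sum() == 0:
        raise ValueError("no genes pass the expression filter")
    return StudyBundle(bundle.counts.loc[keep], bundle.meta.copy())


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (Smyth's method)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_prior(s2: np.ndarray, df: int):
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    residual variances via the log-variance distribution."""
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    evar = np.var(e, ddof=1)
    excess = evar - polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(ebar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def onevsrest_de(matrix: NormalizedMatrix, lineage_labels: pd.Series,
                 target: str, d0_override: float | None = None) -> ModeratedStats:
    """Moderated two-group DE of one lineage against all the rest.

    OLS per gene on [intercept, is_target]; empirical-Bayes moderation of
    the residual variances; moderated t with d + d0 df; F = t^2; BH within
    the comparison.  ``d0_override=0`` reproduces the ordinary t test.
    """
    labels = lineage_labels.reindex(matrix.samples)
    x = (labels == target).to_numpy(dtype=float)
    n1, n0 = int(x.sum()), int((1 - x).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need >=2 samples on each side")
    n = n1 + n0
    df = n - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    Y = matrix.values.to_numpy(dtype=float)
    m1 = Y[:, x == 1].mean(axis=1)
    m0 = Y[:, x == 0].mean(axis=1)
    lfc = m1 - m0
    rss = (((Y[:, x == 1] - m1[:, None]) ** 2).sum(axis=1)
           + ((Y[:, x == 0] - m0[:, None]) ** 2).sum(axis=1))
    s2 = rss / df
    v = 1.0 / n1 + 1.0 / n0  # unscaled variance of the contrast

    d0, s0sq = (_fit_prior(s2, df) if d0_override is None
                else (d0_override, float(np.median(s2))))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = 1e6
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_post * v)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    tab = pd.DataFrame({"log2fc": lfc, "s2": s2, "df": df, "t": t,
                        "F": t**2, "p": p, "padj": bh_adjust(p)},
                       index=matrix.genes)
    return ModeratedStats(tab, float(d0), float(s0sq))


def select_markers(stats_by_lineage: dict, alpha: float = 0.05,
                   cap: int = 200) -> MarkerTable:
    """Per lineage: filter padj <= alpha and log2FC > 0, rank by descending
    F (ties by smaller padj then lexicographic gene id), truncate at cap."""
    rows = []
    for lineage, ms in stats_by_lineage.items():
        t = ms.table
        ok = t[(t["padj"] <= alpha) & (t["log2fc"] > 0)].copy()
        ok = ok.reset_index(names="gene")
        ok = ok.sort_values(["F", "padj", "gene"],
                            ascending=[False, True, True], kind="stable")
        ok = ok.head(cap)
        for r, (_, row) in enumerate(ok.iterrows(), start=1):
            rows.append({"lineage": lineage, "gene": row["gene"],
                         "F": row["F"], "rank": r})
    return MarkerTable(pd.DataFrame(rows,
                                    columns=["lineage", "gene", "F", "rank"]))


# ---------------------------------------------------------------------------
# PCA and correlation clustering
# ---------------------------------------------------------------------------

def pca_embed(matrix: NormalizedMatrix, features, k: int = 2):
    """PCA of the samples on the given feature genes via SVD.

    Returns (scores: samples x k DataFrame, explained variance fractions).
    Features are mean-removed across samples before decomposition.
    """
    feats = [g for g in features if g in matrix.genes]
    X = matrix.values.loc[feats].to_numpy(dtype=float).T  # samples x features
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if len(S) else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = U[:, :k] * S[:k]
    ev = S**2 / max((S**2).sum(), 1e-300)
    return (pd.DataFrame(scores, index=matrix.samples,
                         columns=[f"PC{i+1}" for i in range(k)]),
            ev[:k])


def correlation_cluster(matrix: NormalizedMatrix, features):
    """Sample-sample Pearson correlation over the feature genes, plus the
    leaf order of average-linkage hierarchical clustering on 1 - r."""
    feats = [g for g in features if g in matrix.genes]
    X = matrix.values.loc[feats].to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = list(matrix.samples[sds == 0])
        raise ValueError(f"zero-variance sample(s) over features: {bad}")
    R = np.corrcoef(X.T)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    dist = 1.0 - R
    iu = np.triu_indices_from(dist, k=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z = hierarchy.average(np.maximum(dist[iu], 0.0))
    order = hierarchy.leaves_list(Z)
    corr = pd.DataFrame(R, index=matrix.samples, columns=matrix.samples)
    return corr, [matrix.samples[i] for i in order]
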