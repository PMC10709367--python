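"""Orthology filtering, cross-species merging, normalization and the
five-category cross-species expression-profile classifier.

All composite cross-species computations run on one-to-one high-confidence
ortholog pairs; merged genes are keyed by the species-A (human-side) symbol.
Normalization offers log2(CPM + prior), log2(TPM + 1), and TMM-scaled CPM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fit_lmm_ml
from .core_io import StudyBundle

HOMOLOGY_CLASSES = ("one2one", "one2many", "many2many", "none")
_ORTHO_COLS = ["gene_a_id", "gene_a_symbol", "gene_b_id", "gene_b_symbol",
               "homology_class", "high_confidence"]


@dataclass
class OrthologyMap:
    """Gene-pair table bridging species A and B.

    Columns: gene_a_id, gene_a_symbol, gene_b_id, gene_b_symbol,
    homology_class in {one2one, one2many, many2many, none},
    high_confidence in {0, 1}.  Genes with class "none" have an empty
    partner side.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _ORTHO_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"orthology table lacks columns {missing}")
        bad = set(self.table["homology_class"]) - set(HOMOLOGY_CLASSES)
        if bad:
            raise ValueError(f"unknown homology classes {sorted(bad)}")
        pairs = self.table[["gene_a_id", "gene_b_id"]]
        if pairs.duplicated().any():
            dups = pairs[pairs.duplicated()].head().to_records(index=False)
            raise ValueError(f"duplicated gene pairs: {list(dups)}")

    @classmethod
    def from_tsv(cls, path) -> "OrthologyMap":
        tab = pd.read_csv(path, sep="\t", dtype={"high_confidence": int},
                          keep_default_na=False)
        return cls(tab)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __len__(self):
        return len(self.table)


def filter_orthologs(omap: OrthologyMap, classes={"one2one"},
                     confidence: str = "high") -> OrthologyMap:
    """Restrict the map to the requested homology classes and confidence.

    When only one2one pairs are requested the result must be bijective; a
    duplicated partner on either side is an error listing the offenders.
    """
    classes = set(classes)
    tab = omap.table
    tab = tab[tab["homology_class"].isin(classes)]
    if confidence == "high":
        tab = tab[tab["high_confidence"] == 1]
    tab = tab.reset_index(drop=True)
    if classes == {"one2one"}:
        for col in ("gene_a_symbol", "gene_b_symbol"):
            dup = tab[col][tab[col].duplicated()]
            if len(dup):
                raise ValueError(
                    f"one2one map not bijective; duplicated {col}: "
                    f"{sorted(set(dup))[:10]}")
    return OrthologyMap(tab)


def merge_cross_species(bundle_a: StudyBundle, bundle_b: StudyBundle,
                        omap: OrthologyMap) -> StudyBundle:
    """Merge two species' bundles on one-to-one orthologs.

    Rows are the mapped pairs keyed by the species-A symbol, sorted
    canonically; columns are the union of samples with species recorded in
    the metadata.
    """
    tab = filter_orthologs(omap, {"one2one"}, "high").table
    tab = tab[tab["gene_a_symbol"].isin(bundle_a.genes)
              & tab["gene_b_symbol"].isin(bundle_b.genes)]
    if tab.empty:
        raise ValueError("no mappable ortholog pairs between the bundles")
    tab = tab.sort_values("gene_a_symbol")
    a = bundle_a.counts.loc[tab["gene_a_symbol"]]
    b = bundle_b.counts.loc[tab["gene_b_symbol"]]
    b.index = a.index
    counts = pd.concat([a, b], axis=1)
    meta_a = bundle_a.meta.copy()
    meta_b = bundle_b.meta.copy()
    if "species" not in meta_a.columns:
        meta_a["species"] = "A"
    if "species" not in meta_b.columns:
        meta_b["species"] = "B"
    meta = pd.concat([meta_a, meta_b])
    return StudyBundle(counts, meta)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedMatrix:
    """Real-valued genes x samples matrix with an explicit unit tag."""

    values: pd.DataFrame
    unit: str  # log2cpm | log2tpm1 | centered
    factors: pd.Series | None = None

    @property
    def genes(self):
        return self.values.index

    @property
    def samples(self):
        return self.values.columns


def _ma_stats(ref, obs):
    """Per-gene M (log ratio), A (log abundance) and asymptotic variance of M
    for two library-scaled count columns; infinite entries masked."""
    n_r, n_o = ref.sum(), obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        p_r, p_o = ref / n_r, obs / n_o
        m = np.log2(p_o) - np.log2(p_r)
        a = 0.5 * (np.log2(p_o) + np.log2(p_r))
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (n_o - obs) / (n_o * obs) + (n_r - ref) / (n_r * ref)
    ok = np.isfinite(m) & np.isfinite(a)
    return m[ok], a[ok], v[ok]


def tmm_factors(counts, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1.

    Reference column: the sample whose 75th count percentile (of nonzero
    scale) is closest to the mean across samples.  M values are doubly
    trimmed (trim_m of M, trim_a of A) and averaged with inverse
    approximate-variance weights.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    mat = df.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    libsize = mat.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("all-zero sample(s): "
                         f"{list(df.columns[libsize == 0])}")
    uq = np.array([np.quantile(col[col > 0] / col.sum(), 0.75)
                   if (col > 0).any() else 0.0 for col in mat.T])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = mat[:, ref_idx]
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        m, a, v = _ma_stats(ref, mat[:, j])
        if m.size == 0:
            continue
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            continue
        w = 1.0 / v[keep]
        factors[j] = 2 ** (np.sum(w * m[keep]) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor")


def normalize(bundle: StudyBundle, method: str = "cpm",
              lengths: pd.Series | None = None,
              prior: float = 0.5) -> NormalizedMatrix:
    """Library-size normalization to log2(CPM + prior) or log2(TPM + 1).

    method="tmm_cpm" additionally divides library sizes by TMM factors.
    TPM requires positive per-gene lengths.
    """
    counts = bundle.counts.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("zero library size")
    if method in ("cpm", "tmm_cpm"):
        eff = libsize.copy()
        factors = None
        if method == "tmm_cpm":
            factors = tmm_factors(bundle.counts)
            eff = eff * factors.to_numpy()
        cpm = counts / eff * 1e6
        vals = np.log2(cpm + prior)
        unit = "log2cpm"
    elif method == "tpm":
        if lengths is None:
            raise ValueError("tpm requires per-gene lengths")
        lens = lengths.reindex(bundle.genes).to_numpy(dtype=float)
        if np.any(~np.isfinite(lens)) or np.any(lens <= 0):
            raise ValueError("tpm requires positive lengths for every gene")
        rate = counts / lens[:, None]
        tpm = rate / rate.sum(axis=0) * 1e6
        vals = np.log2(tpm + 1.0)
        unit = "log2tpm1"
        factors = None
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return NormalizedMatrix(
        pd.DataFrame(vals, index=bundle.genes, columns=bundle.samples),
        unit, factors)


def center_per_group(matrix: NormalizedMatrix, group: pd.Series) -> NormalizedMatrix:
    """Mean-center every gene within each sample group (e.g. species)."""
    if matrix.unit not in ("log2cpm", "log2tpm1", "centered"):
        raise ValueError("centering expects a log-scale matrix")
    import warnings
    vals = matrix.values.copy()
    g = group.reindex(vals.columns)
    for level, cols in vals.columns.groupby(g).items():
        if len(cols) == 1:
            warnings.warn(f"group {level!r} has a single sample; centers to 0",
                          stacklevel=2)
        sub = vals[cols]
        vals[cols] = sub.sub(sub.mean(axis=1), axis=0)
    return NormalizedMatrix(vals, "centered")


# ---------------------------------------------------------------------------
# Five-category cross-species profile classifier
# ---------------------------------------------------------------------------

CATEGORIES = ("high_both", "high_a_low_b", "high_b_low_a",
              "high_a_no_ortholog", "high_b_no_ortholog")


def classify_profiles(expr_a: NormalizedMatrix, expr_b: NormalizedMatrix,
                      omap: OrthologyMap,
                      lineage_specific_a, lineage_specific_b,
                      study_a: pd.Series | None = None,
                      study_b: pd.Series | None = None,
                      pct: float = 95.0, beta_min: float = 1.0,
                      alpha: float = 0.05,
                      joint_percentile: bool = False) -> pd.DataFrame:
    """Classify lineage-specific ortholog pairs into five cross-species
    expression profiles.

    Candidate pairs are the lineage-specific genes of either species mapped
    through high-confidence {one2one, one2many, many2many} relations, plus
    unmappable lineage-specific genes.  Each mapped pair is tested for a
    species effect with a random-intercept LMM on log2(TPM+1)
    (full: ~ species + (1|study); null: ~ (1|study)), BH-corrected over all
    tested pairs.  "High" means mean expression above the pct-th percentile
    of the candidate pool (per species by default).

    Returns a frame with pair_key, category, mean_a, mean_b, beta, p, padj.
    """
    la, lb = set(lineage_specific_a), set(lineage_specific_b)
    if not la and not lb:
        raise ValueError("no candidate lineage-specific genes")
    tab = omap.table
    mapped = tab[(tab["high_confidence"] == 1)
                 & tab["homology_class"].isin(("one2one", "one2many",
                                               "many2many"))]
    cand = mapped[(mapped["gene_a_symbol"].isin(la)
                   | mapped["gene_b_symbol"].isin(lb))
                  & mapped["gene_a_symbol"].isin(expr_a.genes)
                  & mapped["gene_b_symbol"].isin(expr_b.genes)]

    mappable_a = set(mapped["gene_a_symbol"])
    mappable_b = set(mapped["gene_b_symbol"])
    orphan_a = sorted((la - mappable_a) & set(expr_a.genes))
    orphan_b = sorted((lb - mappable_b) & set(expr_b.genes))

    if study_a is None:
        study_a = pd.Series("s0", index=expr_a.samples)
    if study_b is None:
        study_b = pd.Series("s1", index=expr_b.samples)

    rows = []
    va = expr_a.values
    vb = expr_b.values
    mean_a_all = va.mean(axis=1)
    mean_b_all = vb.mean(axis=1)
    for _, r in cand.iterrows():
        ga, gb = r["gene_a_symbol"], r["gene_b_symbol"]
        ya = va.loc[ga].to_numpy()
        yb = vb.loc[gb].to_numpy()
        y = np.concatenate([ya, yb])
        is_a = np.concatenate([np.ones_like(ya), np.zeros_like(yb)])
        X = np.column_stack([np.ones_like(y), is_a])
        groups = np.concatenate([study_a.to_numpy(), study_b.to_numpy()])
        beta, se, ll_full, *_ = fit_lmm_ml(y, X, groups)
        _, _, ll_null, *_ = fit_lmm_ml(y, X[:, :1], groups)
        from scipy.stats import chi2
        stat = max(0.0, 2 * (ll_full - ll_null))
        p = float(chi2.sf(stat, df=1))
        rows.append({"pair_key": f"{ga}|{gb}", "gene_a": ga, "gene_b": gb,
                     "mean_a": float(ya.mean()), "mean_b": float(yb.mean()),
                     "beta": float(beta[1]), "p": p})
    res = pd.DataFrame(rows)
    if not res.empty:
        res["padj"] = bh_adjust(res["p"].to_numpy())

    # "high" thresholds from the candidate pool's mean expression
    pool_a = res["mean_a"].to_numpy() if not res.empty else np.array([])
    pool_b = res["mean_b"].to_numpy() if not res.empty else np.array([])
    pool_a = np.concatenate([pool_a, mean_a_all.reindex(orphan_a).to_numpy()])
    pool_b = np.concatenate([pool_b, mean_b_all.reindex(orphan_b).to_numpy()])
    if joint_percentile:
        thr_a = thr_b = np.percentile(np.concatenate([pool_a, pool_b]), pct)
    else:
        thr_a = np.percentile(pool_a, pct) if pool_a.size else np.inf
        thr_b = np.percentile(pool_b, pct) if pool_b.size else np.inf

    def _cat(row):
        hi_a = row["mean_a"] > thr_a
        hi_b = row["mean_b"] > thr_b
        diverged = row["padj"] < alpha and abs(row["beta"]) >= beta_min
        if hi_a and hi_b and not diverged:
            return "high_both"
        # the sign of the species effect decides which side is "high"
        if diverged and row["beta"] >= beta_min and hi_a:
            return "high_a_low_b"
        if diverged and row["beta"] <= -beta_min and hi_b:
            return "high_b_low_a"
        return ""

    if not res.empty:
        res["category"] = res.apply(_cat, axis=1)
    else:
        res = pd.DataFrame(columns=["pair_key", "gene_a", "gene_b", "mean_a",
                                    "mean_b", "beta", "p", "padj", "category"])
    extra = []
    for g in orphan_a:
        mu = float(mean_a_all[g])
        extra.append({"pair_key": g, "gene_a": g, "gene_b": "",
                      "mean_a": mu, "mean_b": np.nan, "beta": np.nan,
                      "p": np.nan, "padj": np.nan,
                      "category": "high_a_no_ortholog" if mu > thr_a else ""})
    for g in orphan_b:
        mu = float(mean_b_all[g])
        extra.append({"pair_key": g, "gene_a": "", "gene_b": g,
                      "mean_a": np.nan, "mean_b": mu, "beta": np.nan,
                      "p": np.nan, "padj": np.nan,
                      "category": "high_b_no_ortholog" if mu > thr_b else ""})
    if extra:
        res = pd.concat([res, pd.DataFrame(extra)], ignore_index=True)
    return res.reset_index(drop=True)
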