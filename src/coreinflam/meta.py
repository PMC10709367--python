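"""Fisher combined-probability meta-analysis across studies and extraction
of the conserved up ("core inflammation program") and down gene sets.

The method: per-gene per-comparison DE p-values (BH-adjusted within each
comparison by default) are combined with Fisher's method over the
comparisons where the gene was tested, restricted to genes tested in at
least a fraction f (default 0.8) of the units; the combined p-values are
BH-corrected across genes, genes are ranked, the rank-R (default 500)
cutoff applied, and the selected genes split by mean log2 fold change
(|m| >= theta, default 0.5) into the up and down programs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust  # noqa: F401  (spec surface: meta.bh_adjust)
from .core_io import AnalysisConfig
from .study_de import DEResult

log = logging.getLogger("coreinflam")


@dataclass
class CoreProgram:
    up: list
    down: list
    rank_cutoff: int
    lfc_threshold: float
    coverage_fraction: float
    padj_threshold: float

    def __post_init__(self):
        assert not set(self.up) & set(self.down)


@dataclass
class MetaResult:
    """Per-gene Fisher statistics and the extracted program.

    table columns: k, fisher_stat, fisher_p, fisher_padj, mean_log2fc,
    rank, in_core_up, in_core_down.
    """

    table: pd.DataFrame
    program: CoreProgram | None = None


def harmonize_gene_keys(de_list: list[DEResult], omap) -> list[DEResult]:
    """Re-key every DE table to the canonical species-A symbol through the
    high-confidence one-to-one orthology map; genes without a one-to-one
    partner are dropped from species-B tables."""
    from .orthology import filter_orthologs
    tab = filter_orthologs(omap, {"one2one"}, "high").table
    b_to_a = dict(zip(tab["gene_b_symbol"], tab["gene_a_symbol"]))
    a_syms = set(tab["gene_a_symbol"])
    out = []
    for de in de_list:
        idx = de.table.index
        n_a = idx.isin(a_syms).sum()
        n_b = idx.isin(b_to_a).sum()
        if n_b > n_a:  # species-B table: translate
            t = de.table[idx.isin(b_to_a)].copy()
            t.index = [b_to_a[g] for g in t.index]
            t = t[~t.index.duplicated()]
            out.append(DEResult(t, de.shrunk, dict(de.extras)))
        else:
            out.append(de)
    return out


def coverage_filter(de_list: list[DEResult], min_frac: float = 0.8,
                    unit: str = "study") -> pd.Index:
    """Genes tested in at least ceil(min_frac * n_units) units.

    A unit is a study (default) or a comparison; studies contributing
    several comparisons count once, with a gene covered in the study if it
    was tested in any of its comparisons.
    """
    unit_ids = []
    for i, de in enumerate(de_list):
        col = "study_id" if unit == "study" else "comparison_id"
        if col in de.table.columns:
            unit_ids.append(str(de.table[col].iloc[0]))
        else:
            unit_ids.append(f"unit{i}")
    n_units = len(set(unit_ids))
    need = math.ceil(min_frac * n_units)
    covered: dict[str, set] = {}
    for uid, de in zip(unit_ids, de_list):
        for g in de.table.index[de.tested]:
            covered.setdefault(g, set()).add(uid)
    keep = [g for g, u in covered.items() if len(u) >= need]
    return pd.Index(sorted(keep))


def build_p_table(de_list: list[DEResult], genes: pd.Index,
                  use_adjusted: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x comparison tables of p-values and log2 fold changes, NaN where
    a gene was untested in a comparison."""
    pcols, lcols = {}, {}
    col = "padj" if use_adjusted else "p"
    for i, de in enumerate(de_list):
        cid = (str(de.table["comparison_id"].iloc[0])
               if "comparison_id" in de.table.columns else f"cmp{i}")
        t = de.table.reindex(genes)
        tested = t["tested"].eq(True)
        pcols[cid] = t[col].where(tested)
        lcols[cid] = t["log2fc"].where(tested)
    return pd.DataFrame(pcols, index=genes), pd.DataFrame(lcols, index=genes)


def fisher_combine(p_table: pd.DataFrame, p_floor: float = 1e-300) -> MetaResult:
    """Fisher's method per gene over the non-missing comparisons.

    X = -2 sum ln p_i ~ chi^2 with 2k df under the null; k varies per gene
    with missingness.  Zero p-values are clipped to p_floor with a warning.
    """
    p = p_table.to_numpy(dtype=float)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in (0, 1]")
    nz = (p == 0) & ~np.isnan(p)
    if nz.any():
        warnings.warn(f"{int(nz.sum())} zero p-values clipped to {p_floor}",
                      stacklevel=2)
        p = np.where(nz, p_floor, p)
    k = (~np.isnan(p)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        X = -2.0 * np.nansum(np.log(p), axis=1)
    fisher_p = stats.chi2.sf(X, df=2 * k)
    tab = pd.DataFrame({"k": k, "fisher_stat": X, "fisher_p": fisher_p},
                       index=p_table.index)
    tab = tab[tab["k"] > 0]
    tab["fisher_padj"] = bh_adjust(tab["fisher_p"].to_numpy())
    return MetaResult(tab)


def rank_cutoff(meta: MetaResult, method: str = "fixed_rank",
                R: int = 500) -> tuple[pd.Index, float, int]:
    """Select the top-ranked genes by ascending Fisher padj.

    fixed_rank: genes with rank <= R (ties at the boundary all included, so
    the selection may exceed R).  kneedle: R* = the rank maximizing the
    distance of the (rank, -log10 padj) curve from its endpoint chord.
    Returns (selected genes, realized padj threshold, R used).
    """
    tab = meta.table.sort_values(
        ["fisher_padj", "fisher_p"], kind="stable")
    m = len(tab)
    if method == "kneedle":
        y = -np.log10(np.maximum(tab["fisher_padj"].to_numpy(), 1e-300))
        xn = np.arange(m) / max(m - 1, 1)
        yn = (y - y[-1]) / max(y[0] - y[-1], 1e-12)
        # distance from the chord between the endpoints of the normalized
        # curve; absolute so both convex and concave rank curves work
        chord = yn[0] + (yn[-1] - yn[0]) * xn
        R = int(np.argmax(np.abs(yn - chord))) + 1
    elif method != "fixed_rank":
        raise ValueError(f"unknown rank_cutoff method {method!r}")
    if R > m:
        warnings.warn(f"rank cutoff {R} exceeds gene count {m}; taking all",
                      stacklevel=2)
        R = m
    thr = float(tab["fisher_padj"].iloc[R - 1])
    selected = tab.index[tab["fisher_padj"].to_numpy() <= thr]
    return selected, thr, R


def add_ranks(meta: MetaResult) -> MetaResult:
    tab = meta.table
    order = tab.sort_values(["fisher_padj", "fisher_p"], kind="stable").index
    rank = pd.Series(np.arange(1, len(order) + 1), index=order)
    tab = tab.copy()
    tab["rank"] = rank.reindex(tab.index)
    return MetaResult(tab, meta.program)


def extract_program(meta: MetaResult, lfc_table: pd.DataFrame,
                    theta: float = 0.5, R: int = 500,
                    method: str = "fixed_rank",
                    coverage_fraction: float = 0.8) -> MetaResult:
    """Split the rank-selected genes by mean log2FC into up/down programs.

    mean_log2fc is the unweighted arithmetic mean over contributing
    comparisons.  up: m >= theta; down: m <= -theta (boundary inclusive).
    """
    selected, thr, R_used = rank_cutoff(meta, method, R)
    tab = add_ranks(meta).table
    mbar = lfc_table.reindex(tab.index).mean(axis=1, skipna=True)
    tab["mean_log2fc"] = mbar
    sel = tab.index.isin(selected)
    if theta == 0:
        # theta=0 partitions the selection into up, down and {m = 0 exactly}
        tab["in_core_up"] = sel & (mbar > 0)
        tab["in_core_down"] = sel & (mbar < 0)
    else:
        tab["in_core_up"] = sel & (mbar >= theta)
        tab["in_core_down"] = sel & (mbar <= -theta)
    up = sorted(tab.index[tab["in_core_up"]])
    down = sorted(tab.index[tab["in_core_down"]])
    prog = CoreProgram(up, down, R_used, theta, coverage_fraction, thr)
    log.info("program extracted: %d up, %d down, padj threshold %.3g",
             len(up), len(down), thr)
    return MetaResult(tab, prog)


def run_meta(de_list: list[DEResult], config: AnalysisConfig | None = None,
             omap=None, **kw) -> MetaResult:
    """Full meta-analysis: harmonize gene keys (when an orthology map is
    given) -> coverage filter -> Fisher -> BH -> rank cutoff -> program
    extraction."""
    if config is None:
        config = AnalysisConfig(**kw)
    if omap is not None:
        de_list = harmonize_gene_keys(de_list, omap)
    genes = coverage_filter(de_list, config.coverage_fraction,
                            config.coverage_unit)
    if len(genes) == 0:
        raise ValueError("no genes pass the coverage filter")
    p_tab, lfc_tab = build_p_table(de_list, genes, config.use_adjusted_p)
    meta = fisher_combine(p_tab, config.p_floor)
    return extract_program(meta, lfc_tab, theta=config.lfc_threshold,
                           R=config.rank_cutoff,
                           coverage_fraction=config.coverage_fraction)
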