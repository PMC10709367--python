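"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: multi-study
two-species NB count matrices with batch effects and a planted shared
up/down program, a lineage atlas with marker blocks, single-cell log-normal
expression with condition shifts, p-value mixtures with known pi0, and
accessibility label tables.  All generators are pure functions of
(config, seed); defaults mirror the published analysis shape (11 studies,
10,000 genes, 150 up + 40 down planted genes, per-study log2FC ~ N(+-1, 0.3),
4 samples per group, NB dispersion ~ logNormal(ln 0.1, 0.5)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AnalysisConfig, StudyBundle
from .orthology import OrthologyMap


@dataclass
class SimConfig:
    n_genes: int = 10000
    n_studies_a: int = 7
    n_studies_b: int = 4
    n_per_group: int = 4
    n_core_up: int = 150
    n_core_down: int = 40
    n_study_specific: int = 50   # extra DE genes private to each study
    effect_mean: float = 1.0     # |per-study log2FC| of planted program genes
    effect_sd: float = 0.3
    batch_sd: float = 0.3        # per-study baseline shift sd (log2)
    baseline_mean: float = 5.0   # log2 baseline expression ~ N(5, 2)
    baseline_sd: float = 2.0
    disp_logmean: float = float(np.log(0.1))
    disp_logsd: float = 0.5
    lib_size_range: tuple = (3e6, 8e6)
    frac_one2one: float = 0.85
    frac_one2many: float = 0.10  # remainder has no ortholog
    shared_weight: float = 0.8   # cross-species baseline correlation weight
    # lineage atlas
    n_lineages: int = 4
    markers_per_lineage: int = 40
    marker_lfc: float = 3.0
    atlas_samples_per_lineage: int = 6
    # single-cell
    sc_samples_per_arm: int = 3
    sc_cells_per_sample: int = 300
    sc_delta: float = 1.0
    sc_sample_sd: float = 0.2
    sc_dropout: float = 0.3
    # p-mixture / accessibility
    pi0: float = 0.7
    beta_a: float = 0.15
    q0: float = 0.15
    q1: float = 0.5
    seed: int = 0

    @classmethod
    def from_analysis_config(cls, cfg: AnalysisConfig) -> "SimConfig":
        return cls(n_genes=cfg.n_genes, n_studies_a=cfg.n_studies_a,
                   n_studies_b=cfg.n_studies_b, n_per_group=cfg.n_per_group,
                   n_core_up=cfg.n_core_up, n_core_down=cfg.n_core_down,
                   effect_mean=cfg.effect_mean, effect_sd=cfg.effect_sd,
                   batch_sd=cfg.batch_sd, seed=cfg.seed)


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    core_up: list = field(default_factory=list)
    core_down: list = field(default_factory=list)
    study_specific: dict = field(default_factory=dict)
    lineage_markers: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    pi0: float = np.nan
    q0: float = np.nan
    q1: float = np.nan

    def to_dict(self) -> dict:
        return {"core_up": self.core_up, "core_down": self.core_down,
                "study_specific": self.study_specific,
                "lineage_markers": self.lineage_markers,
                "pi0": None if np.isnan(self.pi0) else self.pi0,
                "q0": None if np.isnan(self.q0) else self.q0,
                "q1": None if np.isnan(self.q1) else self.q1}


def _gene_ids(n, prefix="G"):
    return [f"{prefix}{i:05d}" for i in range(n)]


def _make_orthology(genes_a, genes_b, rng, frac_one2one, frac_one2many):
    """Orthology table: a leading block of one2one pairs, a slice of
    one2many pairs (one A gene to two B genes), the rest unmapped."""
    n = len(genes_a)
    n_11 = int(round(frac_one2one * n))
    n_1m = int(round(frac_one2many * n))
    rows = []
    for i in range(n_11):
        rows.append((f"ENSA{i:05d}", genes_a[i], f"ENSB{i:05d}", genes_b[i],
                     "one2one", 1))
    for i in range(n_11, min(n_11 + n_1m, n)):
        rows.append((f"ENSA{i:05d}", genes_a[i], f"ENSB{i:05d}", genes_b[i],
                     "one2many", 1))
        rows.append((f"ENSA{i:05d}", genes_a[i], f"ENSBx{i:05d}",
                     genes_b[i] + "x", "one2many", 1))
    for i in range(n_11 + n_1m, n):
        rows.append((f"ENSA{i:05d}", genes_a[i], "", "", "none", 1))
    tab = pd.DataFrame(rows, columns=["gene_a_id", "gene_a_symbol",
                                      "gene_b_id", "gene_b_symbol",
                                      "homology_class", "high_confidence"])
    return OrthologyMap(tab)


def _nb_draw(rng, mu, alpha):
    """NB(mu, alpha) with var = mu + alpha mu^2, via gamma-Poisson."""
    shape = 1.0 / np.maximum(alpha, 1e-12)
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def gen_cross_species_studies(config: SimConfig | None = None,
                              **kw) -> tuple[list, OrthologyMap, SimTruth]:
    """Simulate the multi-study two-species inflammation compendium.

    Per study: n_per_group resting + n_per_group inflamed samples; counts
    y ~ NB(mu = s_j 2^(b_g + batch + x_inflamed lfc_g,study), alpha_g).
    Planted core genes carry lfc ~ N(+-effect_mean, effect_sd) in every
    inflamed comparison; each study additionally gets n_study_specific
    private DE genes.  Species share ortholog baselines with weight
    shared_weight.  Returns (bundles, orthology map, truth).
    """
    cfg = config or SimConfig(**kw)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes_a = _gene_ids(n, "GA")
    genes_b = _gene_ids(n, "GB")
    omap = _make_orthology(genes_a, genes_b, rng, cfg.frac_one2one,
                           cfg.frac_one2many)

    shared = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n)
    priv_a = rng.normal(0.0, cfg.baseline_sd, n)
    priv_b = rng.normal(0.0, cfg.baseline_sd, n)
    # shared_weight is the shared variance fraction, hence also the
    # expected cross-species correlation of ortholog baselines
    w = cfg.shared_weight
    base_a = np.sqrt(w) * shared + np.sqrt(1 - w) * priv_a
    base_b = np.sqrt(w) * shared + np.sqrt(1 - w) * priv_b
    alpha = np.exp(rng.normal(cfg.disp_logmean, cfg.disp_logsd, n))

    # planted program on the one2one block so both species carry it
    n_11 = int(round(cfg.frac_one2one * n))
    picks = rng.choice(n_11, size=cfg.n_core_up + cfg.n_core_down,
                       replace=False)
    up_idx = np.sort(picks[: cfg.n_core_up])
    down_idx = np.sort(picks[cfg.n_core_up:])
    truth = SimTruth(core_up=[genes_a[i] for i in up_idx],
                     core_down=[genes_a[i] for i in down_idx])

    bundles = []
    study_specs = ([("A", i) for i in range(cfg.n_studies_a)]
                   + [("B", i) for i in range(cfg.n_studies_b)])
    for species, si in study_specs:
        sid = f"{species}{si+1}"
        base = base_a if species == "A" else base_b
        genes = genes_a if species == "A" else genes_b
        batch = rng.normal(0.0, cfg.batch_sd)
        lfc = np.zeros(n)
        lfc[up_idx] = rng.normal(cfg.effect_mean, cfg.effect_sd,
                                 len(up_idx))
        lfc[down_idx] = rng.normal(-cfg.effect_mean, cfg.effect_sd,
                                   len(down_idx))
        planted = set(up_idx) | set(down_idx)
        avail = np.array([i for i in range(n) if i not in planted])
        spec = rng.choice(avail, size=cfg.n_study_specific, replace=False)
        lfc[spec] = rng.normal(0.0, 1.0, len(spec)) + np.sign(
            rng.standard_normal(len(spec))) * 0.5
        truth.study_specific[sid] = [genes[i] for i in np.sort(spec)]
        truth.effects[sid] = lfc

        n_s = cfg.n_per_group
        x = np.array([0] * n_s + [1] * n_s)
        lib = rng.uniform(*cfg.lib_size_range, size=2 * n_s)
        log2mu = (base[:, None] + batch
                  + lfc[:, None] * x[None, :])
        mu_rel = 2.0 ** np.clip(log2mu, -10, 28)
        mu = mu_rel / mu_rel.sum(axis=0, keepdims=True) * lib[None, :]
        counts = _nb_draw(rng, mu, alpha[:, None])
        samples = [f"{sid}_s{j+1}" for j in range(2 * n_s)]
        meta = pd.DataFrame({
            "study_id": sid, "species": species,
            "condition": np.where(x == 1, "inflamed", "resting"),
            "tissue": "blood"}, index=pd.Index(samples, name="sample_id"))
        bundles.append(StudyBundle(
            pd.DataFrame(counts, index=genes, columns=samples), meta))
    return bundles, omap, truth


def gen_lineage_atlas(config: SimConfig | None = None,
                      **kw) -> tuple[StudyBundle, SimTruth]:
    """Simulate a multi-lineage atlas with planted marker blocks.

    Each lineage gets markers_per_lineage genes upshifted by marker_lfc
    (log2) in its own samples only.
    """
    cfg = config or SimConfig(**kw)
    if cfg.n_lineages < 2:
        raise ValueError("need at least 2 lineages")
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_genes
    genes = _gene_ids(n, "GA")
    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n)
    alpha = np.exp(rng.normal(cfg.disp_logmean, cfg.disp_logsd, n))
    lineages = [f"L{i+1}" for i in range(cfg.n_lineages)]
    marker_idx = {}
    if cfg.markers_per_lineage > 0:
        all_idx = rng.choice(n, size=cfg.markers_per_lineage * cfg.n_lineages,
                             replace=False)
        for li, lin in enumerate(lineages):
            marker_idx[lin] = np.sort(
                all_idx[li * cfg.markers_per_lineage:
                        (li + 1) * cfg.markers_per_lineage])
    else:
        marker_idx = {lin: np.array([], dtype=int) for lin in lineages}
    truth = SimTruth(lineage_markers={
        lin: [genes[i] for i in idx] for lin, idx in marker_idx.items()})

    cols, metas = [], []
    mats = []
    for lin in lineages:
        shift = np.zeros(n)
        shift[marker_idx[lin]] = cfg.marker_lfc
        k = cfg.atlas_samples_per_lineage
        lib = rng.uniform(*cfg.lib_size_range, size=k)
        log2mu = base[:, None] + shift[:, None]
        mu_rel = 2.0 ** np.clip(log2mu, -10, 28)
        mu = mu_rel / mu_rel.sum(axis=0, keepdims=True) * lib[None, :]
        mats.append(_nb_draw(rng, mu, alpha[:, None]))
        names = [f"{lin}_s{j+1}" for j in range(k)]
        cols.extend(names)
        metas.append(pd.DataFrame({"study_id": "atlas", "species": "A",
                                   "condition": "resting", "lineage": lin},
                                  index=pd.Index(names, name="sample_id")))
    counts = pd.DataFrame(np.hstack(mats), index=genes, columns=cols)
    return StudyBundle(counts, pd.concat(metas)), truth


def gen_single_cell(config: SimConfig | None = None,
                    **kw) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a two-arm single-cell experiment for module scoring.

    Log-normal expression with per-sample random intercepts; the planted
    program genes are shifted by sc_delta in inflamed cells only; optional
    dropout zeroes entries at rate sc_dropout.  Returns (cells x genes
    matrix, per-cell labels frame, truth).
    """
    cfg = config or SimConfig(**kw)
    rng = np.random.default_rng(cfg.seed + 2)
    n = min(cfg.n_genes, 2000)  # single-cell panels are smaller
    genes = _gene_ids(n, "GA")
    n_prog = min(cfg.n_core_up, n // 10)
    prog_idx = np.sort(rng.choice(n, size=n_prog, replace=False))
    truth = SimTruth(core_up=[genes[i] for i in prog_idx])
    base = rng.normal(1.0, 0.5, n).clip(0.05)

    rows, conds, samps = [], [], []
    for arm, label in ((0, "resting"), (1, "inflamed")):
        for s in range(cfg.sc_samples_per_arm):
            sid = f"{label[:3]}_{s+1}"
            intercept = rng.normal(0.0, cfg.sc_sample_sd)
            mean = base + intercept
            if arm == 1:
                mean = mean.copy()
                mean[prog_idx] += cfg.sc_delta
            X = rng.normal(mean[None, :], 0.5,
                           size=(cfg.sc_cells_per_sample, n))
            if cfg.sc_dropout > 0:
                X[rng.random(X.shape) < cfg.sc_dropout] = 0.0
            X = np.maximum(X, 0.0)
            rows.append(X)
            conds.extend([label] * cfg.sc_cells_per_sample)
            samps.extend([sid] * cfg.sc_cells_per_sample)
    mat = np.vstack(rows)
    cells = [f"c{i:06d}" for i in range(mat.shape[0])]
    df = pd.DataFrame(mat, index=cells, columns=genes)
    labels = pd.DataFrame({"condition": conds, "sample_id": samps},
                          index=cells)
    return df, labels, truth


def gen_pvalues(m: int, pi0: float = 0.7, beta_a: float = 0.15,
                seed: int = 0) -> tuple[np.ndarray, SimTruth]:
    """p ~ pi0 Uniform(0,1) + (1 - pi0) Beta(beta_a, 1), with truth."""
    rng = np.random.default_rng(seed)
    null = rng.random(m) < pi0
    p = np.where(null, rng.random(m), rng.beta(beta_a, 1.0, m))
    return p, SimTruth(pi0=pi0)


def gen_accessibility(universe, program, q0: float = 0.15, q1: float = 0.5,
                      seed: int = 0,
                      p_decrease: float = 0.1) -> tuple[pd.Series, SimTruth]:
    """Accessibility labels over a gene universe: "increase" with
    probability q1 for program genes and q0 otherwise; non-increase genes
    split between "decrease" and "none"."""
    rng = np.random.default_rng(seed)
    prog = set(program)
    labels = []
    for g in universe:
        q = q1 if g in prog else q0
        if rng.random() < q:
            labels.append("increase")
        elif rng.random() < p_decrease:
            labels.append("decrease")
        else:
            labels.append("none")
    return (pd.Series(labels, index=pd.Index(universe, name="gene"),
                      name="label"),
            SimTruth(q0=q0, q1=q1))
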