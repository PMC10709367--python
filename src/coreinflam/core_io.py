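"""Data model, file I/O and pipeline plumbing.

The central in-memory containers are :class:`StudyBundle` (one study's
gene x sample integer count matrix plus aligned sample metadata) and
:class:`GeneSetCollection` (ordered GMT-style gene sets).  All tabular I/O is
plain TSV / MatrixMarket so that runs are reproducible from text files alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

log = logging.getLogger("coreinflam")

REQUIRED_META = ("sample_id", "study_id", "condition")
OPTIONAL_META = ("species", "subcondition", "tissue", "lineage")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Integer count matrix (genes x samples) with aligned sample metadata.

    ``counts`` is a DataFrame indexed by gene id with sample ids as columns;
    ``meta`` is indexed by sample_id in the same column order and must carry
    at least study_id and condition.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        vals = self.counts.to_numpy()
        if np.issubdtype(vals.dtype, np.floating):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(vals != np.round(vals))[0]
                raise ValueError(
                    "non-integer count at gene "
                    f"{self.counts.index[bad[0]]!r}, sample "
                    f"{self.counts.columns[bad[1]]!r}")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}")
        if list(self.counts.columns) != list(self.meta.index):
            missing = set(self.counts.columns) - set(self.meta.index)
            if missing:
                raise ValueError(f"metadata missing samples: {sorted(missing)}")
            self.meta = self.meta.loc[list(self.counts.columns)]
        for col in REQUIRED_META[1:]:
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        if self.meta.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self):
        return self.counts.shape

    def subset_genes(self, genes: Sequence[str]) -> "StudyBundle":
        return StudyBundle(self.counts.loc[list(genes)], self.meta.copy())


class GeneSetCollection(dict):
    """Ordered name -> gene-list mapping with optional per-set descriptions."""

    def __init__(self, sets=None, descriptions=None):
        super().__init__()
        self.descriptions: dict[str, str] = {}
        for name, genes in (sets or {}).items():
            self.add(name, genes,
                     (descriptions or {}).get(name, ""))

    def add(self, name: str, genes: Sequence[str], description: str = ""):
        genes = [g for g in genes if g]
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate genes within set {name!r}")
        if name in self:
            raise ValueError(f"duplicate set name {name!r}")
        self[name] = list(genes)
        self.descriptions[name] = description


_CONFIG_FIELDS: dict[str, type] = {}


@dataclass
class AnalysisConfig:
    """All downstream tunables, defaulting to the published analysis choices.

    rank_cutoff (R), lfc_threshold (theta) and coverage_fraction (f) drive
    the program extraction; n_bins the expression matching; the rest
    parameterize the component engines and generators.
    """

    rank_cutoff: int = 500
    lfc_threshold: float = 0.5
    coverage_fraction: float = 0.8
    n_bins: int = 25
    ctrl_size: int = 50
    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.05
    prefilter_min_count: int = 2
    prefilter_min_samples: int = 1
    shrink_lfc: bool = True
    use_adjusted_p: bool = True
    coverage_unit: str = "study"
    marker_cap: int = 200
    marker_alpha: float = 0.05
    p_floor: float = 1e-300
    # synthetic-data knobs (see coreinflam.simulate for semantics)
    n_genes: int = 10000
    n_studies_a: int = 7
    n_studies_b: int = 4
    n_per_group: int = 4
    n_core_up: int = 150
    n_core_down: int = 40
    effect_mean: float = 1.0
    effect_sd: float = 0.3
    batch_sd: float = 0.3

    def __post_init__(self):
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            want = f.type if isinstance(f.type, type) else eval(f.type)  # noqa: S307
            if want is float and isinstance(val, int) and not isinstance(val, bool):
                setattr(self, f.name, float(val))
            elif not isinstance(val, want) or (want is int and isinstance(val, bool)):
                raise TypeError(
                    f"config key {f.name!r} expects {want.__name__}, "
                    f"got {type(val).__name__} ({val!r})")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path=None, overrides: dict | None = None) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML document; unknown keys are rejected.

    An empty / absent document yields all defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config document must be a mapping")
    data.update(overrides or {})
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = AnalysisConfig(**data)
    log.info("config loaded: %s", cfg.to_dict())
    return cfg


# ---------------------------------------------------------------------------
# Counts I/O
# ---------------------------------------------------------------------------

def read_counts(path, fmt: str = "tsv", meta_path=None,
                genes_path=None, samples_path=None) -> StudyBundle:
    """Read a count matrix (genes x samples) as a StudyBundle.

    fmt="tsv": header row of sample ids, first column gene ids.
    fmt="mtx_triplet": MatrixMarket coordinate file with gene and sample
    sidecar lists (one id per line).  Metadata comes from a TSV keyed by
    sample_id; when absent a minimal single-study metadata frame is built.
    """
    path = Path(path)
    if fmt == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "mtx_triplet":
        if genes_path is None or samples_path is None:
            genes_path = path.with_suffix(".genes.txt")
            samples_path = path.with_suffix(".samples.txt")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = [l.strip() for l in Path(genes_path).read_text().splitlines() if l.strip()]
        samples = [l.strip() for l in Path(samples_path).read_text().splitlines() if l.strip()]
        counts = pd.DataFrame(np.asarray(mat), index=genes, columns=samples)
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    if meta_path is not None:
        meta = read_metadata(meta_path)
        meta = meta.reindex(counts.columns)
        if meta["study_id"].isna().any():
            missing = meta.index[meta["study_id"].isna()].tolist()
            raise ValueError(f"metadata missing samples: {missing}")
    else:
        meta = pd.DataFrame({"study_id": "study1",
                             "condition": "resting"},
                            index=counts.columns)
        meta.index.name = "sample_id"
    return StudyBundle(counts, meta)


def write_counts(bundle: StudyBundle, path, meta_path=None) -> None:
    df = bundle.counts.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    if meta_path is not None:
        write_metadata(bundle.meta, meta_path)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_META:
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {i}: fewer than 3 fields")
            name, desc, *genes = fields
            coll.add(name, [g for g in genes if g], desc)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

STAGES = ("simulate", "de", "meta", "concordance")


def run_pipeline(config: AnalysisConfig, stages: Sequence[str], outdir) -> dict:
    """Run the requested stages in order, writing one TSV per result table,
    a GMT of the extracted program, and a machine-readable manifest.

    Deterministic given the config (all seeds derive from ``config.seed``).
    Returns the manifest dict.
    """
    from . import concordance as conc
    from . import meta as meta_mod
    from . import simulate, study_de

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(),
                      "config_hash": config.digest(),
                      "stages": {}}
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]

    for stage in stages:
        if stage == "simulate":
            bundles, omap, truth = simulate.gen_cross_species_studies(
                simulate.SimConfig.from_analysis_config(config))
            for b in bundles:
                sid = b.meta["study_id"].iloc[0]
                write_counts(b, outdir / f"counts_{sid}.tsv",
                             outdir / f"meta_{sid}.tsv")
            omap.to_tsv(outdir / "orthology.tsv")
            (outdir / "truth.json").write_text(json.dumps(truth.to_dict(),
                                                          indent=1))
            manifest["stages"]["simulate"] = {
                "n_studies": len(bundles),
                "n_genes": int(bundles[0].shape[0]),
                "seed": config.seed}
        elif stage == "de":
            import glob
            paths = sorted(glob.glob(str(outdir / "counts_*.tsv")))
            if not paths:
                raise RuntimeError(
                    "stage 'de': no counts_*.tsv found; run 'simulate' first "
                    "or place per-study count tables in the output directory")
            tables = []
            for p in paths:
                sid = Path(p).stem.replace("counts_", "")
                bundle = read_counts(p, "tsv", outdir / f"meta_{sid}.tsv")
                bundle = study_de.prefilter(bundle, config.prefilter_min_count,
                                            config.prefilter_min_samples)
                de = study_de.nb_wald(bundle, ("inflamed", "resting"),
                                      shrink_lfc=config.shrink_lfc)
                de = study_de.independent_filter(de)
                de.table["study_id"] = sid
                de.table["comparison_id"] = sid
                sp = bundle.meta["species"].iloc[0] if "species" in bundle.meta else ""
                de.table["species"] = sp
                de.table.to_csv(outdir / f"de_{sid}.tsv", sep="\t")
                tables.append(de)
            manifest["stages"]["de"] = {
                "n_comparisons": len(tables),
                "rows": [int(t.table.shape[0]) for t in tables]}
        elif stage == "meta":
            de_list = _load_de_tables(outdir)
            if not de_list:
                raise RuntimeError("stage 'meta': no de_*.tsv found; run 'de' first")
            omap = None
            opath = outdir / "orthology.tsv"
            if opath.exists():
                from .orthology import OrthologyMap
                omap = OrthologyMap.from_tsv(opath)
            meta_res = meta_mod.run_meta(de_list, config, omap=omap)
            meta_res.table.to_csv(outdir / "meta.tsv", sep="\t")
            prog = meta_res.program
            coll = GeneSetCollection(
                {"CORE_UP": prog.up, "CORE_DOWN": prog.down})
            write_gmt(coll, outdir / "program.gmt")
            manifest["stages"]["meta"] = {
                "n_genes": int(meta_res.table.shape[0]),
                "n_core_up": len(prog.up), "n_core_down": len(prog.down),
                "padj_threshold": prog.padj_threshold,
                "coverage_unit": config.coverage_unit,
                "use_adjusted_p": config.use_adjusted_p}
        elif stage == "concordance":
            de_list = _load_de_tables(outdir)
            if not de_list:
                raise RuntimeError(
                    "stage 'concordance': no de_*.tsv found; run 'de' first")
            opath = outdir / "orthology.tsv"
            if opath.exists():
                from .orthology import OrthologyMap
                de_list = meta_mod.harmonize_gene_keys(
                    de_list, OrthologyMap.from_tsv(opath))
            pi1 = conc.pairwise_replicability(de_list, alpha=config.alpha)
            pi1.to_csv(outdir / "pi1_matrix.tsv", sep="\t")
            lfc = conc.lfc_correlation(de_list)
            lfc.to_csv(outdir / "lfc_correlation.tsv", sep="\t")
            manifest["stages"]["concordance"] = {
                "n_units": int(pi1.shape[0])}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest


def _load_de_tables(outdir):
    import glob

    from .study_de import DEResult
    out = []
    for p in sorted(glob.glob(str(Path(outdir) / "de_*.tsv"))):
        tab = pd.read_csv(p, sep="\t", index_col=0)
        if "p" not in tab.columns or "log2fc" not in tab.columns:
            raise RuntimeError(f"corrupted DE table {p}: missing columns")
        out.append(DEResult(tab))
    return out
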