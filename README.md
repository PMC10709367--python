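# coreinflam

Cross-species meta-analysis of inflammatory transcriptional programs in
neutrophils (or any comparable two-species, multi-study bulk RNA-seq
compendium), with the resampling-based validation statistics that such an
analysis needs: replicability (π1), expression-matched background scoring,
bias-aware overrepresentation, and studentized bootstraps.

## The problem

Individual inflammation studies disagree: different stimuli, tissues,
platforms and species produce largely non-overlapping lists of
differentially expressed genes. The question this package addresses is
whether a *conserved core* exists — a set of genes consistently induced
across many independent studies in both human and mouse — and how to extract
it with statistics that respect per-study heterogeneity.

## The method

1. **Ortholog integration.** Per-study gene×sample count matrices from two
   species are bridged by high-confidence one-to-one orthologs; merged genes
   are keyed by the species-A (human-side) symbol. TMM-scaled log2(CPM)
   and log2(TPM+1) normalization, per-species mean-centering.
2. **Per-study differential expression.** A reference negative-binomial Wald
   engine per study: median-of-ratios size factors, method-of-moments
   dispersions moderated toward an a₀ + a₁/μ trend, vectorized IRLS for
   log μ = log s_j + β₀ + β₁·x_inflamed, a t reference with 2(n−2) df,
   ridge-shrunken log2 fold changes, independent filtering and a
   count-outlier mask. Precomputed DE tables can be substituted.
3. **Fisher combination.** For each gene tested in ≥80% of studies, the
   within-study BH-adjusted p-values are combined:
   X = −2·Σᵢ ln pᵢ ~ χ²(2k). BH across genes, genes ranked, rank R = 500
   cutoff, and the selection split by mean log2FC: the up subset
   (m̄ ≥ 0.5) is the **core inflammation program**, m̄ ≤ −0.5 the down set.
4. **Validation statistics.** Storey π1 (spline-smoothed, truncated-p
   variant) for replicability between studies; log2FC correlation matrices;
   preranked GSEA with a gene-permutation null; per-cell module scores
   against expression-matched control genes (25 equal-frequency bins,
   50 controls per gene) tested with a random-intercept mixed model;
   PWF-weighted Wallenius overrepresentation; and a two-sided studentized
   bootstrap of accessibility-label counts against matched background sets.

Everything runs on synthetic data with planted ground truth
(`coreinflam.simulate`), so the full pipeline is testable offline.

## Worked example

```python
from coreinflam import AnalysisConfig, meta, study_de
from coreinflam.simulate import SimConfig, gen_cross_species_studies

bundles, omap, truth = gen_cross_species_studies(SimConfig(seed=1))
des = []
for b in bundles:
    de = study_de.independent_filter(
        study_de.nb_wald(study_de.prefilter(b)))
    de.table["study_id"] = de.table["comparison_id"] = b.meta.study_id.iloc[0]
    des.append(de)
res = meta.run_meta(des, AnalysisConfig(), omap=omap)
up = set(res.program.up); tu = set(truth.core_up)
print(len(res.program.up), len(res.program.down))
print(round(len(up & tu) / len(up), 3), round(len(up & tu) / len(tu), 3))
```

prints

```
141 36
1.0 0.94
```

— from 11 simulated studies (7 "human", 4 "mouse", 10,000 genes, 4
samples/group) carrying 150 planted up and 40 planted down genes with
per-study log2FC ~ N(±1, 0.3), the meta-analysis recovers a 141-gene up
program with precision 1.0 and recall 0.94, plus 36 of the 40 down genes.

The same run from a shell:

```sh
coreinflam --seed 1 --outdir results all
```

writes per-study DE tables, the meta table, the program GMT
(`CORE_UP`/`CORE_DOWN`), π1 and log2FC-correlation matrices, and a manifest
with the realized padj threshold.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch — simulation, per-study NB
differential expression, Fisher meta-analysis, program extraction and the
replicability stage — at the default scale, writes the pipeline tables next
to the output file and the result JSON to `--out`. The validation
properties themselves (closed-form oracles, null calibration,
planted-truth recovery, structural invariants) live in
`tests/test_acceptance.py`.
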