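# comethnet

Consensus weighted co-methylation network analysis for multi-cohort DNA
methylation studies.

Aging leaves a reproducible footprint on CpG methylation. Rather than
testing CpGs one at a time, `comethnet` looks for **consensus modules** —
clusters of CpG probes that are co-methylated in *every* one of several
independent datasets (different cohorts, tissues, labs) — and asks which
of those modules track chronological age. Because a consensus module must
replicate across datasets by construction, it is robust to batch effects
and platform quirks, and its *module eigengene* gives a single, stable
age-association readout per cohort. The package is aimed at epigenomics
researchers who have several probe × sample beta-value matrices (e.g. GEO
series matrices from Illumina 27K/450K arrays) and want a tested,
scriptable version of the consensus-module workflow, including a
synthetic-data generator so every stage can be exercised without any
external download.

## The method

For each dataset *s* with probe profiles *x_i* (beta values in [0, 1]):

1. **QC** — iteratively drop samples whose mean inter-array correlation is
   ≤ 2 SD below the mean.
2. **Marginal age association** — biweight midcorrelation of every probe
   with age; two-sided p from the Student-t transform; per-dataset
   Z_s = Φ⁻¹(1 − p/2)·sign(r); Stouffer meta-analysis
   `metaZ = Σ w_s Z_s / √(Σ w_s²)` (equal weights by default), BH
   q-values, and the signed log p-value −log₁₀(p)·sign(r).
3. **Signed network** — adjacency `a_ij = ((1 + cor(x_i, x_j)) / 2)^b`
   with soft threshold *b* = 12, transformed to the topological overlap
   matrix `TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`.
4. **Calibration & consensus** — each dataset's TOM is raised to the power
   that equates its 95th percentile with the reference; the consensus TOM
   is the entrywise lower quartile, and `DissCTOM = 1 − CTOM` is clustered
   with average linkage. Branches of ≥ 30 probes become modules; the rest
   stay "grey".
5. **Eigengenes & kME** — per dataset, each module's eigengene is the
   first principal component of its standardized submatrix; a probe's
   module membership kME is its correlation with the eigengene, averaged
   across datasets into the consensus kME.
6. **Preservation** — modules are validated in held-out datasets with
   permutation density statistics summarized by Zdensity (median of four
   per-statistic Z scores), averaged over reference sets; Zdensity > 10
   means strong preservation, < 2 none. medianRank compares modules of
   different sizes.
7. **Annotation** — consensus kME (or the signed log meta-p) is related to
   probe annotations (Polycomb occupancy counts, CpG island status,
   chromosome, distance to TSS) via grouped means ± SE, Kruskal-Wallis
   tests, sequential (type-I) ANOVA variance decomposition, and
   hypergeometric gene-list enrichment with Bonferroni correction.

## Worked example

```python
import comethnet as cn

design = cn.default_design(seed=1)           # 4 cohorts x 80 samples x 2,000 probes
pairs = cn.generate_consensus_datasets(design)
betas = {n: b for n, (b, _) in zip(design.dataset_names, pairs)}
samples = {n: s for n, (_, s) in zip(design.dataset_names, pairs)}

result = cn.run_consensus(betas, samples)
print("module sizes:", dict(result.module_set.sizes()))
print(result.trait_table[["module", "color", "dataset", "r", "p"]].to_string(index=False))
```

prints

```
module sizes: {1: 60, 2: 51}
 module     color dataset         r            p
      1 turquoise     ds1  0.673766 2.558544e-11
      2      blue     ds1  0.035816 7.587199e-01
      1 turquoise     ds2  0.761489 5.797768e-16
      2      blue     ds2 -0.002082 9.855667e-01
      1 turquoise     ds3  0.618798 3.281290e-09
      2      blue     ds3  0.011830 9.197615e-01
      1 turquoise     ds4  0.627652 1.002522e-09
      2      blue     ds4  0.015312 8.948471e-01
```

Module 1 (turquoise) is the planted aging module: its eigengene correlates
positively with age in every cohort (r ≈ 0.62–0.76 at the generative
effect size of 0.7). Module 2 recovers the planted sex-driven
X-chromosome module — strongly co-methylated everywhere but unrelated to
age. The planted dataset-specific module is correctly *not* reported: a
block of probes correlated in only one cohort cannot survive the
lower-quartile consensus. Ranking probes by consensus kME
(`cn.top_module_probes(result.consensus_kme, 1, 5)`) returns the tightest
module members (kME ≈ 0.88–0.89).

## Command line

```bash
comethnet simulate --seed 1 --out data/          # write beta/sample/probe TSVs
comethnet qc data/ds1_beta.tsv --out qc/         # outlier removal for one matrix
comethnet all config.yaml                        # full pipeline from a YAML config
```

`comethnet all` writes per-stage artifacts (QC reports, meta-analysis
tables, module assignment, consensus kME, module–age grids for reference
and validation sets, preservation summaries, annotation ANOVA tables,
figures) plus a run manifest with the config hash and seed.

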