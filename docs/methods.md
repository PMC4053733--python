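# Methods

## Model and scope

`comethnet` implements consensus weighted correlation network analysis
for DNA methylation. The working assumptions are those of the weighted
co-methylation framework: probe profiles are continuous beta values in
[0, 1]; biological co-regulation shows up as positive correlation across
samples; and a module that reflects biology rather than batch structure
must be detectable in every one of several independent datasets. The
signed adjacency `((1 + cor)/2)^b` maps correlation into [0, 1] so that
anti-correlated probes get near-zero weight; the topological overlap
transform rewards shared neighborhoods and is the clustering substrate;
the consensus operator (entrywise low quantile of calibrated TOMs) keeps
an edge only if it is strong in most datasets.

Age association is treated marginally (probe by probe) and modularly
(eigengene and kME). The two are deliberately kept as separate measures:
the marginal route is the Stouffer meta-analysis of per-dataset
correlation tests; the modular route is the consensus kME, and the
annotation analyses quantify how much more signal the modular measure
carries.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| soft threshold `b` | 12 | standard signed-network power; weighted networks are robust to this choice |
| calibration quantile | 0.95 | matches each TOM's upper scale (roughly its maximum) across datasets before consensus |
| consensus quantile | 0.25 | lower quartile: an edge must be at least this strong in 75% of datasets; any value in [0, 0.5] is supported |
| correlation estimator | bicor | biweight midcorrelation (9·MAD tuning, Pearson fallback at MAD = 0) resists single-sample outliers |
| QC SD multiplier | 2 | a sample is an outlier when its mean inter-array correlation is ≤ mean − 2 SD |
| QC max iterations | 2 | see below |
| min module size | 30 | branches smaller than this stay grey |
| cut height | 0.99 × top merge height | see below |
| preservation permutations | 200 | null SD of the density statistics stabilizes well before this |
| Stouffer weights | equal | per-dataset weighting changes little and equal weights are the default convention |

## The synthetic study

The generator emulates a multi-cohort methylation study: several
datasets from ≥ 2 tissues, each a probe × sample beta matrix with an
accompanying sample table (age, sex, disease, tissue) and a probe table
(chromosome, CpG-island status, Polycomb occupancy count 0–3,
polymorphic / cross-reactive flags). Each probe has a baseline level
`mu_p ~ N(0, 1.5²)` on the logit scale, shared across datasets — this is
what makes cross-dataset concordance of probe means high, as in real
arrays. Module members load on a per-sample latent factor with loading
`sqrt(rho)` (default within-module correlation 0.8); the aging module's
factor is `e·z(age) + sqrt(1−e²)·noise` with effect size `e = 0.7`, the
sex module's factor is driven by sex, and dataset-specific factors exist
in one dataset only. Betas are the inverse logit of the latent value, so
they are strictly inside (0, 1). Corrupted samples are whole columns of
independent noise — exactly the failure mode the inter-array-connectivity
QC rule is meant to catch. Ages are uniform within each cohort's range;
sex is Bernoulli(0.5) unless a cohort is declared single-sex. One integer
seed drives everything; per-dataset streams are spawned from it, so the
whole collection is byte-reproducible.

Default study size: 4 datasets (2 "blood", 2 "brain") × 80 samples ×
2,000 probes, with a 60-probe aging module, a 50-probe sex module and a
50-probe dataset-specific module. The effect size 0.7 was chosen so a
planted module is comfortably detectable at cohort sizes near 100 — the
scale at which the generative eigengene–age correlation (≈ e) can be
recovered to ±0.1 by the mean over cohorts.

What the generator does **not** emulate: probe-level intensity (M/U)
noise, plate/batch effects, realistic genomic coordinates or LD between
probes, cell-type composition, and non-uniform age distributions. Tests
passing on this generator therefore demonstrate the correctness and
operating characteristics of the algorithms under a clean factor model,
not performance on real arrays.

## Numerical choices

* **Quantile convention.** All quantiles (calibration, consensus) use
  linear interpolation between order statistics (`numpy.quantile`
  default). This is stated because conventions differ between tools.
* **Calibration refinement.** The closed-form exponent
  `log(q_ref)/log(q_s)` equates quantiles only to ~1e-9, because the
  interpolated sample quantile does not commute exactly with the power
  transform. A few fixed-point refinements push the agreement below
  1e-12. The reference is the first dataset's quantile (a pooled median
  is available via configuration).
* **QC iterations.** The per-sample mean inter-array correlation is
  bounded above, hence left-skewed, so the "repeat until nothing is ≤
  mean − 2 SD" rule never strictly converges on clean data — it keeps
  shaving the left tail. Two passes capture the rule's intent: the first
  removes gross outliers (whose presence inflates the SD), the second
  confirms on the cleaned distribution. More iterations are available
  via `max_iter`. Ties at the threshold are removed (the rule is
  inclusive).
* **Cut height.** The branch cut defaults to 0.99 × the top merge
  height. On TOM dissimilarities the unassigned background forms a dense
  plateau of merges just below the maximum height, so a cut placed at a
  quantile of the merge heights would land inside the plateau and fuse
  the background into one spurious module; a cut just below the top
  merge separates real branches (which join far lower) from the plateau.
  `deep_split` (0–3) lowers the factor to 0.995/0.99/0.97/0.94. The full
  dynamic-hybrid cutting with PAM-like reassignment is out of scope; the
  static cut plus minimum-size pruning recovers planted partitions and
  keeps the procedure transparent.
* **Ties and determinism.** Module labels are ordered by decreasing
  size, ties broken by cluster id; kME rankings break ties by probe id;
  average-linkage uses scipy's deterministic nearest-neighbor chain.
  Permutation nulls draw probe sets without replacement from non-module
  probes, with per-(reference, module) streams spawned from one seed.
* **Degenerate inputs.** Zero-variance probes get correlation 0 (hence
  adjacency 2^-b) and kME NaN; a probe equal to the age vector caps at
  signed log p = ±300 (p floored at 1e-300); an all-identical sample in
  Kruskal-Wallis returns (0, 1); a zero permutation SD reports Z = +inf
  with a warning.
* **Missing betas.** Association tests use pairwise-complete samples per
  probe; network construction and eigengenes impute by probe mean first
  (a network needs complete data, and the imputation is neutral for
  correlations).

## Statistical decisions at open points

* **Z from the t test.** The per-dataset Z entering the meta-analysis is
  obtained from the two-sided t-test p-value with the sign of r, not
  from Fisher's atanh transform: it matches the "combine correlation
  test statistics" formulation and behaves correctly at small n.
* **Sign convention.** Signed log p is −log₁₀(p) · sign(r): probes whose
  methylation rises with age get positive values.
* **q-values.** Benjamini–Hochberg step-up stands in for a local-FDR
  estimator; it is monotone in p-rank, needs no density estimation, and
  its guarantees suffice for ranking probes.
* **Density statistics.** Zdensity is the median of four permutation Zs:
  mean sign-aware within-module correlation, mean signed adjacency,
  eigengene proportion of variance explained, and mean sign-aware kME.
  The sign-aware statistics take signs from the reference set, which is
  what makes Zdensity depend on the reference and motivates averaging
  Zdensity(k) across reference sets. Connectivity statistics
  (correlation of reference vs test kME and of intramodular correlation
  patterns, summarized by Zconnectivity, with Zsummary their mean) are
  computed and reported but are not the preservation criterion: density
  (is the module still dense?) and connectivity (are the same probes the
  hubs?) answer different questions, and hub status is known to travel
  poorly across tissues.
* **Enrichment universe.** Gene-list enrichment deduplicates to one vote
  per gene and defaults to the universe of all genes on the analyzed
  (QC-surviving, platform-shared) probe set; the universe is
  configurable because published analyses are often ambiguous on this
  point and the p-value is sensitive to it.
* **ANOVA.** The variance decomposition is sequential (type-I), computed
  from nested least-squares fits in the user's stated factor order —
  formula machinery is avoided because it silently reorders categorical
  terms, which changes a sequential decomposition. Island status enters
  as a 2-df categorical, X-chromosome as binary, distance to TSS as a
  1-df covariate.

## Problem sizes

The test suite exercises the full stack at 4 × 80 × 2,000 (the default
study), with 200-permutation preservation, 50-replicate QC operating
characteristics, and a 10,000-probe null calibration of the
meta-analysis; unit tests use 400-probe versions of the same design.
These sizes were chosen so the complete suite and the acceptance script
each run in minutes on a single CPU while leaving the planted-signal
checks well-powered.

## Limitations

* The tree cut is static-height plus size pruning; deeply nested or
  overlapping modules that dynamic-hybrid cutting would separate may be
  merged or greyed.
* Dense probe × probe matrices bound the practical problem size to a few
  tens of thousands of probes on a desktop; variance pre-filtering is
  the intended route to 450K-scale data.
* bicor's t-based p-values are asymptotic; at very small n (< 15) the
  meta-analysis inherits mild anti-conservatism.
* The preservation null draws random probe sets of equal size, which
  controls for size but not for annotation composition (e.g. island
  density) of the module.
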