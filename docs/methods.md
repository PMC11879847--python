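# Methods

`lpsprofiler` implements a functional-metagenomic workflow that asks whether
the lipid A acylation capacity of a patient's gut microbiome is associated
with response to anti-PD-1 immunotherapy. The workflow has five stages:
rule-based prediction of each bacterial species' LPS structure from its
pangenome, quantification of LPS categories and genes in patient
metagenomes, ratio statistics, functional enterotyping, and nonparametric
association tests. Because the workflow is exercised on simulated cohorts
with planted effects, every stage can be validated against known truth.

## LPS structure prediction

A gene is attributed to a species when it is encoded by at least 50% of the
genomes in that species' pangenome (frequency >= 0.5, boundary inclusive).
Gene calls from two annotation schemata are merged by union (maximum
frequency), except *lpxM*, for which only the first schema is trusted — the
second systematically over-calls it in taxa known not to encode it.

Classification follows the canonical lipid A biosynthesis pathway:

| capacity | rule |
| --- | --- |
| lipid IVA (LPS-encoding) | *lpxA*, *lpxB*, *lpxC*, *lpxD*, *lpxK* all present |
| KDO2-lipid IVA | additionally *waaA* |
| tetra-acylated | LPS-encoding, no *lpxL* |
| penta-acylated | *lpxL* without *lpxM*/*lpxJ* |
| hexa-acylated | *lpxL* and at least one of *lpxM*, *lpxJ* |

*lpxH* belongs to the backbone pathway and is carried in the vocabulary,
but the operational rule deliberately omits it: the five-gene rule is the
definition behind the reported taxon counts, and requiring *lpxH* would
change them. Likewise the lipid A modification genes (*lpxE*, *lpxF*,
*pagL*, *pagP*) are carried through reporting but never alter the acylation
class. A species encoding both hexa routes is recorded with both, and
counted once in hexa totals. Taxa without a pangenome entry are treated as
non-LPS (conservative) and logged.

The classifier is verified exhaustively against an independently written
truth table over all 1,024 subsets of the ten classification genes.

## Quantification

* **GCPM** (gene count per million), used for single cohorts:
  `GCPM_i = (q_i/l_i) / sum_j(q_j/l_j) * 1e6`, with raw mapped reads `q_i`
  and gene length `l_i` (bp). Columns sum to 1e6 by construction.
* **CPM** on batch-adjusted counts `A_i`: `CPM_i = A_i / sum(A) * 1e6`.
  The pooled pipeline's default first log-transforms with a 1e-6
  pseudocount and then scales the transformed values to a million
  (`cpm_pipeline(mode="pseudolog")`); the plain formula on raw adjusted
  counts is available as `mode="raw"`. Both orders are exposed because the
  two descriptions of this step are not mutually consistent; the
  pseudocount is always added *before* the log, since the logarithm of zero
  is undefined.
* **CLR**: per-sample `log(x_i) - mean_j log(x_j)` after closing the
  composition; zeros are replaced by half the smallest nonzero value of the
  sample (multiplicative replacement — deterministic, no tuning).
* **Batch adjustment** is intentionally simple plumbing: per feature, the
  median log-count of each batch (over samples where the feature is
  detected) is centred to the feature's global median by a multiplicative
  factor. Zeros stay zero, single-sample batches are left unadjusted with a
  warning, and a single batch is the identity. It removes constant
  multiplicative study effects only; it is not a count-model batch
  correction and does not attempt to preserve group effects the way
  dedicated tools do.
* **Filters**: KEGG-ortholog features detected in fewer than five samples
  are dropped (a feature detected in exactly five is kept); per-gene
  analyses exclude samples where the gene is undetected (zero), and the
  number of exclusions is reported.
* **Ratios** (hexa:penta category abundance, lpxM:lpxL gene abundance) are
  guarded: zero-denominator samples are flagged undefined (NaN) and
  excluded from group summaries, mirroring the zero-sample exclusion.
* Natural logarithms are used wherever a base is unstated, consistently
  with the Jensen–Shannon convention below.

## Enterotyping

Samples are clustered on relative-abundance functional profiles using the
square root of the Jensen–Shannon divergence (natural log), which is a
metric bounded by sqrt(ln 2); plain JSD is available by flag. Clustering is
k-medoids: instances with at most 5,000 candidate medoid sets are solved
exactly by enumeration, larger instances by the classical PAM BUILD+SWAP
local search (steepest improving swap, ties to the lowest sample index —
deterministic without a seed). The exact small-instance path exists because
BUILD+SWAP, like any local search, can stall in local optima that exhaustive
search avoids at negligible cost at these sizes.

The number of clusters (default range 2–6) maximizes the Calinski–Harabasz
index computed purely from pairwise distances via the Huygens identity
`sum_i d(x_i, c)^2 = (1/n) sum_{i<j} d(x_i, x_j)^2`, since JSD space has no
coordinates; ties go to the smaller k. Between-class analysis centres
profiles per feature (covariance, not correlation, scaling), eigendecomposes
the size-weighted covariance of class centroids, and reports the
between/total inertia ratio, with a permutation null available. PCoA is
classical scaling with non-positive eigenvalue axes dropped.

## Association statistics

* Mann–Whitney, two-tailed: exact enumeration when both groups have at most
  8 untied values, otherwise the tie-corrected normal approximation.
* Kruskal–Wallis with post hoc Dunn z tests from pooled midranks
  (tie-corrected) and family-wise Bonferroni adjustment
  (`p_adj = min(1, p × #pairs)`). Bonferroni controls the family-wise error
  rate, not the false discovery rate; it is applied here as the
  conventional companion of the Dunn test.
* Two-proportion Z-test with pooled variance and no continuity correction,
  one-tailed by default; a degenerate pooled proportion (0 or 1) returns
  p = 1 with a warning.
* NMDS: each restart minimizes Kruskal stress-1 by SMACOF with isotonic
  regression; the first restart starts from PCoA coordinates, the rest from
  random Gaussian configurations. Restarts stop early when the Procrustes
  RMSE between the two best solutions (after scaling to unit total
  variance) drops below 1e-4, i.e. independent starts agree on one
  configuration; otherwise all `n_restarts` are used and the lowest-stress
  solution is kept. Group separation on an axis is tested with a two-tailed
  pooled-variance t-test.
* Responder mapping for clinical metadata: complete response, partial
  response and stable disease map to R; progressive disease to NR.

## Synthetic cohorts

The generator emulates the study's data structure, not its sequences: a
two-arm cohort (default 50 responders, 50 non-responders) pooled over 3
study batches, 150 species of which 70% encode LPS (10% tetra, 35% penta,
15% hexa via *lpxM*, 10% hexa via *lpxJ* — LPS-encoding taxa are common in
these cohorts, and the penta class dominates as it does among human gut
Gram-negatives), and 100,000 classified reads per sample.

* Base species abundances are log-normal (meanlog 0, sdlog 1), shared
  across samples — heavy-tailed, like real gut communities.
* Planted effects follow the reported directions: responders' hexa-encoding
  taxa are multiplied by 2 (the hexa:penta ratio roughly doubles in
  responders; because the ratio divides two categories of the same
  composition, the planted fold equals the expected ratio contrast), and
  non-responders' LPS-encoding taxa by 1.5 (total LPS load higher in
  non-responders; no abundance-scale effect size is reported, so a
  moderate, clearly detectable fold was fixed once).
* Batch effects are log-additive per (batch, species), N(0, 0.3²) —
  multiplicative study effects of the kind batch correction targets.
* Taxon counts are Dirichlet-multinomial with concentration
  1/dispersion (default dispersion 0.005; multinomial at 0). Gene counts
  are Poisson with expectation proportional to taxon count × gene presence
  × gene length, emulating a read-mapping quantifier; gene lengths default
  to U(600, 3000) bp, the typical bacterial ORF range, which exercises the
  length term of GCPM.
* Pangenome frequencies are drawn U(0.8, 1) for encoded genes and
  U(0, 0.2) otherwise, so thresholding at 0.5 recovers the planted category
  exactly; annotation noise flips calls across the 0.5 boundary per
  evidence channel with a configurable rate, with schema-A *lpxM* calls
  exempt by default (reproducing the one-schema curation of *lpxM*).
* Everything is a pure function of (config, seed); per-stage generators are
  derived from the global seed by fixed offsets.

What the generator does **not** emulate: read-level sequence content,
strain variation, compositional correlations between unrelated taxa,
non-multiplicative batch artefacts, or covariate structure (age, antibiotic
exposure). Passing tests therefore demonstrate that the pipeline's
inference machinery is correct and calibrated under its stated noise model,
not that the biological effect sizes of any particular patient cohort will
be reproduced.

## Numerical choices and problem sizes

Distance matrices are validated (symmetry 1e-10, zero diagonal); the CLR
and category partition identities are enforced to 1e-9; GCPM/CPM column
sums to 1e-6 relative. PAM swaps require an improvement of more than 1e-12
to avoid cycling on ties. NMDS uses a SMACOF tolerance of 1e-7 on relative
stress decrease and at most 300 iterations per restart; the orchestrated
pipeline defaults to 100 restarts, which reaches the global configuration
reliably at cohort sizes of order 100 samples. Monte-Carlo validation uses
100 simulation seeds for power and fold-recovery checks and 100–200 seeds
for null calibration; cluster-recovery checks use 60-sample,
40-feature communities with three planted clusters.

## Known limitations

* The batch adjustment removes only constant per-batch multiplicative
  shifts; confounded batch/group designs are not protected.
* The pseudolog CPM default produces negative values for undetected genes
  (log of the pseudocount); downstream per-gene tests exclude undetected
  samples first, but users consuming the matrix directly should be aware.
* CH-based selection cannot return k = 1; a cohort without cluster
  structure will still be split, and the non-informative-distance guard
  only catches the fully degenerate case.
* Exact Mann–Whitney enumeration is skipped in the presence of ties at any
  sample size (the tie-corrected normal approximation is used instead).
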