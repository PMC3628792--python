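# Methods

This note documents the statistical procedures, the synthetic-data model, the
tunable parameters, and the design choices made where the design was
genuinely open.

## Normalization and filtering

Raw bead-array intensities are strictly positive. Normalization is the
percentile-shift scheme: log2 transform; subtract the per-sample 75th
percentile of the log2 values; subtract the per-gene median across samples.
"Dividing" by the percentile and the median is performed on the raw scale,
i.e. as subtraction after the log transform — division of log values is
scale-pathological. The percentile uses linear interpolation between order
statistics (the numpy default); the convention and both centering vectors are
recorded in the `NormalizationReport` so a reader can reproduce any value.
Median centering uses all samples.

The two centering steps do not commute and the composite map is **not**
idempotent: re-centering gene medians perturbs the sample percentiles.
The guaranteed postconditions are exactly: per-sample p75 of the step-1
values = 0, and per-gene median of the output = 0. Multiplying one raw sample
by a constant leaves its normalized values unchanged.

Detection flags (P/M/A) define the analysis universe: a gene is kept when it
has ≥ `min_informative` (default 1) flags in {P, M} across all samples. The
universe default for every enrichment stage is this detection-filtered set
rather than the whole genome — detection-filtered universes avoid abundance
bias; a whole-annotation universe remains available by passing the full
annotation unrestricted. The choice is visible in each result's N column.

## Differential-expression selection

Three lists mirror a two-strain × {control, LPS} × duration design:

* **List 1** — Mann–Whitney U on the strain contrast under LPS at one
  duration, BH-adjusted p < `p_threshold`, plus direction-free raw-scale fold
  change ≥ `fc_threshold` (default 1.5). The U statistic uses midrank ties;
  the p-value is exact (full enumeration) when n1+n2 ≤ 12 and the pooled
  data is tie-free, otherwise the normal approximation with tie and
  continuity correction. The method used is recorded per run.
* **List 2** — fold change ≥ threshold between LPS and control within either
  strain ("at least one condition"); no rank test gates this list.
* **List 3** — balanced two-way ANOVA. The factor pair is configurable
  (strain × treatment by default, treatment × duration supported); the
  BH-adjusted p of one declared main effect (default: strain) is
  thresholded. The choice of thresholded factor is logged on every run.

Fold changes are ratios of anti-logged group means, reported direction-free
(max(r, 1/r)) for thresholding and signed in the reports. BH adjustment is
the step-up procedure, capped at 1, ties preserved.

A replication caveat: with r arrays per group, the exact two-sided
Mann–Whitney p-value has minimum 2/C(2r, r). At r = 3 that minimum is 0.1,
so a BH-corrected 0.05 threshold can never fire; List 1 becomes informative
from r ≳ 5–6 (at r = 6 the minimum is 2/924 ≈ 0.0022). The pipeline
therefore requires ≥ 2 replicates per compared group and the test suite
exercises List-1 power at r = 6, while end-to-end recovery at the default
r = 3 flows through Lists 2 and 3. A permissive p threshold of 0.5
(less-stringent screening mode) is supported and flagged prominently in the
logs because it is unusually lax.

Lists are combined either as the full union (default) or as genes shared by
at least 2 of the 3 lists; both readings exist in the source material, so the
rule is explicit, recorded in provenance, and the 7-region Venn partition is
always reported rather than silently resolved.

## Clustering

Agglomerative clustering of the combined gene set on expression profiles:
average linkage (default) or complete linkage, on 1 − Pearson correlation
(default) or Euclidean distance, cut into k = 2 groups. The merge history is
retained. Tie-breaks in minimal distance follow scipy's deterministic
agglomeration order; on continuous expression data exact ties have measure
zero, and partition invariance under input permutation is tested on tie-free
data. Constant profiles have undefined correlation distance and are rejected
with an explicit error.

## GO over-representation

For a query of n genes and a term with K members in a universe of N, the
p-value is the hypergeometric upper tail P(X ≥ k), computed with log-gamma
stabilization. Terms are tested only when 2 ≤ K ≤ 500 (degenerate and
uninformative terms inflate the BH family); BH correction spans exactly the
tested terms. Annotations are flat term → gene sets: no ontology-graph
ancestor propagation is attempted, since the flat form is what the input
formats (two-column TSV, GMT) carry.

## Promoter motif enrichment

PWMs are 4 × L column-stochastic matrices; count matrices (JASPAR or
TRANSFAC text) are regularized with a pseudocount c: p = (count + c) /
(total + 4c). A window of length L scores
`sum_j log2(p[base_j, j] / q[base_j])` against a background base composition
q — by default the composition of the background promoter set, uniform
switchable. A window is a hit when its score reaches `threshold_frac`
(default 0.85) of the maximum achievable score; both strands are scanned
(reverse-complement matrix over the forward sequence). Windows containing N
are skipped rather than penalized, which avoids distorting the background
model. Scanning uses float32 accumulation with a 1e-6 hit-calling slack; the
test suite checks batch scanning against a per-window float64 oracle.

Statistics are gene-level, not site-level: a gene counts once if its
promoter has ≥ 1 hit, matching a prevalence reading of motif enrichment.
With hits_set of |set| and hits_bg of |bg| (the background always includes
the query set, keeping the hypergeometric sampling frame coherent):

* EF = (hits_set/|set|) / (hits_bg/|bg|), NaN when hits_bg = 0;
* p = P(X ≥ hits_set) for X ~ Hypergeom(N=|bg|, K=hits_bg, n=|set|);
* BH across the PWM library.

EF of the background against itself is identically 1; raising
`threshold_frac` never adds hits.

## miRNA aggregation and empirical enrichment

Each prediction table maps miRNA → predicted target genes. Per miRNA and
algorithm, the count is |targets ∩ enriched TFs|; counts are summed across
algorithms and miRNAs ranked by the sum (descending). Tie-break: more
algorithms with a nonzero count, then larger minimum per-algorithm count,
then lexicographic id — a declared convention, not an inferred one. miRNAs
with sum 0 are excluded from the report but counted in provenance. An
optional family map collapses miRNA ids to families (max count per family
and algorithm), because family definitions are database-specific and cannot
be derived from the inputs.

The empirical functional-enrichment p-value for a (miRNA, GO term) pair
draws B (default 1000, minimum 100) resamples of |targets| genes uniformly
without replacement from the universe and applies the add-one rule
p = (1 + #{overlap ≥ observed}) / (1 + B), so p ∈ (0, 1] and the estimate is
never exactly zero. This is a deliberate simplification of
stratified-resampling schemes that condition on 3′UTR length: no such
covariate exists in this package's inputs, so resampling is uniform. As
B → ∞ the estimate converges to the exact hypergeometric tail, which the
tests verify by enumeration on a 6-gene universe. Significant pairs
(BH-adjusted across all tested pairs) are attached to the ranked report;
candidates without a significant term carry an empty annotation column.

## Synthetic data model

The generator emulates a two-strain bead-array experiment: 2 strains ×
{control, LPS} × {24h, 48h} × `n_replicates_per_condition` arrays.
Intensities are Gaussian on the log2 scale (baseline per gene ~
N(`baseline_log2_mean` = 8, `baseline_log2_sd` = 1.5), noise SD
`noise_sd_log2` = 0.4) and exponentiated for the raw file, so planted
effects are exactly log2 fold changes. Planted structure:

* `frac_strain_de` (default 0.05) of genes carry a signed log2 effect
  (±1.5) on the first strain — the "strain" cluster;
* `frac_lps_de` (default 0.05) of genes carry a signed log2 effect (±1.5)
  under LPS in both strains — the "lps" cluster; the two sets are disjoint;
* flags: per sample, A below 0.98× the `flag_absent_quantile` (default
  0.05) raw quantile, M within ±2% of it, P otherwise (an assumed
  convention — only the flags' use, not their rule, is specified upstream);
* GO terms sampled without forced disjointness; one planted term per
  cluster draws `planted_go_enrichment_frac` (0.6) of its members from the
  cluster;
* promoters are uniform-random 3-kb ACGT sequences; PWMs have
  consensus-dominated columns (0.85–0.97 of the mass on one base), which
  emulates the sharp core positions of curated TFBS matrices and makes sites
  sampled from the matrix recoverable at the 0.85 scan threshold — 5 of the
  15 library PWMs are planted into the strain cluster's promoters at
  `motif_plant_rate` = 0.6, one sampled site per promoter at a uniform
  position and strand;
* every PWM maps to a distinct TF gene outside the planted clusters; the
  planted miRNA's intended target set is the 5 TF genes of the planted PWMs;
  each of two prediction tables gives the planted miRNA
  ceil(coverage × 5) = 4 of those TFs (coverage 0.8, independently sampled
  per table) while 29 decoy miRNAs target universe genes at rate 0.05.

Defaults are desk-scale study conditions chosen once: n_genes = 1000,
50 GO terms, 30 miRNAs. What the generator does **not** emulate: scanner or
spatial artifacts, probe sequences, correlated noise between genes, realistic
promoter base composition or repeat structure, and 3′UTR-dependent target
prediction biases. Passing tests therefore demonstrate correctness of the
inferential machinery under the planted model, not performance on real
arrays.

One generalization is deliberate: the original pooled design (one array per
condition, pooled biological samples) is widened to ≥ 2 independent arrays
per condition, because rank tests and replicated ANOVA are degenerate with a
single array per cell.

## Pipeline, determinism, and numerical conventions

Stage order: normalize → flag filter → DE selection → Venn combination →
clustering → per-cluster GO enrichment → per-cluster motif enrichment →
PWM→TF mapping → target aggregation → empirical enrichment → report. The
PWM→TF-gene mapping is an explicit two-column input, since turning an
enriched binding profile into a TF gene id is an identification step that
should not be implicit. Every stage logs input/output counts into the run
provenance; an empty intermediate set produces a structured
"terminated at stage X" result instead of an exception.

Identical config+seed reproduces byte-identical report files. To make that
hold, written provenance deliberately contains no wall-clock timestamps
(they appear only in the log stream). All randomness flows from the config
seed through `numpy` `SeedSequence` spawning; the empirical-enrichment
stage derives one child seed per (miRNA, term) pair.

Numerical conventions: hypergeometric tails via log-gamma-stabilized exact
summation; ANOVA sums of squares computed vectorized over genes with a
zero-residual guard (noiseless planted effects give F = ∞, p = 0 when the
effect SS is positive, p = 1 otherwise); BH capped at 1 with ties preserved;
motif hit-calling tolerance 1e-6 under float32 batch scanning.

## Known limitations

* List 1 has no power at the default 3 replicates (see above); this is a
  property of the exact rank test, surfaced rather than hidden.
* Uniform FAME-style resampling ignores target-set covariates (3′UTR
  length, expression level); p-values on real prediction tables will be
  anti-conservative for miRNAs with many long-UTR targets.
* Flat GO annotations: without ancestor closure, enrichment of specific
  terms does not propagate to general ones.
* PWM scanning uses a fraction-of-maximum LLR threshold; matrices whose
  maximum achievable score is near zero (nearly uniform columns) make the
  threshold semantics weak — library matrices are assumed informative.
* The test surface scales simulations to desk size (hundreds to a thousand
  genes); these sizes are the package's declared study conditions.
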