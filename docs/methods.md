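# Methods

This note records the models, defaults and numerical choices behind
`notchsig`, and what the synthetic-data tests do and do not establish.

## The coherence score and its null

For genes g1…gn in a cohort, the coherence score is

    CS = (2 / (n(n−1))) · Σ_{i<j} r(g_i, g_j)

with r the Pearson correlation computed on the cohort's analysis scale:
log2(CPM+1) for count platforms, stored log2 intensities for microarrays.
An average of correlations among n variables is bounded below by −1/(n−1)
(the equicorrelation bound) and above by 1; every computed score is
checked against these bounds in the test suite. Spearman correlation is
available by flag; Pearson is the default because the coherence-score
literature uses it.

Significance is an empirical tail probability against random gene sets
drawn from the same gene universe (sampling without replacement within a
set, independent sets across draws, mandatory seed). Two size policies
exist:

* `pooled` (default): set sizes uniform on [3, 100]. This mirrors the
  original formulation, but mixes sampling variances across sizes — small
  sets dominate the null's tails.
* `matched`: all draws of the signature's own size; statistically cleaner
  and used in the calibration tests.

p is the plain count fraction k/N with no +1 smoothing; k = 0 is reported
as the explicit bound "< 1/N" (`p_is_bound`), matching how vanishing
empirical p-values are conventionally printed (e.g. < 10⁻⁵ at
N = 100,000). The 100,000-draw null is tractable because the universe's
gene–gene correlation matrix is computed once (float32) and each draw is a
fancy-indexed submatrix sum, batched by set size.

## Screening

Differential expression uses per-gene OLS on the analysis scale with the
condition indicator and categorical covariates; the condition
coefficient's t statistic gives two-sided p-values (n − p degrees of
freedom) and BH adjustment across genes. This is a deliberate
simplification of a negative-binomial GLM: the selection logic downstream
consumes only per-gene (log2FC, p) tables, so any DE backend producing
such tables can be substituted. On fully null simulations the p < 0.05
rate is within binomial noise of 0.05 (tested over 20 replicates).

The left-skew gate is a one-sided binomial excess rule: a contrast passes
when its fraction of p ≤ 0.05 exceeds 0.05 + k·√(0.05·0.95/m) with k = 3
(m = number of genes, minimum 100 p-values). The published workflow judged
skewness from histograms; a deterministic, calibratable rule is required
for a pipeline, and k = 3 gives a false-trip rate of ~0.1% on uniform
p-values. The DEG gate is BH-adjusted p < 0.05 with no fold-change floor
(configurable; the source workflow states no threshold). Both the gate
and the contrast grid (condition pairs × {8h, 72h, pooled}) are
config-driven rather than hard-coded, because the exact enumeration that
produced "74 comparisons" in the original study is not fully specified.

Universe filtering removes genes with < 10 total counts (or max CPM < 1
in `cpm` mode) and symbol classes matched by configurable regular
expressions (immunoglobulin segments, ribosomal genes, readthrough
transcripts, Y-linked genes, XIST). Y-linked genes cannot be recognized
from symbols alone without an annotation database; the default list names
the common ones explicitly. Filtering is idempotent.

## Size optimization

The coherence curve records CS and empirical p of every top-k prefix of a
ranked candidate list (k in [3, 50] by default, shared pooled null).
Within the size window [10, 30] the optimizer filters to minimal
empirical p, then maximal CS, then returns the smallest k. One property
of this rule matters for interpreting results: when a candidate list
begins with a homogeneous co-expressed block (as the synthetic generator
plants), the true CS is flat over all prefix sizes inside the block and
the empirical p saturates at its bound for the whole window, so the
tie-break resolves on sampling noise of nested running means — which
systematically favours the window's lower edge. Measured over 50 seeded
runs with a 20-gene block at correlation 0.3, the chosen size falls in
[15, 25] only ~38% of the time (mostly 10–16). Real candidate lists are
heterogeneous (correlation strength decays down the ranking), which is
what gives the curve an interior optimum; the homogeneous-module
simulation is a boundary case for the optimizer, not a typical one. The
corresponding end-to-end recovery test documents this behaviour and is
expected to fail under the homogeneous generator.

Candidate retention uses the strict rule CS > 0.2.

## Normalization and scoring

TMM factors follow the trimmed-mean-of-M-values definition: against a
reference sample (the one whose upper-quartile relative expression is
closest to the cohort mean — deterministic), gene-wise log2 ratios M and
abundances A are computed over genes expressed in both samples, doubly
trimmed (30% on M, 5% on A, both sides, average-tie ranks), and combined
as a precision-weighted mean with inverse approximate binomial variances
as weights; factors are rescaled to geometric mean 1. The implementation
agrees with the canonical R implementation to 1e−6 relative tolerance on
random count matrices (cross-checked in the test suite). Exact invariance
to depth scaling of a single sample holds for M and the trim but not for
the weights (the reference term does not rescale), so factor invariance is
approximate at the sub-percent level.

The signature score of a sample is the mean over signature genes of the
gene-wise Z-score (ddof = 1) of normalized expression. Counts are taken to
log2(TMM-CPM + 1) before Z-scoring: Z-scores of raw counts would be
dominated by high-expression genes, and the microarray arm is log2 by
construction, so the log scale keeps the two platforms comparable. When
every signature gene is scored the cohort mean score is 0 by construction.
Missing or zero-variance genes are dropped with a warning listing them;
scoring is refused when more than half the signature would be dropped,
because a silently partial signature changes the measurand.

The relative score is treatment − matched ground state (same cell line,
timepoint, replicate; group-mean fallback when no exact partner exists),
so pathway activation is positive. The underlying convention is
direction-ambiguous in prose descriptions; this orientation makes
"activation raises the score" literal.

## ROC, GSEA, similarity, clustering

AUC uses the midrank Mann–Whitney estimator; the 95% CI uses the DeLong
placement-value variance (the default of the standard R ROC tooling,
against which the implementation is cross-checked to 1e−9), clipped to
[0, 1]; a stratified bootstrap CI is available by flag. The AUC equals an
all-pairs concordance count (ties half) to 1e−12 on random instances.

The pre-ranked enrichment score walks the ranked list with hits stepping
up by |score|^weight (normalized over hits; weight 1 default) and misses
stepping down by 1/(N − N_hits); ES is the extremal deviation, sign
retained. A set covering the whole list has no misses and is rejected.
The null permutes hit positions (gene-label permutation; phenotype
permutation does not exist for pre-ranked input), 1000 permutations by
default, mandatory seed. NES = ES / mean(|same-sign permutation ES|), p is
the exceedance fraction within the same-sign stratum. Ranking metrics:
signed test statistic ("wald") or −log10(p)·log2FC, descending,
alphabetical tie-break; zero p-values are floored at the smallest positive
float and flagged.

Set similarity is Jaccard |A∩B|/|A∪B| or overlap |A∩B|/min(|A|,|B|)
(Jaccard ≤ overlap always). Clustering is complete-linkage on Euclidean
distances via scipy, with rows pre-sorted by label so tie resolution does
not depend on input order; trees export to Newick through scikit-bio.

## Network centrality

Distances are unweighted shortest-path (hop) lengths to the hub, even on
weighted edge lists, because published mean distances on this scale are
small integers consistent with hop counts (weighted mode is a flag).
Genes absent, isolated, or in another component are missing and excluded
from the mean (fraction reported). The null draws exactly size-matched
random sets from the network's non-hub nodes — the only unambiguous
reading of "sizes comparable" — and p counts random sets with strictly
smaller mean distance. Because hop-count means are discrete, the strict
rule sheds the tie mass: p = 1 is unattainable whenever the observed set
itself can be redrawn, and the p distribution under random signatures is
sub-uniform by the tie mass. Tests therefore compare against exhaustive
enumeration on small graphs rather than a continuous uniform.

## Composite alteration score

Per patient, events over the core Notch genes (NOTCH1–4, DLL1/3/4,
JAG1/2) are summed: −1 for truncating, missense and homozygous-deletion
events, +1 for amplifications, 0 for none. Structural variants default to
0 and are configurable, since the scoring rule never assigns them a
direction. Missense events score −1 uniformly even though some missense
mutations are activating; this keeps fidelity to the published rule at
the cost of biological nuance. Scores partition patients into activation
(> 0), inactivation (< 0) and wild-type (= 0); patients whose events
cancel land at 0 and are flagged `mixed`, because the sum cannot
distinguish them from unaltered patients. Multiple events count once per
recorded event, with no per-gene capping.

## Synthetic data: what it emulates and what it does not

The generators are first-class, tested code and define the conditions the
pipeline is validated under:

* **Cell-line experiment** — 6 cell lines × {notch_on, ground, notch_off}
  × {8h, 72h} × 3 replicates (108 samples); negative-binomial counts
  (variance μ + φμ², dispersion φ = 0.1) with log-normal gene means
  (log2 mean 6, sd 2), cell-line effects (sd 0.5 in log2) dominating
  timepoint effects (sd 0.2), per-sample depth variation (sd 0.2), and
  optional additive log-scale batches tied to replicates. The default
  universe is 5,000 genes with 200 Notch-responsive ones shifted ±e/2
  around the ground state (e = 2 log2 units), so the ground state is the
  midpoint of activation and blockade.
* **Patient cohort** — 500 samples, microarray-like log2 intensities; a
  20-gene module loads on one shared latent factor with loading √ρ
  (ρ = 0.3 default), giving expected pairwise correlation exactly ρ;
  background genes independent; heterogeneous per-gene means/scales
  (Pearson-invariant); PAM50-style subtype labels.
* **Alteration table** — per-patient, per-class Bernoulli events on a
  uniformly chosen core gene.
* **Network** — Barabási–Albert preferential attachment (connected by
  construction), highest-degree node relabelled as the hub; requested
  gene symbols placed on random nodes.

All generators are byte-deterministic under a fixed seed. What passing
tests on these data do **not** show: real cohorts have correlated
backgrounds, batch structure confounded with biology, heavy-tailed
library sizes and alias-ridden gene symbols; the homogeneous planted
module is a stylized extreme (see the size-optimization note above); the
synthetic network has no biological wiring, so centrality p-values on it
are calibration checks, not biology.

## Problem sizes in the validation suite

The test suite runs the empirical null at N = 100,000 draws over a
5,020-gene universe once (the headline bound check) and at N = 2,000–5,000
elsewhere; recovery of the planted correlation uses 15 replicate cohorts
of 2,000 samples; the end-to-end size-recovery simulation uses 50 seeded
runs on 1,020-gene cohorts. These sizes were chosen so the full suite
exercises every property at meaningful precision in a few minutes on one
CPU.

## Known limitations

* No gene-identifier alias resolution; identity is the upper-cased symbol.
* The OLS screening stage ignores count heteroscedasticity; it is a
  stand-in contract for any DE backend, not a recommendation.
* The pooled null mixes set sizes; size-matched nulls are preferable when
  comparing signatures of fixed size.
* GSVA/ssGSEA-style scoring, survival analysis and external database
  access (STRING, MSigDB, cBioPortal, GEO) are out of scope.
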