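# Methods

This note documents the statistical procedures implemented in `orbitdx`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Data model

Counts live in a `CountMatrix`: probes × samples with each probe in one of
the four nCounter classes (Endogenous, Housekeeping, Negative, Positive).
Raw counts are non-negative integers; normalized matrices are fractional.
RCC files are read (and, for raw counts, written) per sample; cohort-level
data use a CSV dialect whose canonical probe order is Endogenous
alphabetical first, controls last, to keep written files diff-stable.
Normalized matrices are never written as RCC — that format semantically
holds raw instrument counts.

## Normalization

**Technical step.** For each sample, the background is
`mean + 2·SD` of the negative-control counts (SD with n−1 denominator, as
in R's `sd`). It is subtracted from every Endogenous and Housekeeping
probe and the result is floored at zero: negative expression is
meaningless and the downstream noise filter assumes non-negative counts.
Control probes pass through unchanged. At least two negative probes are
required (the SD is undefined otherwise). The step is idempotent only when
every negative count is zero.

**Biological step.** Each sample is rescaled so that its housekeeping
geometric mean equals the cohort-wide geometric mean of those means.
Geometric (not arithmetic) means are the standard for housekeeping
normalization of count panels; a +1 pseudocount is applied only inside the
log-mean so zero counts are tolerated, and a sample whose housekeeping
counts are all zero is an error naming the sample. Scaling preserves
within-sample ratios of Endogenous probes exactly. The order is technical
first, then biological.

**Basal-noise filter.** Per gene and disease group, a one-sided one-sample
t-test of the gene's counts against the group's background threshold (the
per-sample `mean + 2·SD` of negatives, averaged over the group's samples);
a gene counts as expressed overall if p ≤ α (default 0.05) in at least one
group. The test is per group rather than pooled, because expression "in at
least one group" is the retention criterion. Zero-variance groups are
resolved by position: strictly above the threshold → expressed (p = 0),
strictly below → not expressed (p = 1), exactly at it → p = 0.5 (the
t-statistic-0 limit), which keeps the filter monotone in the counts.
Positive-control (spike-in) probes are parsed and carried through all I/O
but take part in no computation: the workflow defines only
negative-control and reference-gene steps, so a positive-control
normalization would be an invention.

## Differential expression

Entity-vs-rest (not all-pairs) screening. For each expressed gene the
Shapiro–Wilk test gates the choice of test: a two-sided t-test when both
arms look normal (p ≥ 0.05 in each), the Wilcoxon–Mann–Whitney rank-sum
test otherwise. Arms with fewer than three samples, or with zero variance,
cannot be assessed by Shapiro–Wilk and default to the rank test. The
t-test is Welch's (unequal variances) by default — safer for the very
unequal group sizes of entity-vs-rest designs — with a flag for the pooled
variant. Direction is the sign of mean(entity) − mean(rest). Raw p-values
are Benjamini–Hochberg-adjusted *within* entity (the alternative, a global
adjustment across the three screens, changes little but mixes hypotheses
of different prevalence; within-entity was chosen and is the `p.adjust`
default behaviour a practitioner would get screening one entity at a
time). Overlap summaries report all pairwise intersections with both
directional percentages.

## Conditional inference tree

A deliberately simplified univariate conditional inference tree, not a
re-implementation of the full party/ctree influence-function framework
(whose exact statistic and multiplicity scheme the original description
leaves open):

* **Association test.** Per gene, a Kruskal–Wallis-type quadratic form on
  ranks. The permutation p-value uses exhaustive enumeration over distinct
  relabellings when there are at most 10,000 of them, Monte-Carlo sampling
  otherwise. Tie correction is omitted deliberately: for fixed data it is a
  constant factor, so the permutation p-value is identical and the
  statistic stays a strictly monotone function of the classical H.
* **Multiplicity.** Bonferroni across the candidate genes at each node;
  the winner must clear α (default 0.05) after adjustment. Ties in p
  (common when several genes hit the Monte-Carlo floor) break toward the
  larger observed statistic, then the panel order.
* **Cut-point.** The midpoint between adjacent sorted unique values
  maximizing the 2×k chi-square of split side vs class, ties toward the
  smaller cut-off; candidates must leave `min_node` samples per side
  (default 3 — the screening design has 3 samples per group). The left
  branch takes values ≤ cut-off.
* **Monte-Carlo budget.** `n_perm` (default 9,999) is the *refinement*
  budget: every gene is screened with 999 shared permutations, and only
  genes whose screen-stage exceedance count is small (≤ 20) are re-tested
  at the full budget. This keeps panel-wide scans affordable while giving
  the potential winners a p-value resolution fine enough to clear α/G —
  with 1364 candidate genes the winner needs p ≤ 3.7·10⁻⁵, so tree fits on
  the full screening panel should use `n_perm` around 10⁵.
* Trees are invariant to sample order and to strictly monotone transforms
  of any gene (rank statistics), and deterministic for a fixed seed.

Because every split's permutation p is Bonferroni-adjusted, under the null
the probability of *any* split is at most α family-wise; the test suite
checks calibration of the underlying permutation p by KS against uniform.

A note on tier order: when several planted markers each separate their own
group cleanly, their rank statistics are equal by construction (ranks see
only the ordering), so which marker lands in which tier is decided by
noise. Structure-recovery experiments therefore assert the recovered
*set* of split genes; the published three-tier ordering is one of the
equivalent arrangements.

## Binarized scores

Each panel rule is `gene, direction, cut-off` on the normalized-count
scale; the score is the number of rules that fire. Inequalities are strict
(a count exactly at the cut-off scores 0 for either direction) — the
printed cut-offs carry no boundary semantics, so the convention is
centralized in one function and can be flipped. The panels ship as a YAML
config. The union of the three panels is 36 distinct genes (AQP1, CLIC4
and NRP1 appear in two panels each), which the validation CodeSet adopts
as its target list together with five named reference genes (ACTB, B2M,
GAPDH, RPL19, RPLP0). The count of 36 is computed from the transcribed
rules, never hard-coded.

## Risk models

Three parametric forms (shift, two-parameter shift, plateau) with an
orientation sign `s`. As literally printed the shift forms *decrease* with
score, contradicting both the rising risk-vs-score curves and the scores'
construction ("1 = better chance of the event"); the default is therefore
`s = −1` (risk rises with score), with the verbatim curves available via
`s = +1`. The half-risk point of the shift form is at `x = a` under either
orientation. Three caveats are intrinsic to the printed models and are
surfaced rather than hidden:

* In the two-parameter shift form only `a − b` enters; fitting therefore
  reports the identifiable offset (in `a`, with `b = 0`) while the
  published pair is stored verbatim. With the published NSOI pair the
  offset is −115.9, far outside the 0–12 score range, so the literal NSOI
  curve is degenerate (≈ 1 for s = −1 everywhere on the score range).
* The plateau form saturates at `1/a`; the published `a = 0.8164` gives
  1.22 > 1, so "relative risk" there is not a probability. Raw values are
  exposed alongside a [0, 1]-clamped companion.
* Evaluation clips exponents at ±700, so predictions are finite for any
  score in ±10⁶.

Fitting computes the empirical risk (target-entity fraction) at each
distinct score and runs nonlinear least squares of the chosen form,
weighted by the per-score sample counts. The score→label association is a
likelihood-ratio test of a binomial logit GLM against the intercept-only
model. Because the shift form is forced monotone from 0 to 1, it cannot
represent a flat (null) risk profile — under no association the GLM p is
the meaningful diagnostic, not the fitted curve. Leave-one-out validation
refits the model on n−1 samples and evaluates the held-out sample's score.

## ROC and bootstrap

AUC is computed as the normalized Mann–Whitney U statistic (half credit
for ties), which equals the trapezoidal area under the ROC sweep; the test
suite holds this against an O(n²) pairwise oracle. Confidence intervals
are percentile bootstrap over stratified resamples (each class resampled
separately, 1000 iterations by default), so every resample contains both
classes by construction. The validation report assembles per-entity
scores, model risks, ROC + CI, GLM p, a samples × scores synopsis and an
alert list (default: lymphoma score ≥ 1 in a non-lymphoma sample).

## Synthetic cohorts

The generator emulates the study design, not the data: Endogenous and
Housekeeping counts are negative binomial (variance `m + d·m²`), negative
controls Poisson, positive controls a deterministic 4-fold spike-in ladder
(top count 4096), and a lognormal per-sample scale factor (σ = 0.2)
multiplies all probes so the reference-gene step has something to correct.
Defaults: baseline 200 counts, housekeeping 500, negative controls 10,
dispersion 0.05 — chosen as a plausible panel-count regime in which
reference-gene normalization recovers relative scale factors to within
about 5%, as the pipeline assumes. Entity effects are log2 fold changes on
named genes; relapsing NSOI carries the NSOI profile (expression could not
separate the two) under its own label. Because the published cut-offs span
5–5500 normalized counts, marker genes get per-gene baselines — the
geometric mean of each gene's direction-adjusted cut-off targets
(cut-off/2 for up rules, 2·cut-off for down rules) — so that a planted
±2 log2FC crosses every relevant cut-off, including for the three genes
shared between panels. The decision-tree preset instead plants effects on
PLA2G2A (severe/relapsing NSOI), RBM47 (IgG4-ROD) and AQP1 (mild NSOI),
with baselines (305/19/15) placed so the planted boundaries sit near the
published cut-offs (610/38/30).

What the generator does **not** emulate: real library-size and FFPE
degradation structure, gene–gene correlation, the heterogeneity of NSOI
sub-entities, or the cohorts' absolute count distributions. Passing
recovery tests therefore shows the machinery is correct and calibrated on
its stated model — not that the published accuracy transfers to patients.
The published cohort-derived numbers (gene-list sizes, Venn counts,
validation AUCs of 0.81/0.82/0.67) depend on unavailable patient data and
are deliberately not targets; synthetic experiments reproduce the
qualitative structure (marker recovery, score separation, the
lymphoma-overlap ordering) only.

## Problem sizes and tolerances in the test suite

Brute-force oracles (normalization arithmetic, BH step-up, exhaustive
permutation enumeration, pairwise AUC) run on 6–40-sample instances at
1e-9–1e-12 tolerances. Stochastic recovery experiments use the study's
cohort shapes: 48-sample validation cohorts at 2 log2FC (score AUCs
≥ 0.9; label shuffling collapses them to 0.5 ± 0.1 over 20 replicates),
four-group 15-per-group cohorts on the full 1364-gene panel for tree
recovery (≥ 18/20 seeds), 500-sample draws for risk-parameter recovery
(a = 6 ± 0.5, 10/10 seeds), and 1000-replicate null calibration of the
permutation p at 999 permutations. All stochastic tests run under fixed
seeds.

## Known limitations

* The CIT is univariate with no surrogate splits, ordinal responses or
  missing-value handling.
* The noise filter compares (possibly rescaled) endogenous counts against
  thresholds from untouched negative controls, mirroring the workflow it
  implements; after aggressive rescaling the threshold scale is
  approximate.
* The screening analysis treats 1364 genes as one panel; per-panel batch
  structure (two separate CodeSets) is not modelled.
* RCC parsing covers the per-sample text format with prefix-folded
  CodeClass dialects; RLF/CodeSet-definition files and batched archives
  are out of scope.
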