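# Methods

## The screening model

The screen targets a longitudinal design with one pooled small-RNA library
per age. With a single sample per timepoint there is no within-age variance
to estimate, so candidate selection is a deterministic trajectory
classification, not a hypothesis test. The package treats the following as
the defining pipeline, in order: per-sample depth normalization, per-locus
coverage filtering, pairwise log2 ratios, unidirectional trend
classification, ranking.

**Depth normalization.** All samples are scaled *down* to the shallowest
library: values are multiplied by min(N)/N_s, where N_s is the sample's total
read count. The minimum-depth convention (rather than counts-per-million)
preserves the interpretation of values as achievable read counts at the
common depth. The operation is idempotent and order-preserving within a
sample; classification downstream is invariant to it whenever a uniform
per-sample factor is applied, because trend calls depend only on per-feature
ratios across timepoints up to the per-sample scale factors, which cancel in
consecutive-step ratios only when depths are equalized first — hence
normalization precedes classification.

**Locus assembly and coverage.** Reads are 0-based half-open intervals.
Two reads join the same locus iff connected by a chain of pairs whose gap
(next.start − prev.end) is at most `merge_distance` (default 0, which merges
overlapping *and* book-ended reads — the `bedtools merge` convention; the
formal gap rule is what the assembly oracle tests pin down). Coverage is mean
per-base depth, Σ read lengths / locus length. The 6× cutoff is inclusive
(coverage = 6.0 passes) and applies per timepoint: a feature below the cutoff
at any age is excluded from classification entirely and recorded in the
filter log, since it cannot contribute a trustworthy ratio at every step.
"Coverage" could alternatively be read as a multiple of a baseline
sequencing rate; mean per-base depth is the standard reading and is exposed
as `ScreenConfig.coverage_cutoff` rather than hard-wired.

**Trend classification.** For consecutive ages, r = (Exp(t+1)+c)/(Exp(t)+c)
with pseudocount c (default 0). The no-change band is the *open* interval
(1−ε, 1+ε), ε = 0.10: a ratio exactly at 1−ε is a down-step. A feature is
decreasing iff it has no up-step and at least `min_changing_steps` (default
1) down-steps; a fully flat trajectory is "none" — flat features are not
candidates. With c = 0, 0/0 steps are scored "no change" and x/0 (x > 0)
steps "up"; a small c is the right choice for raw counts and is a config
knob, not the default, because the reference workflow operates on
normalized expression.

Note the band is not inversion-symmetric: r ∈ (0.9, 1/1.1] is a no-change
step whose reversal 1/r ≥ 1.1 is an up-step. Consequently "reversing a
trajectory swaps decreasing and increasing" holds only for trajectories whose
step ratios avoid the two asymmetric zones (0.9, 1/1.1] and [1.1, 1/0.9).
This is a property of the band definition as written, not an implementation
artifact; the property suite asserts the flip outside those zones.

**Ranking.** Within each direction, candidates are ordered by expression at
the youngest age, descending. The rationale: among two similar decliners, the
one with several-fold higher starting expression is the more plausible
regulator in that cell type. Other keys could be defended (total abundance,
steepness); first-timepoint expression is the default and currently the only
implemented key.

## Synthetic data

`generate_trajectory_matrix` emulates the screen's input: 572 features over
ages 3–30 months by default, geometric trajectories value(t_k) = baseline ×
step_fold^k for monotone classes, constant for flat, and one randomly placed
inverted step for the nonmonotone class (the minimal violation of
unidirectionality). Baselines not specified explicitly are drawn lognormal
(median 50, σ_log 1.5) to mimic the heavy-tailed abundance distribution of
miRNA libraries. Default programmed effect: 30 decliners at 0.85× per step —
a step fold chosen to sit clearly outside the 0.9 band edge, as a screen
designer would program a positive control.

Noise models are stand-ins, not estimates: the pooled one-sample-per-age
design gives no empirical noise structure to fit. `lognormal(σ)` applies
median-preserving multiplicative noise; `negative_binomial(d)` draws counts
with variance μ + dμ². Because E[X₂/X₁] = (step fold)·(1 + CV²) + O(CV⁴), the
per-replicate ratio is a biased estimator of the step fold (~+11% at d =
0.1); the calibration test therefore checks the ratio of across-replicate
means, which is unbiased for the generative step fold. Passing tests
demonstrate recovery under these synthetic conditions; they say nothing
about biological replicate variance, batch structure, or mappability
artifacts in real libraries.

`generate_reads_for_loci` places each plan's reads on evenly spaced anchors
with bounded jitter, guaranteeing each plan assembles into exactly one locus
(so planned truth is unambiguous); plans whose span exceeds count × read
length are rejected rather than silently fragmented. Truth records the
realized read-union span.

`generate_qpcr_plate` shifts a target's expected Ct by −log_E(fold) (E =
amplification efficiency, default 2.0) relative to the control group, keeps
housekeeping Cts group-independent, and adds Gaussian per-well noise. At zero
noise the ΔΔCt pipeline inverts it exactly — the generator/analyzer adjoint
property the test suite enforces.

## ΔΔCt conventions

Ct > 36 wells are excluded *before* technical-replicate averaging (an
undetected replicate must not drag the mean); the cutoff is strict (36.0 is
retained). Multi-gene housekeeping normalization averages the housekeeping
Cts arithmetically, which equals geometric-mean normalization of linear
abundances. The ΔΔCt reference is the mean ΔCt of the control group (not a
single calibrator), so the control group's geometric mean fold is exactly 1
by construction. No efficiency correction is applied (folds are plain
2^−ΔΔCt). Linear-scale signals (hybridization/luminescence assays) use the
same arithmetic via `scale="linear"`, referenced to the control group's
geometric mean. Group summaries are arithmetic mean ± SEM of per-sample
folds, with SEM flagged undefined for single-sample groups.

## Mito Stress arithmetic

Background is defined by the rotenone/antimycin-A phase: each biological
sample's mean rot/AA OCR is subtracted from all of its measurements. The
residual rounding mean is re-subtracted so the post-subtraction rot/AA mean
is zero to within one ulp of the trace scale and the operation is idempotent
at machine precision (exact zero is not representable for generic doubles).
Technical-replicate wells are averaged cycle-wise per biological sample.
Basal respiration is the baseline-phase mean; maximal respiration defaults to
the FCCP-phase *maximum* (the common Mito Stress convention), with the phase
mean available by flag since either summary is defensible.

## Exact rank-sum test

U counts pairs (xᵢ, yⱼ) with xᵢ > yⱼ (+0.5 per tie). For tie-free data with
n₁+n₂ ≤ 20 the null distribution of U is built by the counting recurrence
N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1), and the two-sided p is twice the
smaller-tail probability, capped at 1 — the tail-doubling convention of
standard biostatistics software, which reproduces the familiar
complete-separation minima 2/C(n₁+n₂, n₁): 0.0022 for 6 vs 6, 0.0238 for
3 vs 6, 0.0006 for 7 vs 7 after 4-decimal rounding. With ties or larger
samples the tie-corrected normal approximation with continuity correction is
used and flagged in the result. The discreteness of the exact null makes the
test conservative: the simulated type-I error at nominal 0.05 for 6 vs 6 is
≈ 0.041.

One-way ANOVA is the classical fixed-effects F test; pairwise post-tests use
the pooled within-group mean square (df = N − k) with Bonferroni
multiplication over the planned comparisons, capped at 1. Repeated-measures
("mixed") designs over instrument time-series are out of scope; only the
ordinary one-way contract is guaranteed.

## Problem sizes and numerical choices

Test and acceptance runs use the study-scale design (572 × 6) where the
design itself is the point, 50-seed Monte-Carlo batches for screen
sensitivity, 200–500-seed batches for generator calibration, and 4000
simulated null datasets for the type-I error check — sizes chosen so the
Monte-Carlo standard errors are comfortably smaller than the bands being
checked. Log2 ratio tables are computed as log₂(a) − log₂(b) so antisymmetry
is exact in floating point. Ties in top-k selection are broken by feature ID
lexicographic order and logged when the tie crosses the k boundary.

## Known limitations

- The screen is deterministic by design; it attaches no uncertainty to a
  trend call and cannot, with one pooled sample per age.
- The noise models are generic stand-ins (see above); sensitivity estimates
  under them do not transfer to real biological replication.
- Locus assembly ignores CIGAR structure, soft-clipping and multi-mappers;
  reads are taken as plain intervals.
- No efficiency-corrected qPCR model, no standard curves, no multi-plate
  calibration.
- The unidirectional rule's band, taken literally as the open interval
  (0.9, 1.1), is asymmetric under trajectory reversal at the edges (see
  above).
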