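# Methods

## Data model and quality gating

The pipeline's universal input is a Cq cohort: per-sample, per-target
quantification cycles with Bethesda diagnoses (NILM, LSIL, HSIL, CC, or
unknown for cell lines). Instrument values above 40 cycles, and wells with
no amplification, are *expression-negative*; they are stored capped at
exactly 40.00 rather than as missing so that every downstream ΔCq feature
is finite. This matters in practice: a cancer cell line in which the
downregulated epithelial mRNAs do not amplify at all gets a very large
(correct) DF precisely because the cap enters the features. Truly missing
wells cannot be distinguished from expression-negative ones in this
encoding; both are conflated under the cap.

Samples are excluded before analysis when an adequacy control indicates
insufficient template: DNA control (HMBS) mean Cq ≥ 35, checked first,
then RNA control (PGK1) mean Cq ≥ 35. The thresholds are inclusive and
configurable. The filter is idempotent, and a filtered cohort passes its
own filter.

Two diagnostic contrasts are supported: the screening contrast ≤LSIL
(NILM + LSIL) vs ≥HSIL (HSIL + CC), and NILM vs CC with intermediate
grades dropped.

## Pair features

For a pair (X; Y), ΔCq(X, Y) = Cq(Y) − Cq(X) = log2 C(X)/C(Y). The
canonical orientation names the downregulated member first (DU pairs such
as MAL-CDKN2A) and biomarkers before housekeeping references; within one
regulation class, panel order is kept. Orientation is a pure labeling
convention — flipping a pair negates its feature, and a trained weight
absorbs the sign, so classification is orientation-invariant (asserted by
test). Pair enumeration covers the eight biomarkers plus the RNA-adequacy
housekeeping mRNA (36 unordered pairs; the DNA control gauges genomic
template, not expression, and never enters features). Replicates are
averaged on the Cq scale before differencing — the geometric mean of
concentrations — and amplification efficiency is assumed to be exactly 2
per cycle.

In the pair screen, discriminatory power is reported orientation-free as
max(a, 1 − a) of the raw feature AUC, with the direction recorded
separately: a DU feature *falls* with severity, so its raw AUC is below
0.5 even when the pair is the strongest in the panel.

## Classifier

DF = w0 + Σ wᵢ·ΔCqᵢ, fit by logistic regression with negligible
regularization (C = 10⁸) so the DF is an unconstrained linear score.
Stratified 5-fold cross-validation (K configurable, shuffled with a fixed
seed) produces out-of-fold DF values for unbiased evaluation; the reported
weights are refit on all samples. Near-perfect separation produces a
large-margin solution with scale-unstable weights; a warning is raised.

Cutoff tuning scans the exact ROC sweep — midpoints between consecutive
sorted DF values plus ±∞, positives called by strict DF > cutoff — and
shifts the intercept so the chosen threshold maps to DF = 0 (hence DF = 0
itself is called low-risk). Five strategies: *basic* minimizes
|sens − spec|; *high-sens* requires sens > 90% with spec ≥ 80% and
maximizes specificity; *very-high-sens* requires sens ≥ 95% (the 95–99%
band is a target, not an exclusion — a perfect operating point satisfies
it); the two specificity-first strategies mirror these. Ties break toward
higher specificity. An infeasible strategy raises an error carrying the
best attainable operating point.

Borderline results: a DF within 10% of the observed values above and
below the cutoff — i.e. within 0.1·max(DF) above zero or 0.1·|min(DF)|
below — is flagged as gray-zone but the call is never changed. Two other
readings of "within 10%" (10% of the full range; the 10% of samples
nearest the cutoff) were considered; the per-side reading is used because
it treats an asymmetric DF distribution sensibly, and the flag threshold
is a parameter.

## Evaluation statistics

ROC AUC is computed as the mid-rank Mann–Whitney statistic U/(n₁n₀), ties
counted one half (identical to the trapezoidal empirical ROC area;
cross-checked against scikit-learn in tests). Its CI is the DeLong
placement-variance normal interval, clipped to [0, 1]. Sensitivity and
specificity CIs are exact Clopper–Pearson (beta-quantile) intervals —
this choice reproduces published intervals for 70/78 and 78/89 to the
printed decimals. Group comparisons use the two-sided Mann–Whitney U test
(exact enumeration when both groups have ≤ 8 tie-free values, otherwise
normal approximation with continuity and tie correction), with Bonferroni
per-comparison thresholds α/m. Rank correlations are Spearman. Report
percentages round half-up to one decimal.

## Replicate error propagation

The DF is linear in each target's Cq with net weight a_t = Σ(±wᵢ) over
pairs containing target t. For m targets in r replicates each, all r^m
replicate-choice combinations are enumerated (5⁵ = 3125 for the 4-pair
classifier) and a DF computed for each. Exact identities follow from
linearity and the product structure: the mean of the combination DFs
equals the DF of the per-target mean Cq, and the population variance of
the DF set equals Σ a_t²·Var(replicates of t). Dispersion is summarized
as CV = 100·SD/|mean| with the sample (n−1) SD by default (population SD
selectable; with unpublished raw replicates neither convention can be
singled out, and the identities above hold for the population form). A
single value has CV 0; a zero mean leaves the CV undefined. Products
beyond 10⁶ combinations require the seeded Monte-Carlo subsampling mode.

## Heat-map scaling

Each biomarker column is mapped to [0, 100] by a two-segment linear
transform anchored at the column minimum (0), median P50 (50, the white
point) and maximum (100). A single global linear map cannot hit all three
anchors for a skewed column, so the piecewise map is the minimal
construction honoring them; a flat segment (P50 equal to an extreme) maps
onto 50, keeping the white point invariant. Markers that fall with disease
are inverted *after* scaling (u → 100 − u), which fixes the white point
and is an involution. Anchors are cohort-wide extremes; robust percentiles
can be supplied instead by constructing the scale directly. Rows are
ordered FN, FP (cytology/classifier discrepancies), then concordant NILM,
LSIL, HSIL, CC.

## Synthetic cohort generator

The generator emulates the study design, not any particular dataset:
group sizes 61/28/42/36; per-target group mean Cq values anchored to the
ranges of the nine-specimen reference table and to the relative
single-marker performance ordering (CDKN2A strongest, TMPRSS4 weakest),
monotone in severity by construction (non-increasing for upregulated
targets, non-decreasing for downregulated, flat for housekeeping — a
violated direction is a configuration error). Noise is Gaussian on the Cq
(log2 concentration) scale: within-group biological SD 2.0 cycles per
target, technical replicate SD 0.15 cycles (consistent with the low
published DF CVs). A per-sample latent severity z ~ N(0,1) carries a 0.4
loading on each directional target (marginals stay Gaussian with the
stated SD) and drives the covariates: HPV load, emitted directly on the
2^-ΔCq relative scale with group-wise negativity probabilities taken from
published positivity counts (26.7% → 96.9% positive from NILM to HSIL),
and lactobacilli fraction, a clipped Gaussian falling with severity. The
loadings were chosen once to put the DF–covariate rank correlations near
+0.55/−0.55; the observed values on a default cohort are ≈ +0.58/−0.53.

`design_auc` gives the analytic ROC AUC of any pair feature under the
generator: within each group ΔCq is Gaussian with variance
σ_X² + σ_Y² − 2σ_Xσ_Y c_X c_Y (+ 2·replicate_sd²/r), and the AUC is the
exact Φ-mixture over group pairs. Empirical AUCs on a 20 000-sample cohort
match it within ±0.01 (tested).

What the generator does *not* emulate: the default effect sizes separate
the groups more cleanly than real smears (pair AUCs ≈ 0.99 vs ≈ 0.9
clinically), because real cohorts contain diluted atypical cells,
borderline lesions and molecular subtypes that no Gaussian group model
reproduces. Passing tests therefore demonstrate correctness of the
machinery and calibration of the statistics, not clinical performance.
A null configuration (identical group means) is provided for calibration
checks: single-feature AUCs center on 0.5, no pair survives Bonferroni,
and out-of-fold classifier AUCs average 0.5.

## Problem sizes and numerical choices

Tests run the study-size cohort (167 samples) throughout; calibration
checks use 20 000 samples for AUC convergence, 20 × n = 2000 for logistic
weight-ratio recovery (seed-averaged ratios within ±15% of the generating
model's), and 100 study-size null cohorts for the unbiasedness check —
all chosen to make sampling error comfortably smaller than the asserted
tolerances while keeping the suite under half a minute. Logistic fits use
lbfgs with up to 10⁴ iterations. Cq values are written with two decimals
and round-trip exactly at that precision.

## Known limitations

- Published whole-cohort metrics (AUC 0.935, sens 89.7%, spec 87.6%) are
  not reproducible without the study's raw 167-smear Cq data, which are
  not deposited; the reference-table worked example and the statistical
  identities are the reproducible surface.
- The recovered reference weights are an OLS reconstruction from printed,
  rounded DF values — accurate to ~0.001 in DF but not the original fit.
- Expression-negative and missing wells are conflated at the 40.00 cap.
- The generator draws diagnosis groups as Gaussian clusters; it cannot
  produce the discrepant-sample structure (FN/FP blocks) in realistic
  proportions unless effect sizes are reduced.
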