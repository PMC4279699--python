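# Methods

## Normalization model

Background-subtracted bead-array intensities are modelled as
multiplicative, so analysis happens on the log10 scale.  Because
background subtraction can produce values ≤ 0, intensities are floored at
a configurable `log_floor` (default 1.0, so floored cells sit at 0 on the
log scale) before the transform; the count of floored cells is logged.
Each sample is then standardized over **all probes in the matrix** (after
any cross-dataset probe intersection, never per contrast): Z-scores use
the sample mean and the n−1 standard deviation of that sample's log10
values.  This removes per-sample location and scale — labelling
efficiency, scanner gain, RNA input — and makes samples directly
comparable; the package asserts mean 0 and SD 1 per column to 1e-9.
Floored/undetected probes are included in the per-sample mean and SD; the
alternative (excluding them) would couple the normalization to the
detection rule, and with tens of thousands of probes the difference is
negligible.

## DAT statistics

*Z-ratio.*  The per-probe group mean-Z difference divided by a single
scalar, the n−1 SD of those differences across all probes.  It asks how
extreme a probe's shift is relative to the array-wide shift distribution;
±1.96 is treated as the 5% cut by analogy with the normal.  A fully null
contrast (identical group means for every probe) has an undefined ratio;
the implementation returns zeros in that case and raises only when the
differences are constant but non-zero.

*Z-test.*  A per-probe two-sample statistic with per-group n−1 variances
(Welch-style; the variance formula divides per-group spread by the
respective group size), referenced to the standard normal.  No
small-sample t correction is applied: the method is defined as a Z test,
and with the default 40 + 40 samples the difference is immaterial — but
with small groups the normal reference is anti-conservative, which the
test suite documents rather than hides.  Probes with zero variance in
both groups keep their row: z = 0, p = 1 when the means agree; p = 0 with
a logged warning when they differ.

*Multiple testing.*  Benjamini-Hochberg step-up (via statsmodels) over all
probes of a contrast; ties share the adjusted value through the
cumulative-minimum monotonicity rule.  The same adjustment is used for
the Z-test p-values and the GLM p-values.

*DAT filter.*  The conjunction |Z-ratio| ≥ 1.96 AND adjusted Z-test
p ≤ 0.05 AND detected in ≥ 1 sample of the union of the two groups.
Direction (more/less abundant) is assigned to DATs from the Z-ratio sign.

## Cell-count GLM

Per probe, ordinary least squares of the Z-score on an intercept, the
absolute lymphocyte, neutrophil and monocyte counts (untransformed,
cells/µL), and a 0/1 group indicator.  All probes share one design
matrix, so the fits are solved in a single vectorized pass; a
statsmodels-based per-probe fit serves as an independent cross-check in
the tests.  Inference on the group coefficient β₂ uses the large-sample
normal reference on β̂₂/SE, consistent with the Z-based framework, then BH
over probes.  Samples missing a covariate are dropped from this stage
only (logged); a covariate that is constant over the contrast samples is
reported by name as a rank-deficiency error.

A GLM DAT needs adjusted p < 0.05 **and** fold-difference > 1.5.  The
fold-difference is the ratio of group geometric mean intensities,
10^|Δ mean log10|, folded to ≥ 1 — computed from the raw (unadjusted)
log10 intensities, the standard microarray convention.  A
`model_fold=True` option instead back-transforms |β₂| through the mean
per-sample log-scale SD, giving a covariate-adjusted fold; it is off by
default because the raw convention is the common one and the two differ
exactly when composition matters.

Covariate-adjusted and unadjusted calls answer different questions:
the Z statistics measure abundance differences in whole blood as drawn;
the GLM estimates the group effect at fixed cell composition.  Probes
driven purely by composition pass the first and fail the second — the
discrimination the acceptance suite quantifies.

## Enrichment and pathway comparison

Over-representation of a DAT gene list inside a gene set is tested with
the one-sided Fisher exact test (upper hypergeometric tail) on the 2×2
table [k, K−k; n−k, N−K−n+k], where the universe N is **all genes mapped
on the array**, not the genome: enrichment is judged against what was
measured.  Sets are intersected with the universe first; emptied sets are
dropped and logged.  BH runs across the tested sets.  Odds ratios get a
Haldane 0.5 shift only when a table margin is zero.  Probe→gene
collapsing uses the any-probe rule (a gene is a DAT gene if any of its
probes is one), with unmapped DAT probes counted and logged.

Up- and down-regulated DAT lists are tested separately — enrichment
signals of opposite directions would otherwise dilute each other.

`compare_contrasts` classifies each gene set from its per-contrast
significance pattern (adjusted p ≤ α): significant in every contrast →
`all_conditions`; in the focal contrast and ≥ 1 contrast of one
comparison group but none of the other → `focal_plus_groupA`/`B`; only in
the focal contrast → `focal_specific`; anything else → `other`.  Each set
receives exactly one label, and the matrix of −log10 adjusted p values is
returned alongside for plotting.

## Synthetic data: what it emulates and what it does not

The generator draws bead-array-like studies at desk scale — defaults:
5,000 probes, 40 + 40 samples, probe baselines ~ Uniform(1.5, 3.5) log10
units, i.i.d. Normal(0, 0.25) residual noise, 2% detection dropout.  Two
probe classes carry signal: 5% truly differential probes shifted by
±0.25 log10 units in the acute-like group, and a disjoint 5% of
confounder-only probes whose log10 intensity rises by 0.33 per 1,000
neutrophils/µL.  Cell counts are group-specific truncated normals
(acute-like: neutrophils 5,240 ± 1,700, lymphocytes 2,950 ± 500,
monocytes 520 ± 220; convalescent-like: 4,000 ± 1,700, 3,000 ± 500,
500 ± 220).  Companion outputs: a 1:1 probe→gene map, a GMT collection in
which 20% of sets draw half their members from the differential genes,
and a truth table.

The cell-count separation and confounder slope were **calibrated
jointly**, by simulation, to place the generator in the regime the method
is about: confounder-only probes are called by the unadjusted Z statistics
in more than half of the cases, while the adjusted GLM keeps its
false-positive rate on them below 1% and still detects ≥ 80% of truly
differential probes.  These three properties pull against each other —
stronger count separation makes confounding more detectable but also
makes the group indicator more collinear with the covariates, inflating
the GLM's standard errors — so the defaults sit deliberately on the
balance point; materially larger separations or slopes sacrifice GLM
sensitivity, smaller ones leave the confounder invisible.  The neutrophil
count (rather than the total leukocyte count) drives the confounded
probes because that concentrates the separation in one covariate and
mirrors how neutrophil-programme transcripts behave in whole blood.

Known simplifications: no paired-subject correlation (acute and
convalescent samples are independent draws, though in real cohorts most
subjects contribute both), no bead-level or spatial noise, no
intensity-dependent variance, symmetric effect sizes, and gene sets
without overlap structure.  Passing tests therefore demonstrate the
statistical machinery under the stated generative model, not performance
on any real cohort.

## Numerical choices and degenerate inputs

- Sample SDs use the n−1 denominator throughout.
- Two-sided p-values from the exact normal survival function.
- BH validates p ∈ [0, 1] and never decreases a p-value.
- The Z-ratio denominator is a scalar per contrast; zero denominator with
  non-zero numerators is an error, with all-zero differences it returns 0.
- OLS uses the explicit (XᵀX)⁻¹ solve after a rank check; σ² uses n − p.
- Results tables round-trip through TSV at 12 significant digits.
- Every silent data modification — floored cells, dropped samples,
  dropped probes, dropped gene sets, unmapped DAT probes — is logged.

## Problem sizes

Unit tests run on 300–800-probe simulations; the acceptance suite and
`scripts/acceptance.py` use the full default conditions (5,000 probes,
40 + 40 samples) over 20 replicate seeds, which completes in well under a
minute on a laptop-class machine.  The acceptance tests evaluate the
fixed seed panel 0–19; the script derives its panel from `--seed`.
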