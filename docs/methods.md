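# Methods

## Setting

The package operates on participant-level tabular data: per-region tau-PET
mean (and optionally median) SUVRs, per-region volumes in mm³, a global
amyloid SUVR, cognitive diagnosis (CU / MCI / AD), and demographics. The
primary analysis set is amyloid stratified: controls are amyloid-negative
CU participants and cases amyloid-positive cognitively impaired (CI)
participants, with amyloid positivity defined as global SUVR ≥ 1.08
(threshold inclusive and configurable). Centiloids are the linear map
`CL = 159.08·SUVR − 151.65` for florbetaben-scale global SUVRs.

## Composite ROIs

A composite SUVR is the volume-weighted average
`Σ_r vol_r·suvr_r / Σ_r vol_r` over its member regions, computed with each
participant's own volumes (equal weighting is available). Per-participant
weighting is the natural reading of "volume-weighted average" for
FreeSurfer-derived tables, where volumes are scan-specific; cohort-level
weights would couple one participant's composite to everyone else's
anatomy. Built-ins: `temporal_composite` (entorhinal, fusiform, inferior
temporal, middle temporal, parahippocampal, amygdala, hippocampus) and
`mtl_composite` (entorhinal, parahippocampal, amygdala).

Data-driven region selection ranks regions by the Pearson correlation
between SUVR and numerically coded diagnosis. The default coding is ordinal
(CU=0, MCI=1, AD=2); a binary CU-vs-CI coding (making the statistic the
point-biserial correlation) and Spearman correlation are available, since
reasonable analysts differ here. Ties break alphabetically.

The mean/median QC computes, per region, the Pearson correlation between
mean and median SUVR across participants; regions with r < 0.96 are
flagged as possibly contaminated by off-target (meningeal/venous) signal,
which inflates means more than medians. Absent medians are an explicit
error, never a silent pass.

## ROC construction and the Youden optimum

Thresholds are the midpoints between consecutive distinct observed scores,
bracketed by ±∞ sentinels. Midpoints make the derived cut-point
independent of which side of a tie the data fall on, and guarantee the
cut-point never coincides with an observed value. During derivation a
score ≥ threshold predicts "case"; sensitivity is therefore non-increasing
and specificity non-decreasing along the grid, and the AUC — the trapezoid
area over (1 − specificity, sensitivity) — equals the pairwise concordance
P(case > control) + ½P(tie) exactly (property-tested against a brute-force
count at 1e-10).

The optimal cut-point maximises J = sens + spec − 1. Ties (to within
1e-12) break toward the *higher* threshold, favouring specificity — the
operating points this kind of analysis reports are specificity-heavy — and
finite thresholds are preferred over the sentinels. Accuracy at the cut is
`(sens·n_case + spec·n_control)/n`, an identity the evaluation layer
re-checks exactly.

A cut-point is *acceptable* when J ≥ 0.6 and sensitivity or specificity
≥ 0.5 (all thresholds inclusive).

## Bootstrap confidence interval

The CI on the cut-point comes from stratified resampling: cases and
controls are drawn with replacement separately, preserving class
composition, and the Youden-optimal cut-point is recomputed per replicate
(default 1000). The interval is the percentile interval — with no stated
preference among bootstrap variants, the percentile method is the least
assumption-laden default. Replicates whose resample collapses to fewer
than two distinct values are skipped and counted; an all-degenerate
bootstrap raises. Fixed seeds make the interval reproducible.

## Two-component Gaussian mixture

`fit_gmm2` fits a univariate two-component Gaussian mixture by EM
(k-means initialisation, 10 restarts keeping the best log-likelihood,
tolerance 1e-6, ≤ 500 iterations, variance floor 1e-6 — all configurable),
implemented on `sklearn.mixture.GaussianMixture`. Components are ordered
by mean and the posterior probability of the higher-mean component is the
per-participant tau-abnormality probability. Non-convergence is carried on
the result as a flag. The mixture is fitted on the pooled sample (cases
and controls together): fitting on pooled data is the only choice that
keeps the posterior a label-blind predictor, so the subsequent ROC on
posteriors is a fair comparison against the raw SUVR ROC. Variances are
unconstrained. Because the posterior is a monotone transform of SUVR when
component variances are equal, the posterior AUC matches the SUVR AUC in
that regime; no SUVR-scale cut-point is reported for this method — the
posterior scale does not invert uniquely onto SUVR when variances differ.

## 2SD+ reference limit

`mean + 2·SD` of the reference group (amyloid-negative CU), with the
sample SD using the n−1 denominator — the convention for reference-limit
estimation from a sample.

## Applying cut-points

Application uses strict ">" positivity: a participant is tau positive when
the ROI SUVR exceeds the cut-point. Derivation uses "≥" on midpoint
thresholds; since midpoints never equal observed data the two conventions
cannot disagree on a derived cut-point (an internal-consistency test
asserts exact agreement). For externally supplied cut-points that tie the
data, both conventions are exposed.

Subgroup evaluation applies the pooled-cohort cut-point within each level
of a grouping column (plus the pooled "all" row); per-class counts below 5
are flagged, not dropped — small subgroups are informative but fragile.
Refitting the ROC per subgroup is available through the same `roc` call on
a stratified sub-cohort.

The full-spectrum comparison drops the amyloid stratification and runs the
identical ROC machinery on the tau ROI and on continuous global amyloid
SUVR per contrast, reporting the winner by Youden index.

Descriptive tables use Kruskal-Wallis for continuous variables (with
optional Dunn rank-based post-hoc z-tests, tie-corrected, unadjusted by
default with a Bonferroni flag) and chi-square for categorical variables;
missing values are excluded per variable with counts reported. Dunn's test
is implemented in-package from the standard rank statistics.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real dataset:

* **Strata.** Cell counts over diagnosis × amyloid status × ethnoracial
  group. The default amyloid-stratified configuration has 675 participants
  (599 amyloid-negative CU, 48 amyloid-positive MCI, 28 amyloid-positive
  AD; 186 Hispanic / 209 non-Hispanic Black / 280 non-Hispanic White); the
  full-spectrum configuration adds 130 amyloid-positive CU, 72
  amyloid-negative MCI and 2 amyloid-negative dementia participants (879
  total), so that dementia is almost entirely amyloid positive while MCI
  is mixed.
* **Latent tau state.** One Bernoulli state (normal/abnormal) per
  participant, shared across regions — tau staging is spatially coherent,
  and a shared state keeps composite-level distributions two-component.
  Default prevalences: 0.05 in amyloid-negative CU, 0.70 in
  amyloid-positive MCI, 0.80 in amyloid-positive AD. The case prevalences
  are *latent* rates obtained by inverting typical observed tau-positivity
  (about two thirds of amyloid-positive MCI and three quarters of
  amyloid-positive dementia called positive at a medial-temporal cut-point
  near 1.26) through the mixture's classification error, so the generated
  cohorts reproduce operating characteristics of that magnitude.
* **SUVRs.** Given the state, a participant-level Gaussian draw from
  N(1.10, 0.07²) (normal) or N(1.50, 0.10²) (abnormal), plus independent
  per-region jitter (SD 0.03); medians add zero-mean noise (SD 0.02),
  keeping mean/median correlations above 0.96 by construction. With these
  defaults the analytic density crossing for the MTL composite sits near
  1.27 and the expected CU-vs-CI Youden near 0.67 — a calibration choice
  so the default cohort exercises the acceptability rule from the passing
  side; it is an assumption, not an estimate from any dataset.
* **Amyloid.** Global SUVR from truncated normals on the correct side of
  the 1.08 threshold per stratum (negative: N(0.98, 0.04²) below;
  positive: N(1.35, 0.20²) above), so drawn values always agree with the
  stratum label.
* **Volumes.** Log-normal around per-region typical values (strictly
  positive, right-skewed). Demographics follow stratum-specific normal or
  Bernoulli draws (age and sex by diagnosis, education by group) with no
  feedback into SUVRs.
* **Planted effects.** `region_shift_scale` multiplies the abnormal shift
  in named regions and `group_separation_scale` attenuates it within an
  ethnoracial group — validation dials for recovery tests (does a planted
  best region rank first? does an attenuated subgroup lose sensitivity at
  the pooled cut-point?). Both default to 1.

Fixing the seed fixes every output bit-for-bit (single `default_rng`
stream, deterministic stratum order).

**What passing tests do and do not show.** The generator contains no
covariate-dependent tau accumulation, no scanner or site effects, no
off-target signal geometry, no education/SES pathways, and subgroup
differences exist only if planted. Tests against it validate the
*estimators and pipeline plumbing* — not any claim about real cohorts, and
in particular not the real-data phenomenon of reduced sensitivity in
specific ethnoracial groups, which the planted-effect tests merely show
the pipeline can detect when present.

## Numerical and edge-case choices

* ROC requires at least one case and one control; the missing class is
  named in the error.
* All-tied scores give AUC 0.5 by the concordance convention.
* GMM fitting requires ≥ 10 distinct values; variance collapse is guarded
  by the floor; non-convergence is flagged, never silent.
* Correlation of a constant series is an explicit undefined-correlation
  error.
* Diagnosis labels outside CU/MCI/AD are rejected, not coerced — silent
  coercion would corrupt prevalence-dependent metrics downstream.
* Report rendering formats to two decimals, uses an em dash for absent
  values (e.g. the GMM method's SUVR cut-point), and is byte-stable.

## Problem sizes in the shipped checks

The test suite and acceptance script run at sizes chosen to make each
property measurable quickly: the analytic Youden check at 20 000 per
group, GMM recovery over 50 replicates of n = 2000, bootstrap behaviour at
100 vs 2000 per class with 1000 replicates, and everything else at the
default 675/879-participant cohorts. These are the package's standard
demonstration sizes; all are configurable.

## Limitations

* Tabular only: no image handling, no FreeSurfer stats parsing (a future
  adapter), no voxelwise statistics.
* Two-component mixtures only; no covariate-adjusted ROC; no partial AUC.
* The percentile bootstrap can undercover for heavily skewed cut-point
  distributions; BCa is not currently implemented.
* The 1.08 amyloid threshold and Centiloid line are tracer- and
  pipeline-specific constants; both are parameters, and results do not
  transfer across tracers without re-anchoring.
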