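# taucut

Deriving and evaluating diagnostic cut-points for tau-PET standardized
uptake value ratios (SUVRs) from participant-level cohort tables.

## The problem

Staging Alzheimer's disease within the Aβ/tau/neurodegeneration framework
needs a threshold on continuous tau-PET signal above which a scan counts as
tau positive. Such thresholds are estimated on a particular sample, and
their transportability — especially across ethnoracial groups with
different comorbidity and amyloid-positivity profiles — has to be checked,
not assumed. `taucut` implements that workflow as a tested, reusable
library for anyone working with tabular tau-PET exports (regional SUVRs +
volumes + diagnoses + a global amyloid SUVR): derive a cut-point, attach an
uncertainty interval, and measure how it performs in subgroups.

## What it computes

For a cohort of amyloid-negative cognitively unimpaired (CU) controls and
amyloid-positive cognitively impaired (CI = MCI ∪ AD) cases, with ROI
scores either single FreeSurfer-style regions or volume-weighted composites
(built-ins: a 7-region temporal composite and the medial temporal "MTL"
composite of entorhinal + parahippocampal + amygdala):

1. **AUROC / Youden** — the full ROC curve over midpoint thresholds; the
   optimal cut-point maximises the Youden index `J = sens + spec − 1`; a
   stratified bootstrap (cases and controls resampled separately, 1000
   replicates) gives a 95% percentile CI on the cut-point. A cut-point is
   *acceptable* when `J ≥ 0.6` and sensitivity or specificity `≥ 0.5`.
2. **GMM posterior AUROC** — a two-component Gaussian mixture fitted to the
   pooled SUVRs; each participant's posterior probability of the
   higher-mean (tau-abnormal) component is scored by the same ROC
   machinery. This method reports no SUVR-scale cut-point.
3. **2SD+ reference limit** — mean + 2 sample SDs of the amyloid-negative
   CU reference group.

Around these: amyloid positivity at global SUVR ≥ 1.08, Centiloid
conversion (`CL = 159.08·SUVR − 151.65`), region-vs-diagnosis correlation
ranking for data-driven composite selection, mean-vs-median SUVR QC for
off-target signal, subgroup evaluation of a pooled cut-point, tau-vs-amyloid
comparison across the full amyloid spectrum, and descriptive cohort tables
(Kruskal-Wallis / Dunn / chi-square).

Because real multi-site cohorts of this kind are access-restricted, the
package ships a synthetic cohort generator (`taucut.simulate`) that draws
cohorts with the assumed structure — a shared latent tau state per
participant, two-component regional SUVR distributions whose abnormal
prevalence rises with diagnostic severity, amyloid SUVRs on the correct
side of the 1.08 threshold — so every stage is testable end to end.

## Worked example

```python
import taucut as tc

cohort, _ = tc.generate(tc.default_habs_like_config(seed=42))
sub, labels = tc.select_contrast(cohort, "cu-vs-ci", amyloid_stratified=True)
scores = tc.roi_scores(sub, "mtl_composite")

analysis = tc.roc(scores, labels)
ci = tc.bootstrap_ci(scores, labels, n_replicates=1000, seed=42)
print(analysis.optimal_cutpoint, (ci.low, ci.high), analysis.auc, analysis.youden)
```

Running `python examples/02_derive_cutpoints.py` (which adds the GMM and
2SD+ methods) prints:

```
AUROC / Youden:
  cut-point 1.277 (95% CI 1.227-1.355)
  AUC 0.84  Youden 0.67  sens 0.71  spec 0.96
  acceptable (J >= 0.6, sens or spec >= 0.5): True

GMM posterior AUROC:
  component means 1.10 / 1.50, weights 0.89 / 0.11
  AUC 0.84  Youden 0.67  (no SUVR-scale cut-point)

2SD+ reference limit:
  cut-point 1.325  Youden 0.66  sens 0.70  spec 0.96
```

Reading: on this synthetic cohort the MTL composite separates CU from CI
with AUC 0.84; the Youden-optimal threshold 1.277 (SUVR units) classifies
71% of cases and 96% of controls correctly and passes the acceptability
rule. The GMM posterior is a monotone transform of the SUVR here, so its
AUC matches. The 2SD+ limit (1.325) is stricter — higher specificity at
the cost of sensitivity, the usual behaviour of reference limits.

The other scripts in `examples/` walk through cohort simulation, subgroup
transportability, the full amyloid spectrum comparison, and region
ranking/QC. A thin CLI mirrors the common paths:

```bash
taucut simulate --seed 5 --out cohort.csv
taucut derive   --cohort cohort.csv --method roc --contrast cu-vs-ci --out result.json
taucut evaluate --cohort cohort.csv --from-derivation result.json --by ethnoracial_group
taucut report   --results result.json --fmt markdown
```

## Cohort table format

One CSV row per participant with columns `participant_id`, `diagnosis`
(CU/MCI/AD), `ethnoracial_group` (Hispanic/NHB/NHW/other), `age`, `sex`,
`education`, `global_amyloid_suvr`, plus the region families
`suvr_mean__<region>`, `vol__<region>` and optionally
`suvr_median__<region>`. Arbitrary source column names can be mapped via
`read_cohort(path, schema={...})`; `merge_bilateral` collapses
`lh_`/`rh_` pairs by volume weighting.

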