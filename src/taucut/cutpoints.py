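"""Cut-point estimators for a continuous biomarker against a binary diagnosis.

Three estimators, matching standard biomarker-positivity practice:

1. **AUROC / Youden** (:func:`roc`, :func:`youden_optimal`): build the full
   ROC curve over midpoint thresholds and pick the threshold maximising the
   Youden index J = sensitivity + specificity - 1. A stratified bootstrap
   (:func:`bootstrap_ci`) attaches a percentile confidence interval to the
   cut-point.
2. **GMM posterior AUROC** (:func:`fit_gmm2`,
   :func:`roc_on_gmm_probabilities`): fit a two-component Gaussian mixture to
   the pooled SUVRs, take each participant's posterior probability of
   belonging to the higher-mean ("tau-abnormal") component, and run the same
   ROC machinery on those probabilities. No SUVR-scale cut-point is reported
   for this method.
3. **2SD+ reference limit** (:func:`two_sd_cutpoint`): mean + 2 sample
   standard deviations of a biomarker-negative, cognitively unimpaired
   reference group.

A cut-point is *acceptable* (:func:`acceptability`) when J >= 0.6 with
sensitivity or specificity >= 0.5.

Conventions (documented, configurable where noted):

* thresholds are midpoints between consecutive distinct scores plus -inf/+inf
  sentinels, so cut-points never coincide with observed data;
* a score >= threshold predicts "case" during derivation;
* Youden ties break toward the higher threshold (favouring specificity),
  preferring finite thresholds;
* the bootstrap CI is the percentile interval; the sample SD uses n-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .cohort import Cohort
from .composites import CompositeDefinition, roi_scores

__all__ = [
    "RocAnalysis",
    "GmmFit",
    "Acceptability",
    "BootstrapCI",
    "roc",
    "youden_optimal",
    "YoudenOptimum",
    "bootstrap_ci",
    "fit_gmm2",
    "roc_on_gmm_probabilities",
    "two_sd_cutpoint",
    "acceptability",
    "rank_rois_by_youden",
]


@dataclass
class RocAnalysis:
    """A full ROC curve plus the Youden-optimal operating point.

    ``thresholds`` ascend; ``sensitivity`` is non-increasing and
    ``specificity`` non-decreasing along them. ``scale`` records whether the
    scores were raw SUVRs or GMM posterior probabilities; for the latter no
    SUVR-scale cut-point exists and ``optimal_cutpoint`` lives on the
    probability scale.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutpoint: float
    youden: float
    sens_at_cut: float
    spec_at_cut: float
    accuracy_at_cut: float
    n_case: int
    n_control: int
    ci95: tuple[float, float] | None = None
    scale: str = "suvr"
    gmm: "GmmFit | None" = None


@dataclass(frozen=True)
class YoudenOptimum:
    cutpoint: float
    youden: float
    sens: float
    spec: float
    accuracy: float


@dataclass(frozen=True)
class Acceptability:
    """Result of the acceptability rule: J >= 0.6 and (sens or spec) >= 0.5."""

    acceptable: bool
    youden: float
    sens: float
    spec: float


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not labels.any():
        raise ValueError("no cases present (labels all False)")
    if labels.all():
        raise ValueError("no controls present (labels all True)")
    return scores, labels


def roc(scores, labels) -> RocAnalysis:
    """ROC analysis of continuous scores against binary case/control labels.

    Thresholds are the midpoints between consecutive distinct observed
    scores, bracketed by -inf/+inf sentinels; a score >= threshold predicts
    case. The AUC is the trapezoid area over (1 - specificity, sensitivity),
    which over midpoint thresholds equals the pairwise concordance
    P(case score > control score) + 0.5 * P(tie).
    """
    scores, labels = _check_scores_labels(scores, labels)
    cases = np.sort(scores[labels])
    controls = np.sort(scores[~labels])
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    n_case, n_control = len(cases), len(controls)
    # sens(t) = P(case >= t); spec(t) = P(control < t)
    sens = (n_case - np.searchsorted(cases, thresholds, side="left")) / n_case
    spec = np.searchsorted(controls, thresholds, side="left") / n_control
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    analysis = RocAnalysis(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutpoint=np.nan,
        youden=np.nan,
        sens_at_cut=np.nan,
        spec_at_cut=np.nan,
        accuracy_at_cut=np.nan,
        n_case=n_case,
        n_control=n_control,
    )
    opt = youden_optimal(analysis)
    analysis.optimal_cutpoint = opt.cutpoint
    analysis.youden = opt.youden
    analysis.sens_at_cut = opt.sens
    analysis.spec_at_cut = opt.spec
    analysis.accuracy_at_cut = opt.accuracy
    return analysis


def youden_optimal(analysis: RocAnalysis) -> YoudenOptimum:
    """The threshold maximising J = sens + spec - 1 along the ROC grid.

    Ties break toward the higher threshold (the more specific operating
    point); finite thresholds are preferred over the sentinels.
    """
    j = analysis.sensitivity + analysis.specificity - 1.0
    jmax = j.max()
    candidates = np.flatnonzero(j >= jmax - 1e-12)
    finite = candidates[np.isfinite(analysis.thresholds[candidates])]
    idx = int((finite if finite.size else candidates)[-1])
    sens = float(analysis.sensitivity[idx])
    spec = float(analysis.specificity[idx])
    n_case, n_control = analysis.n_case, analysis.n_control
    accuracy = (sens * n_case + spec * n_control) / (n_case + n_control)
    return YoudenOptimum(
        cutpoint=float(analysis.thresholds[idx]),
        youden=sens + spec - 1.0,
        sens=sens,
        spec=spec,
        accuracy=accuracy,
    )


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap interval for a cut-point.

    Unpacks as ``low, high = bootstrap_ci(...)``; the replicate cut-points
    and the number of degenerate replicates skipped are kept for inspection.
    """

    low: float
    high: float
    level: float
    n_replicates: int
    n_skipped: int
    replicates: np.ndarray = field(repr=False)

    def __iter__(self) -> Iterator[float]:
        return iter((self.low, self.high))

    @property
    def width(self) -> float:
        return self.high - self.low


def bootstrap_ci(
    scores,
    labels,
    n_replicates: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Stratified percentile bootstrap CI on the Youden-optimal cut-point.

    Cases and controls are resampled separately with replacement, so every
    replicate preserves the class composition; the Youden-optimal cut-point
    is recomputed per replicate and the CI is the percentile interval of the
    replicate cut-points. Replicates whose resample collapses to fewer than
    two distinct scores are skipped and counted.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if n_replicates < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    cases = scores[labels]
    controls = scores[~labels]
    cuts = []
    n_skipped = 0
    lab = np.concatenate([np.ones(len(cases), bool), np.zeros(len(controls), bool)])
    for _ in range(n_replicates):
        rc = cases[rng.integers(0, len(cases), len(cases))]
        rk = controls[rng.integers(0, len(controls), len(controls))]
        resampled = np.concatenate([rc, rk])
        if len(np.unique(resampled)) < 2:
            n_skipped += 1
            continue
        cuts.append(roc(resampled, lab).optimal_cutpoint)
    cuts = np.asarray(cuts)
    if cuts.size < 2:
        raise ValueError("all bootstrap replicates were degenerate")
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(cuts, [alpha, 1.0 - alpha])
    return BootstrapCI(
        low=float(low),
        high=float(high),
        level=level,
        n_replicates=n_replicates,
        n_skipped=n_skipped,
        replicates=cuts,
    )


@dataclass
class GmmFit:
    """Two-component univariate Gaussian mixture, components ordered by mean.

    ``posteriors`` holds each participant's posterior probability of the
    higher-mean (tau-abnormal) component.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    posteriors: np.ndarray
    converged: bool
    loglik: float


def fit_gmm2(
    suvrs,
    seed: int | None = None,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    var_floor: float = 1e-6,
) -> GmmFit:
    """Fit a two-component Gaussian mixture by EM with restarts.

    k-means initialisation plus ``n_init`` random restarts, keeping the best
    log-likelihood; a variance floor guards against component collapse.
    Components are relabelled so the first has the lower mean, and the
    returned posteriors refer to the higher-mean ("abnormal") component.
    Non-convergence is flagged on the result, never silent.
    """
    x = np.asarray(suvrs, dtype=float).reshape(-1, 1)
    if not np.all(np.isfinite(x)):
        raise ValueError("SUVRs must be finite")
    if len(np.unique(x)) < 10:
        raise ValueError("need at least 10 distinct values to fit a 2-component mixture")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        n_init=n_init,
        init_params="kmeans",
        reg_covar=var_floor,
        random_state=None if seed is None else int(seed),
    )
    gm.fit(x)
    means = gm.means_.ravel()
    order = np.argsort(means)
    weights = gm.weights_[order]
    means = means[order]
    sds = np.sqrt(gm.covariances_.reshape(-1)[order])
    post = gm.predict_proba(x)[:, order][:, 1]
    return GmmFit(
        weights=(float(weights[0]), float(weights[1])),
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        posteriors=post,
        converged=bool(gm.converged_),
        loglik=float(gm.score(x) * len(x)),
    )


def roc_on_gmm_probabilities(scores, labels, seed: int | None = None, **gmm_kwargs) -> RocAnalysis:
    """AUROC on posterior abnormality probabilities from a pooled GMM fit.

    The mixture is fitted to all scores pooled (cases and controls together),
    keeping the posterior a label-blind predictor; the ROC then runs on the
    posterior probabilities. The optimal cut-point lives on the probability
    scale — no SUVR-scale cut-point is reported for this method.
    """
    scores, labels = _check_scores_labels(scores, labels)
    fit = fit_gmm2(scores, seed=seed, **gmm_kwargs)
    analysis = roc(fit.posteriors, labels)
    analysis.scale = "probability"
    analysis.gmm = fit
    return analysis


def two_sd_cutpoint(reference_suvrs) -> float:
    """Reference-limit cut-point: mean + 2 sample SDs (n-1 denominator).

    ``reference_suvrs`` are the biomarker values of the reference group —
    amyloid-negative cognitively unimpaired participants in the primary
    analysis.
    """
    x = np.asarray(reference_suvrs, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 reference values")
    if not np.all(np.isfinite(x)):
        raise ValueError("reference SUVRs must be finite")
    return float(x.mean() + 2.0 * x.std(ddof=1))


def acceptability(youden: float, sens: float, spec: float) -> Acceptability:
    """Apply the acceptability rule (thresholds inclusive).

    A cut-point is acceptable when the Youden index is at least 0.6 and
    sensitivity or specificity is at least 0.5.
    """
    for name, v in (("youden", youden), ("sens", sens), ("spec", spec)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if not (-1.0 <= youden <= 1.0 and 0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("youden must lie in [-1, 1] and sens/spec in [0, 1]")
    ok = youden >= 0.6 and (sens >= 0.5 or spec >= 0.5)
    return Acceptability(acceptable=bool(ok), youden=float(youden), sens=float(sens), spec=float(spec))


def rank_rois_by_youden(
    cohort: Cohort,
    rois: Sequence[str | CompositeDefinition],
    labels,
    composites: Mapping[str, CompositeDefinition] | None = None,
) -> list[tuple[str, RocAnalysis]]:
    """Run the ROC analysis for every ROI and rank by Youden index.

    ROIs may be region names or composites. Descending Youden; ties break by
    higher AUC, then alphabetically. Returns (roi-name, RocAnalysis) pairs.
    """
    labels = np.asarray(labels, dtype=bool)
    results = []
    for roi in rois:
        name = roi.name if isinstance(roi, CompositeDefinition) else str(roi)
        analysis = roc(roi_scores(cohort, roi, composites=composites), labels)
        results.append((name, analysis))
    return sorted(results, key=lambda item: (-item[1].youden, -item[1].auc, item[0]))
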