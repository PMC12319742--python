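"""ROC/Youden, bootstrap CI, GMM posterior AUROC, 2SD+, acceptability."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

import taucut as tc


def pairwise_concordance(cases, controls):
    """Brute-force AUC oracle: P(case > control) + 0.5 P(tie)."""
    wins = ties = 0
    for c in cases:
        for k in controls:
            if c > k:
                wins += 1
            elif c == k:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def random_instance(rng, n_max=200):
    n_case = rng.integers(1, n_max // 2)
    n_control = rng.integers(1, n_max // 2)
    # integer-ish grid forces plenty of ties
    scores = np.round(rng.normal(1.2, 0.3, n_case + n_control), 2)
    labels = np.concatenate([np.ones(n_case, bool), np.zeros(n_control, bool)])
    return scores, labels


class TestRoc:
    def test_perfect_separation(self):
        r = tc.roc([3, 4, 1, 2], [True, True, False, False])
        assert r.auc == pytest.approx(1.0)
        assert r.optimal_cutpoint == pytest.approx(2.5)  # midpoint of the gap
        assert r.youden == pytest.approx(1.0)

    def test_all_ties_gives_half(self):
        r = tc.roc([1.0, 1.0, 1.0, 1.0], [True, True, False, False])
        assert r.auc == pytest.approx(0.5)

    def test_counting_oracle_with_tie(self):
        # cases {2,3}, controls {1,2}: 3 wins + 1 tie over 4 pairs
        r = tc.roc([2, 3, 1, 2], [True, True, False, False])
        assert r.auc == pytest.approx(0.875)

    def test_single_class_error_names_missing_class(self):
        with pytest.raises(ValueError, match="control"):
            tc.roc([1, 2], [True, True])
        with pytest.raises(ValueError, match="case"):
            tc.roc([1, 2], [False, False])

    def test_auc_equals_concordance_random_instances(self):
        """Trapezoid AUC == pairwise concordance on 40 random tied instances."""
        rng = np.random.default_rng(1234)
        for _ in range(40):
            scores, labels = random_instance(rng)
            r = tc.roc(scores, labels)
            oracle = pairwise_concordance(scores[labels], scores[~labels])
            assert r.auc == pytest.approx(oracle, abs=1e-10)
            # independent library cross-check
            assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    def test_monotone_sens_spec_along_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            scores, labels = random_instance(rng)
            r = tc.roc(scores, labels)
            assert (np.diff(r.sensitivity) <= 1e-12).all()
            assert (np.diff(r.specificity) >= -1e-12).all()
            assert r.youden == pytest.approx(r.sens_at_cut + r.spec_at_cut - 1.0)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            scores, labels = random_instance(rng)
            r = tc.roc(scores, labels)
            n_case, n_control = labels.sum(), (~labels).sum()
            expected = (r.sens_at_cut * n_case + r.spec_at_cut * n_control) / len(labels)
            assert r.accuracy_at_cut == pytest.approx(expected, abs=1e-12)

    def test_cutpoint_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(17)
        scores, labels = random_instance(rng)
        r1 = tc.roc(scores, labels)
        r2 = tc.roc(np.exp(scores), labels)
        assert r2.auc == pytest.approx(r1.auc, abs=1e-12)
        assert r2.youden == pytest.approx(r1.youden, abs=1e-12)
        # the transformed cut-point separates the same participants
        assert ((np.exp(scores) >= r2.optimal_cutpoint) == (scores >= r1.optimal_cutpoint)).all()

    def test_youden_tie_breaks_toward_higher_threshold(self):
        # cases {1, 3}, controls {0, 2}: J = 0.5 at thresholds 0.5, 1.5(?) ...
        r = tc.roc([1.0, 3.0, 0.0, 2.0], [True, True, False, False])
        j = r.sensitivity + r.specificity - 1.0
        ties = r.thresholds[np.isfinite(r.thresholds) & (j >= j.max() - 1e-12)]
        assert r.optimal_cutpoint == pytest.approx(ties.max())


class TestYoudenAnalytic:
    def test_equal_variance_gaussians_cut_at_mean_midpoint(self):
        """With equal variances the Youden optimum is the density crossing:
        the midpoint of the two means."""
        rng = np.random.default_rng(2024)
        controls = rng.normal(1.1, 0.08, 20_000)
        cases = rng.normal(1.5, 0.08, 20_000)
        scores = np.concatenate([cases, controls])
        labels = np.concatenate([np.ones(20_000, bool), np.zeros(20_000, bool)])
        r = tc.roc(scores, labels)
        assert r.optimal_cutpoint == pytest.approx(1.30, abs=0.02)


class TestBootstrapCI:
    def test_ci_contains_point_estimate_across_seeds(self):
        rng = np.random.default_rng(99)
        for seed in range(5):
            controls = rng.normal(1.1, 0.1, 80)
            cases = rng.normal(1.5, 0.15, 40)
            scores = np.concatenate([cases, controls])
            labels = np.concatenate([np.ones(40, bool), np.zeros(80, bool)])
            point = tc.roc(scores, labels).optimal_cutpoint
            ci = tc.bootstrap_ci(scores, labels, n_replicates=300, seed=seed)
            assert ci.low <= point <= ci.high

    def test_ci_narrower_than_class_gap_when_separated(self):
        rng = np.random.default_rng(3)
        controls = rng.normal(1.0, 0.05, 200)
        cases = rng.normal(2.0, 0.05, 200)
        scores = np.concatenate([cases, controls])
        labels = np.concatenate([np.ones(200, bool), np.zeros(200, bool)])
        ci = tc.bootstrap_ci(scores, labels, n_replicates=500, seed=0)
        gap = cases.min() - controls.max()
        assert ci.width < gap

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(1.2, 0.2, 100)
        labels = rng.random(100) < 0.4
        a = tc.bootstrap_ci(scores, labels, n_replicates=100, seed=7)
        b = tc.bootstrap_ci(scores, labels, n_replicates=100, seed=7)
        assert (a.low, a.high) == (b.low, b.high)

    def test_degenerate_replicates_skipped_and_counted(self):
        # cases are constant at 2; ~25% of control resamples collapse onto them
        scores = np.array([2.0, 2.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        ci = tc.bootstrap_ci(scores, labels, n_replicates=400, seed=0)
        assert ci.n_skipped > 0
        assert len(ci.replicates) == 400 - ci.n_skipped
        assert np.isfinite([ci.low, ci.high]).all()

    def test_all_degenerate_raises(self):
        scores = np.ones(6)
        labels = np.array([True, True, True, False, False, False])
        with pytest.raises(ValueError, match="degenerate"):
            tc.bootstrap_ci(scores, labels, n_replicates=50, seed=0)


class TestGmm:
    def test_parameter_recovery_balanced_mixture(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(1.1, 0.05, 2000), rng.normal(1.5, 0.05, 2000)])
        fit = tc.fit_gmm2(x, seed=0)
        assert fit.converged
        assert fit.means[0] == pytest.approx(1.1, abs=0.02)
        assert fit.means[1] == pytest.approx(1.5, abs=0.02)
        assert fit.weights[0] == pytest.approx(0.5, abs=0.05)
        assert abs(fit.weights[0] + fit.weights[1] - 1.0) < 1e-9

    def test_posterior_crosses_half_at_component_midpoint(self):
        """For an equal-weight, equal-variance fit the posterior's 50% crossing
        sits at the midpoint of the component means (symmetry)."""
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(1.1, 0.05, 2000), rng.normal(1.5, 0.05, 2000)])
        fit = tc.fit_gmm2(x, seed=0)
        order = np.argsort(x)
        crossing = float(np.interp(0.5, fit.posteriors[order], x[order]))
        assert crossing == pytest.approx(0.5 * (fit.means[0] + fit.means[1]), abs=0.01)

    def test_posterior_monotone_when_variances_equal(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(1.1, 0.06, 1500), rng.normal(1.5, 0.06, 1500)])
        fit = tc.fit_gmm2(x, seed=0)
        order = np.argsort(x)
        assert (np.diff(fit.posteriors[order]) >= -1e-3).all()

    def test_posteriors_bounded(self):
        rng = np.random.default_rng(14)
        x = rng.normal(1.2, 0.1, 500)
        fit = tc.fit_gmm2(x, seed=0)
        assert ((fit.posteriors >= 0) & (fit.posteriors <= 1)).all()

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            tc.fit_gmm2([1.0] * 50 + [2.0] * 50)


class TestGmmRoc:
    def test_auc_matches_suvr_auc_under_equal_variances(self, primary_contrast):
        """Posterior is a near-monotone transform of SUVR, so the AUCs agree."""
        _, labels, scores = primary_contrast
        suvr = tc.roc(scores, labels)
        prob = tc.roc_on_gmm_probabilities(scores, labels, seed=0)
        assert prob.scale == "probability"
        assert abs(prob.auc - suvr.auc) < 0.02

    def test_flagged_fit_propagates(self):
        rng = np.random.default_rng(15)
        x = rng.normal(1.2, 0.05, 200)  # one-cluster data
        labels = rng.random(200) < 0.5
        out = tc.roc_on_gmm_probabilities(x, labels, seed=0, max_iter=2, n_init=1)
        assert out.gmm is not None and out.gmm.converged is False


class TestTwoSd:
    def test_hand_values(self):
        assert tc.two_sd_cutpoint(np.array([1.0, 1.2])) == pytest.approx(
            1.1 + 2 * np.sqrt(0.02), abs=1e-12
        )
        assert tc.two_sd_cutpoint([1.3, 1.3, 1.3]) == pytest.approx(1.3)

    def test_mean_plus_two_sd(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            x = rng.normal(1.1, 0.1, rng.integers(2, 500))
            n = len(x)
            mean = sum(x) / n
            sd = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5
            assert tc.two_sd_cutpoint(x) == pytest.approx(mean + 2 * sd, abs=1e-12)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            tc.two_sd_cutpoint([1.0])


class TestAcceptability:
    @pytest.mark.parametrize(
        "youden, sens, spec, expected",
        [
            (0.62, 0.67, 0.95, True),   # typical passing operating point
            (0.45, 0.54, 0.91, False),  # Youden below 0.6
            (0.60, 0.50, 0.40, True),   # boundary: "at least" is inclusive
            (0.59, 0.99, 0.60, False),
            (0.70, 0.49, 0.49, False),  # neither rate reaches 0.5
        ],
    )
    def test_rule(self, youden, sens, spec, expected):
        out = tc.acceptability(youden, sens, spec)
        assert out.acceptable is expected

    def test_range_checks(self):
        with pytest.raises(ValueError):
            tc.acceptability(1.5, 0.5, 0.5)


class TestRankRois:
    def test_single_roi(self, primary_contrast):
        sub, labels, _ = primary_contrast
        out = tc.rank_rois_by_youden(sub, ["mtl_composite"], labels)
        assert len(out) == 1 and out[0][0] == "mtl_composite"

    def test_input_order_invariance(self, primary_contrast):
        sub, labels, _ = primary_contrast
        rois = ["mtl_composite", "hippocampus", "fusiform", "temporal_composite"]
        a = tc.rank_rois_by_youden(sub, rois, labels)
        b = tc.rank_rois_by_youden(sub, rois[::-1], labels)
        assert [name for name, _ in a] == [name for name, _ in b]
        youdens = [r.youden for _, r in a]
        assert youdens == sorted(youdens, reverse=True)
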