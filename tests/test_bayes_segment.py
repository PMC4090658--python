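"""Posterior computation, ROC sweep, threshold selection, coarse masks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dte
from dte import BinaryMask, ClassifierModel, GaussianClassModel
from dte.bayes_segment import PosteriorMap, ROCCurve
from dte.filterbank import CHANNEL_NAMES, FeatureStack


def _gauss(label, mean, cov=None, n=100):
    mean = np.asarray(mean, dtype=float)
    cov = np.eye(8) if cov is None else cov
    return GaussianClassModel(label=label, mean=mean, covariance=cov, n_samples=n)


def _stack(values):
    return FeatureStack(values=values, channel_names=CHANNEL_NAMES)


class TestPosterior:
    def test_equal_class_models_give_half_everywhere(self, rng):
        m = _gauss(1, rng.normal(size=8))
        model = ClassifierModel(
            foreground=m, background=_gauss(0, m.mean, m.covariance)
        )
        post = dte.posterior_map(_stack(rng.normal(size=(12, 12, 8))), model)
        assert np.allclose(post.values, 0.5, atol=1e-12)

    def test_extreme_separation_saturates_without_overflow(self):
        model = ClassifierModel(
            foreground=_gauss(1, np.full(8, 20.0)), background=_gauss(0, np.zeros(8))
        )
        post = dte.posterior_map(_stack(np.full((4, 4, 8), 20.0)), model)
        assert np.all(post.values >= 1 - 1e-9)
        assert np.all(np.isfinite(post.values))

    def test_equidistant_point_scores_half(self):
        model = ClassifierModel(
            foreground=_gauss(1, np.ones(8)), background=_gauss(0, -np.ones(8))
        )
        post = dte.posterior_map(_stack(np.zeros((2, 2, 8))), model)
        assert np.allclose(post.values, 0.5)

    def test_matches_brute_force_density_ratio(self, rng):
        from scipy.stats import multivariate_normal

        A = rng.normal(size=(8, 8))
        fg = _gauss(1, rng.normal(size=8), A @ A.T + np.eye(8))
        B = rng.normal(size=(8, 8))
        bg = _gauss(0, rng.normal(size=8), B @ B.T + np.eye(8))
        model = ClassifierModel(foreground=fg, background=bg)
        X = rng.normal(size=(16, 16, 8))
        post = dte.posterior_map(_stack(X), model)
        g1 = multivariate_normal(fg.mean, fg.covariance).pdf(X.reshape(-1, 8))
        g0 = multivariate_normal(bg.mean, bg.covariance).pdf(X.reshape(-1, 8))
        assert np.abs(post.values.ravel() - g1 / (g0 + g1)).max() <= 1e-9

    def test_complement_model_posterior_sums_to_one(self, rng):
        fg = _gauss(1, rng.normal(size=8))
        bg = _gauss(0, rng.normal(size=8))
        model = ClassifierModel(foreground=fg, background=bg)
        swapped = ClassifierModel(
            foreground=GaussianClassModel(1, bg.mean, bg.covariance, bg.n_samples),
            background=GaussianClassModel(0, fg.mean, fg.covariance, fg.n_samples),
        )
        X = rng.normal(size=(10, 10, 8))
        p1 = dte.posterior_map(_stack(X), model).values
        p0 = dte.posterior_map(_stack(X), swapped).values
        assert np.abs(p1 + p0 - 1.0).max() <= 1e-12

    def test_dimension_mismatch_rejected(self, rng):
        model = ClassifierModel(
            foreground=_gauss(1, np.zeros(8)), background=_gauss(0, np.zeros(8))
        )
        bad = FeatureStack(
            values=rng.normal(size=(8, 8, 3)), channel_names=("a", "b", "c")
        )
        with pytest.raises(ValueError, match="dimension"):
            dte.posterior_map(bad, model)


class TestConfusionCounts:
    def test_perfect_prediction_has_no_errors(self):
        truth = BinaryMask(labels=(np.indices((10, 10)).sum(0) % 2).astype(np.uint8))
        c = dte.confusion_counts(truth, truth)
        assert c.fp == 0 and c.fn == 0 and c.total == 100

    def test_all_ones_prediction(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[:3] = 1  # k = 30 of n = 100
        truth = BinaryMask(labels=labels)
        pred = BinaryMask(labels=np.ones((10, 10), dtype=np.uint8))
        c = dte.confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (30, 70, 0, 0)

    def test_two_by_two_enumeration(self):
        pred = BinaryMask(labels=np.array([[1, 0], [1, 0]], dtype=np.uint8))
        truth = BinaryMask(labels=np.array([[1, 1], [0, 0]], dtype=np.uint8))
        c = dte.confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_shape_mismatch_rejected(self):
        a = BinaryMask(labels=np.zeros((4, 4), dtype=np.uint8))
        b = BinaryMask(labels=np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="mismatch"):
            dte.confusion_counts(a, b)


def _truth(labels):
    return BinaryMask(labels=np.asarray(labels, dtype=np.uint8))


class TestROC:
    def test_perfect_separation_reaches_corner_f2(self):
        truth = np.zeros((20, 20), dtype=np.uint8)
        truth[:5] = 1
        post = PosteriorMap(values=truth.astype(float))
        roc = dte.roc_from_posteriors([post], [_truth(truth)])
        assert roc.f_score.max() == pytest.approx(2.0)
        i = np.argmax(roc.f_score)
        assert roc.fpr[i] == 0 and roc.tpr[i] == 1

    def test_constant_posterior_only_achieves_trivial_points(self):
        truth = np.zeros((20, 20), dtype=np.uint8)
        truth[:5] = 1
        post = PosteriorMap(values=np.full((20, 20), 0.5))
        roc = dte.roc_from_posteriors([post], [_truth(truth)])
        points = set(zip(roc.fpr.tolist(), roc.tpr.tolist()))
        assert points == {(0.0, 0.0), (1.0, 1.0)}

    def test_endpoints_always_present(self, rng):
        truth = (rng.uniform(size=(30, 30)) < 0.3).astype(np.uint8)
        post = PosteriorMap(values=rng.uniform(size=(30, 30)))
        roc = dte.roc_from_posteriors([post], [_truth(truth)])
        pts = set(zip(roc.fpr.tolist(), roc.tpr.tolist()))
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_rates_monotone_as_threshold_decreases(self, rng):
        truth = (rng.uniform(size=(40, 40)) < 0.2).astype(np.uint8)
        post = PosteriorMap(values=rng.uniform(size=(40, 40)))
        roc = dte.roc_from_posteriors([post], [_truth(truth)])
        assert np.all(np.diff(roc.thresholds) <= 0)
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_f_score_within_geometric_bounds(self, rng):
        truth = (rng.uniform(size=(40, 40)) < 0.2).astype(np.uint8)
        post = PosteriorMap(values=rng.uniform(size=(40, 40)))
        roc = dte.roc_from_posteriors([post], [_truth(truth)])
        assert np.all(roc.f_score >= 2 - np.sqrt(2) - 1e-12)
        assert np.all(roc.f_score <= 2 + 1e-12)

    def test_pooling_sums_counts_across_images(self):
        # one image all-correct, one all-wrong: pooled rates are the averages
        t1 = np.zeros((10, 10), dtype=np.uint8); t1[:5] = 1
        p1 = PosteriorMap(values=t1.astype(float))
        p2 = PosteriorMap(values=1.0 - t1.astype(float))
        roc = dte.roc_from_posteriors([p1, p2], [_truth(t1), _truth(t1)])
        assert roc.pooled
        i = np.argmin(np.abs(roc.thresholds - 1.0))
        # at threshold 1.0: tp pooled = 50 of 100 fg, fp pooled = 50 of 100 bg
        assert roc.tpr[i] == pytest.approx(0.5)
        assert roc.fpr[i] == pytest.approx(0.5)

    def test_degenerate_truth_rejected(self, rng):
        post = PosteriorMap(values=rng.uniform(size=(10, 10)))
        with pytest.raises(ValueError, match="degenerate"):
            dte.roc_from_posteriors([post], [_truth(np.ones((10, 10)))])

    def test_uniform_scores_approach_diagonal_optimum(self):
        # i.i.d. scores independent of truth: ROC is the diagonal, whose
        # minimal corner distance is sqrt(2)/2 at fpr = tpr = 1/2
        rng = np.random.default_rng(123)
        truth = (rng.uniform(size=(400, 500)) < 0.5).astype(np.uint8)
        post = PosteriorMap(values=rng.uniform(size=(400, 500)))
        roc = dte.roc_from_posteriors([post], [_truth(truth)])
        assert roc.f_score.max() == pytest.approx(2 - np.sqrt(2) / 2, abs=0.02)


class TestSelectThreshold:
    def test_matches_exhaustive_scan(self, rng):
        truth = (rng.uniform(size=(30, 30)) < 0.3).astype(np.uint8)
        post = PosteriorMap(values=rng.uniform(size=(30, 30)))
        roc = dte.roc_from_posteriors([post], [_truth(truth)])
        thr, f = dte.select_threshold(roc)
        best = max(
            zip(roc.f_score.tolist(), roc.thresholds.tolist()),
            key=lambda p: (p[0], p[1]),
        )
        assert f == best[0] and thr == best[1]

    def test_tie_breaks_toward_larger_threshold(self):
        roc = ROCCurve(
            thresholds=np.array([0.6, 0.4]),
            fpr=np.array([0.1, 0.2]),
            tpr=np.array([0.8, 0.9]),  # both at d_corner = sqrt(0.05)
        )
        thr, _ = dte.select_threshold(roc)
        assert thr == 0.6

    def test_empty_curve_rejected(self):
        roc = ROCCurve(thresholds=np.array([]), fpr=np.array([]), tpr=np.array([]))
        with pytest.raises(ValueError, match="empty"):
            dte.select_threshold(roc)


class TestCoarseSegment:
    def test_threshold_zero_labels_everything(self, rng):
        post = PosteriorMap(values=rng.uniform(size=(8, 8)))
        assert dte.coarse_segment(post, 0.0).n_foreground == 64

    def test_threshold_above_max_labels_nothing(self, rng):
        post = PosteriorMap(values=rng.uniform(0, 0.9, size=(8, 8)))
        assert dte.coarse_segment(post, 0.95).n_foreground == 0

    def test_enumerable_case(self):
        post = PosteriorMap(values=np.array([[0.2, 0.8]]))
        # shape guard: BinaryMask accepts 1x2
        mask = dte.coarse_segment(post, 0.5)
        assert mask.labels.tolist() == [[0, 1]]

    def test_threshold_out_of_range_rejected(self, rng):
        post = PosteriorMap(values=rng.uniform(size=(8, 8)))
        with pytest.raises(ValueError):
            dte.coarse_segment(post, 1.5)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 10_000))
def test_roc_invariants_hold_for_random_scores(seed):
    """d_corner/f identities and monotonicity for arbitrary score fields."""
    rng = np.random.default_rng(seed)
    truth = np.zeros((12, 12), dtype=np.uint8)
    truth.ravel()[rng.choice(144, size=rng.integers(1, 143), replace=False)] = 1
    post = PosteriorMap(values=rng.uniform(size=(12, 12)))
    roc = dte.roc_from_posteriors([post], [_truth(truth)])
    assert np.allclose(roc.d_corner, np.hypot(roc.fpr, 1 - roc.tpr))
    assert np.allclose(roc.f_score, 2 - roc.d_corner)
    assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
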