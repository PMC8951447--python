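"""Metrics: every formula checked against naive enumeration oracles,
plus closed-form and cross-implementation checks for the Fréchet
distance."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import linalg

from irisynth.evaluation import (
    FeatureStatistics,
    confusion,
    feature_statistics,
    fid,
    fw_iou,
    mean_iou,
    mean_pixel_accuracy,
    moment_embedder,
    pixel_accuracy,
    segmentation_report,
)


def brute_force_confusion(pred, true, k):
    cm = np.zeros((k, k), dtype=np.int64)
    for p, t in zip(pred.ravel(), true.ravel()):
        cm[t, p] += 1
    return cm


def brute_force_metrics(cm):
    """Direct triple-sum transcription of the metric formulas."""
    k = cm.shape[0]
    total = cm.sum()
    pa = sum(cm[i, i] for i in range(k)) / total
    recalls, ious, weights = [], [], []
    for i in range(k):
        gt = sum(cm[i, j] for j in range(k))
        if gt == 0:
            continue
        union = gt + sum(cm[j, i] for j in range(k)) - cm[i, i]
        recalls.append(cm[i, i] / gt)
        ious.append(cm[i, i] / union)
        weights.append(gt)
    fwiou = sum(w * v for w, v in zip(weights, ious)) / total
    return pa, np.mean(recalls), np.mean(ious), fwiou


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        labels = np.random.default_rng(0).integers(0, 3, (8, 8))
        cm = confusion(labels, labels, 3)
        assert np.array_equal(cm, np.diag(np.diag(cm)))
        assert cm.sum() == 64

    def test_small_example_counts(self):
        true = np.array([[0, 0], [1, 1]])
        pred = np.array([[0, 0], [1, 0]])
        cm = confusion(pred, true, 2)
        assert cm.sum() - np.trace(cm) == 1
        assert np.array_equal(cm, [[2, 0], [1, 1]])

    def test_matches_per_pixel_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = int(rng.integers(2, 5))
            true = rng.integers(0, k, (6, 7))
            pred = rng.integers(0, k, (6, 7))
            assert np.array_equal(confusion(pred, true, k), brute_force_confusion(pred, true, k))

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([3]), np.array([0]), 2)


class TestSegmentationMetrics:
    def test_perfect_prediction_all_ones(self):
        cm = np.diag([50, 14])
        assert pixel_accuracy(cm) == 1.0
        assert mean_pixel_accuracy(cm) == 1.0
        assert mean_iou(cm) == 1.0
        assert fw_iou(cm) == 1.0

    def test_pa_direct_arithmetic(self):
        assert pixel_accuracy(np.array([[3, 1], [0, 0]])) == 0.75

    def test_completely_wrong_binary_prediction_zero_miou(self):
        cm = np.array([[0, 5], [7, 0]])
        assert mean_iou(cm) == 0.0

    def test_single_class_ground_truth_collapses_fwiou_to_its_iou(self):
        cm = np.array([[8, 2], [0, 0]])
        # only class 0 present: weight 1, IoU = 8 / (10 + 8 - 8)
        assert fw_iou(cm) == pytest.approx(0.8)

    def test_empty_ground_truth_class_excluded_from_averages(self):
        cm = np.array([[6, 2], [0, 0]])
        assert mean_pixel_accuracy(cm) == pytest.approx(6 / 8)
        assert mean_iou(cm) == pytest.approx(6 / 8)

    def test_all_metrics_match_enumeration_oracle_on_random_maps(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            true = rng.integers(0, k, (8, 8))
            pred = rng.integers(0, k, (8, 8))
            cm = confusion(pred, true, k)
            pa, mpa, miou, fwiou = brute_force_metrics(cm)
            assert abs(pixel_accuracy(cm) - pa) <= 1e-10
            assert abs(mean_pixel_accuracy(cm) - mpa) <= 1e-10
            assert abs(mean_iou(cm) - miou) <= 1e-10
            assert abs(fw_iou(cm) - fwiou) <= 1e-10

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            pixel_accuracy(np.zeros((2, 2)))

    def test_report_bundles_all_four(self):
        labels = np.random.default_rng(3).integers(0, 2, (4, 8, 8))
        report = segmentation_report(labels, labels, 2)
        assert set(report) == {"PA", "mPA", "mIoU", "FWIoU"}
        assert all(v == 1.0 for v in report.values())


class TestFeatureStatistics:
    def test_identical_images_zero_covariance(self):
        img = np.random.default_rng(4).random((16, 16))
        stats = feature_statistics([img] * 5)
        assert np.allclose(stats.cov, 0.0)

    def test_two_scalar_embeddings_mean(self):
        stats = feature_statistics([np.zeros((4, 4)), np.ones((4, 4)) * 2],
                                   embedder=lambda im: np.array([im.mean()]))
        assert stats.mean[0] == pytest.approx(1.0)

    def test_gaussian_sample_recovers_moments(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(2.0, 3.0, size=4000)
        stats = feature_statistics(
            [np.full((2, 2), d) for d in draws], embedder=lambda im: np.array([im[0, 0]])
        )
        se_mean = 3.0 / np.sqrt(4000)
        assert abs(stats.mean[0] - 2.0) < 3 * se_mean
        assert abs(stats.cov[0, 0] - 9.0) < 3 * 9.0 * np.sqrt(2 / 3999)

    def test_fewer_than_two_images_rejected(self):
        with pytest.raises(ValueError):
            feature_statistics([np.zeros((4, 4))])

    def test_moment_embedder_deterministic_fixed_dim(self):
        img = np.random.default_rng(6).random((32, 32))
        a, b = moment_embedder(img), moment_embedder(img)
        assert np.array_equal(a, b)
        assert a.shape == (67,)


def _random_psd(rng, d):
    a = rng.standard_normal((d, d))
    return a @ a.T + 0.1 * np.eye(d)


class TestFid:
    def test_identical_statistics_zero(self):
        rng = np.random.default_rng(7)
        cov = _random_psd(rng, 4)
        stats = FeatureStatistics(rng.standard_normal(4), cov, 10)
        assert fid(stats, stats) == pytest.approx(0.0, abs=1e-8)

    def test_unit_gaussians_closed_form_m_squared(self):
        for m in (0.5, 1.0, 3.0):
            a = FeatureStatistics(np.array([0.0]), np.array([[1.0]]), 100)
            b = FeatureStatistics(np.array([m]), np.array([[1.0]]), 100)
            assert fid(a, b) == pytest.approx(m**2, rel=1e-10)

    def test_sampled_unit_gaussians_approach_m_squared(self):
        rng = np.random.default_rng(8)
        n, m = 10_000, 2.0
        xa = rng.normal(0.0, 1.0, n)
        xb = rng.normal(m, 1.0, n)
        ident = lambda im: np.array([im[0, 0]])
        sa = feature_statistics([np.full((1, 1), v) for v in xa], ident)
        sb = feature_statistics([np.full((1, 1), v) for v in xb], ident)
        # dominant error is the mean difference: sd of (mb - ma) is sqrt(2/n)
        assert fid(sa, sb) == pytest.approx(m**2, abs=6 * m * np.sqrt(2 / n) + 0.01)

    def test_matches_scipy_sqrtm_implementation(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            d = int(rng.integers(2, 6))
            mu_a, mu_b = rng.standard_normal(d), rng.standard_normal(d)
            ca, cb = _random_psd(rng, d), _random_psd(rng, d)
            covmean = linalg.sqrtm(ca @ cb)
            expected = float(
                np.sum((mu_a - mu_b) ** 2)
                + np.trace(ca) + np.trace(cb) - 2 * np.trace(covmean.real)
            )
            got = fid(FeatureStatistics(mu_a, ca, 10), FeatureStatistics(mu_b, cb, 10))
            assert got == pytest.approx(expected, rel=1e-6, abs=1e-8)

    def test_symmetric_when_covariances_commute(self):
        rng = np.random.default_rng(10)
        da, db = np.diag(rng.uniform(0.5, 2, 4)), np.diag(rng.uniform(0.5, 2, 4))
        mu_a, mu_b = rng.standard_normal(4), rng.standard_normal(4)
        ab = fid(FeatureStatistics(mu_a, da, 5), FeatureStatistics(mu_b, db, 5))
        ba = fid(FeatureStatistics(mu_b, db, 5), FeatureStatistics(mu_a, da, 5))
        assert ab == pytest.approx(ba, rel=1e-10)

    def test_dimension_mismatch_rejected(self):
        a = FeatureStatistics(np.zeros(3), np.eye(3), 5)
        b = FeatureStatistics(np.zeros(4), np.eye(4), 5)
        with pytest.raises(ValueError):
            fid(a, b)

    def test_nonnegative_after_clipping(self):
        # nearly identical statistics: round-off would go slightly negative
        rng = np.random.default_rng(11)
        cov = _random_psd(rng, 6)
        a = FeatureStatistics(np.zeros(6), cov, 5)
        b = FeatureStatistics(np.zeros(6) + 1e-12, cov + 1e-12, 5)
        assert fid(a, b) >= 0.0
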