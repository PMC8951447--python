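"""Quantitative evaluation.

Segmentation quality is scored from a k x k pixel confusion matrix
(entry (i, j) = pixels of true class i predicted as class j):

    PA    = sum_i p_ii / total
    mPA   = mean_i  p_ii / sum_j p_ij
    mIoU  = mean_i  p_ii / (sum_j p_ij + sum_j p_ji - p_ii)
    FWIoU = (1/total) sum_i (sum_j p_ij) * p_ii / (sum_j p_ij + sum_j p_ji - p_ii)

Classes with zero ground-truth pixels are excluded from the mPA / mIoU
class averages (their ratios are 0/0); FWIoU is unaffected since such
classes carry zero weight.

Image-set similarity is the Fréchet distance between Gaussian fits to
embedded image sets:

    FID = ||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^(1/2))

computed via an eigendecomposition of the symmetrized product
S_r^(1/2) S_g S_r^(1/2); small negative eigenvalues from round-off are
clipped to zero.  The embedder is pluggable: any callable mapping an
image to a d-vector works, and a deterministic pixel/moment embedder is
provided so desk-scale runs need no pretrained weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from scipy import linalg

# ---------------------------------------------------------------- metrics


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray, k: int) -> np.ndarray:
    """Exact k x k pixel counts; entry (i, j) = true i predicted j."""
    pred = np.asarray(pred_mask).ravel()
    true = np.asarray(true_mask).ravel()
    if pred.shape != true.shape:
        raise ValueError("mask shapes differ")
    for arr, name in ((pred, "pred"), (true, "true")):
        if arr.min() < 0 or arr.max() >= k:
            raise ValueError(f"{name} labels outside [0, {k})")
    idx = true.astype(np.int64) * k + pred.astype(np.int64)
    return np.bincount(idx, minlength=k * k).reshape(k, k)


def _check_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    if cm.sum() == 0:
        raise ValueError("confusion matrix is empty")
    return cm


def pixel_accuracy(cm: np.ndarray) -> float:
    """Fraction of correctly labeled pixels."""
    cm = _check_cm(cm)
    return float(np.trace(cm) / cm.sum())


def mean_pixel_accuracy(cm: np.ndarray) -> float:
    """Per-class recall averaged over classes present in the ground truth."""
    cm = _check_cm(cm)
    gt = cm.sum(axis=1)
    present = gt > 0
    return float(np.mean(np.diag(cm)[present] / gt[present]))


def mean_iou(cm: np.ndarray) -> float:
    """Intersection-over-union averaged over classes present in the ground truth."""
    cm = _check_cm(cm)
    gt = cm.sum(axis=1)
    union = gt + cm.sum(axis=0) - np.diag(cm)
    present = gt > 0
    return float(np.mean(np.diag(cm)[present] / union[present]))


def fw_iou(cm: np.ndarray) -> float:
    """Ground-truth-frequency-weighted IoU (robust to class imbalance)."""
    cm = _check_cm(cm)
    gt = cm.sum(axis=1)
    union = gt + cm.sum(axis=0) - np.diag(cm)
    present = gt > 0
    iou = np.diag(cm)[present] / union[present]
    return float((gt[present] * iou).sum() / cm.sum())


def segmentation_report(pred_masks: np.ndarray, true_masks: np.ndarray, k: int = 2) -> dict:
    """All four metrics over a stack of label maps (counts pooled)."""
    cm = confusion(pred_masks, true_masks, k)
    return {
        "PA": pixel_accuracy(cm),
        "mPA": mean_pixel_accuracy(cm),
        "mIoU": mean_iou(cm),
        "FWIoU": fw_iou(cm),
    }


# ------------------------------------------------------------------- FID


@dataclass(frozen=True)
class FeatureStatistics:
    """Gaussian summary (mean, covariance) of an embedded image set."""

    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self) -> None:
        mu, cov = np.asarray(self.mean), np.asarray(self.cov)
        if mu.ndim != 1 or cov.shape != (mu.size, mu.size):
            raise ValueError("mean must be (d,), covariance (d, d)")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


def moment_embedder(image: np.ndarray, grid: int = 8) -> np.ndarray:
    """Deterministic hand-rolled embedding: block-mean downsampled pixels
    plus global intensity moments.  No learned weights involved."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    gh, gw = h // grid, w // grid
    blocks = img[: gh * grid, : gw * grid].reshape(grid, gh, grid, gw).mean(axis=(1, 3))
    mu, sd = img.mean(), img.std()
    sk = 0.0 if sd == 0 else float(((img - mu) ** 3).mean() / sd**3)
    return np.concatenate([blocks.ravel(), [mu, sd, sk]])


def feature_statistics(
    images: Iterable[np.ndarray],
    embedder: Callable[[np.ndarray], np.ndarray] = moment_embedder,
) -> FeatureStatistics:
    """Sample mean and covariance of the embedded image set (>= 2 images)."""
    feats = np.asarray([np.asarray(embedder(im), dtype=np.float64) for im in images])
    if feats.ndim != 2 or len(feats) < 2:
        raise ValueError("need at least 2 images with 1-D embeddings")
    mu = feats.mean(axis=0)
    cov = np.cov(feats, rowvar=False)
    cov = np.atleast_2d(cov)
    return FeatureStatistics(mu, (cov + cov.T) / 2.0, len(feats))


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(stats_real: FeatureStatistics, stats_gen: FeatureStatistics) -> float:
    """Fréchet distance between two Gaussian feature summaries (>= 0)."""
    mu_r, mu_g = np.asarray(stats_real.mean), np.asarray(stats_gen.mean)
    if mu_r.shape != mu_g.shape:
        raise ValueError("embedding dimensions differ")
    s_r, s_g = np.asarray(stats_real.cov), np.asarray(stats_gen.cov)
    if (linalg.eigh((s_r + s_r.T) / 2, eigvals_only=True)[0] < -1e-6) or (
        linalg.eigh((s_g + s_g.T) / 2, eigvals_only=True)[0] < -1e-6
    ):
        raise ValueError("covariance is not positive semi-definite")
    sq_r = _psd_sqrt(s_r)
    # Tr((S_r S_g)^1/2) = Tr((S_r^1/2 S_g S_r^1/2)^1/2), symmetric PSD
    inner = sq_r @ s_g @ sq_r
    vals = np.clip(linalg.eigh((inner + inner.T) / 2.0, eigvals_only=True), 0.0, None)
    tr_sqrt = np.sqrt(vals).sum()
    value = float(np.sum((mu_r - mu_g) ** 2) + np.trace(s_r) + np.trace(s_g) - 2.0 * tr_sqrt)
    return max(value, 0.0)


def fid_between_image_sets(
    real: Iterable[np.ndarray],
    generated: Iterable[np.ndarray],
    embedder: Callable[[np.ndarray], np.ndarray] = moment_embedder,
) -> float:
    return fid(feature_statistics(real, embedder), feature_statistics(generated, embedder))
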