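"""Bayesian per-pixel posterior segmentation and ROC threshold optimization.

With class-conditional Gaussian models g1, g0 for tree and background and a
flat prior of 1/2, the per-pixel posterior reduces to g1 / (g0 + g1).  It is
evaluated in the log-density domain (one Cholesky factorization per class,
logistic of the log-likelihood ratio) so extreme densities cannot underflow.

A sensitivity threshold on the posterior is chosen by sweeping the ROC curve
of pooled confusion counts over the training images and minimizing the
distance to the ideal corner (FPR, TPR) = (0, 1),

    d_corner = sqrt(FPR^2 + (1 - TPR)^2),      F-score = 2 - d_corner,

so F-score lies in [2 - sqrt(2), 2] over realizable ROC points and equals 2
only for a perfect separator.  Confusion counts are computed exactly at every
distinct score value; the stored curve is thinned to ``n_thresholds``
quantile-spaced points (plus the sentinels and the exact optimum, which is
always retained).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .filterbank import FeatureStack
from .io_core import BinaryMask
from .noise_model import ClassifierModel, GaussianClassModel

DEFAULT_N_THRESHOLDS = 512


@dataclass
class PosteriorMap:
    """Per-pixel posterior probability of the tree class."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("posterior map must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite posterior values")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("posterior values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)


@dataclass
class ROCCurve:
    """Threshold-sweep curve of pooled (FPR, TPR) with corner scores.

    Points are ordered by strictly decreasing threshold, so FPR and TPR are
    non-decreasing along the arrays; the endpoints (0,0) (threshold above
    every score) and (1,1) (threshold 0) are always present.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    pooled: bool = False

    @property
    def d_corner(self) -> np.ndarray:
        return np.sqrt(self.fpr**2 + (1.0 - self.tpr) ** 2)

    @property
    def f_score(self) -> np.ndarray:
        return 2.0 - self.d_corner

    def __len__(self) -> int:
        return len(self.thresholds)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "fpr": self.fpr,
                "tpr": self.tpr,
                "d_corner": self.d_corner,
                "f_score": self.f_score,
            }
        )


def _log_gaussian_density(X: np.ndarray, model: GaussianClassModel) -> np.ndarray:
    """Log N(x; mu, Sigma) for each row of X, via a shared Cholesky factor."""
    d = model.dim
    factor = cho_factor(model.covariance, lower=True)
    logdet = 2.0 * np.log(np.diag(factor[0])).sum()
    centered = X - model.mean
    maha = np.einsum("ij,ij->i", centered, cho_solve(factor, centered.T).T)
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def posterior_map(features: FeatureStack, model: ClassifierModel) -> PosteriorMap:
    """Per-pixel posterior P(L=1 | X) under the two-Gaussian model."""
    if features.n_channels != model.foreground.dim:
        raise ValueError(
            f"feature dimension {features.n_channels} does not match "
            f"model dimension {model.foreground.dim}"
        )
    X = features.as_matrix()
    log_ratio = _log_gaussian_density(X, model.foreground) - _log_gaussian_density(
        X, model.background
    )
    log_prior_odds = np.log(model.prior_fg) - np.log(1.0 - model.prior_fg)
    post = expit(log_ratio + log_prior_odds)
    return PosteriorMap(values=post.reshape(features.shape))


def confusion_counts(prediction: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Pixelwise confusion-matrix counts of a prediction against ground truth."""
    if prediction.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: prediction {prediction.shape} vs truth {truth.shape}"
        )
    p = prediction.as_bool()
    t = truth.as_bool()
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _pool_scores(
    score_maps: list, truths: list[BinaryMask]
) -> tuple[np.ndarray, np.ndarray]:
    if len(score_maps) != len(truths):
        raise ValueError("score and truth lists differ in length")
    fg_parts, bg_parts = [], []
    for scores, truth in zip(score_maps, truths):
        vals = scores.values if isinstance(scores, PosteriorMap) else np.asarray(scores)
        if vals.shape != truth.shape:
            raise ValueError(
                f"shape mismatch: scores {vals.shape} vs truth {truth.shape}"
            )
        t = truth.as_bool()
        fg_parts.append(vals[t])
        bg_parts.append(vals[~t])
    fg = np.concatenate(fg_parts)
    bg = np.concatenate(bg_parts)
    if len(fg) == 0:
        raise ValueError("degenerate truth: no foreground pixels in the pool")
    if len(bg) == 0:
        raise ValueError("degenerate truth: no background pixels in the pool")
    return np.sort(fg), np.sort(bg)


def _counts_at(
    thresholds: np.ndarray, fg_sorted: np.ndarray, bg_sorted: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (fpr, tpr) for prediction ``score >= threshold`` (closed bound)."""
    n_fg, n_bg = len(fg_sorted), len(bg_sorted)
    tp = n_fg - np.searchsorted(fg_sorted, thresholds, side="left")
    fp = n_bg - np.searchsorted(bg_sorted, thresholds, side="left")
    return fp / n_bg, tp / n_fg


def roc_from_posteriors(
    posteriors: list,
    truths: list[BinaryMask],
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
) -> ROCCurve:
    """Build the pooled ROC curve of per-pixel scores against ground truth.

    Counts are summed over all images before computing rates.  Every distinct
    score value is evaluated as a candidate threshold; the returned curve
    keeps a quantile-spaced subset of ``n_thresholds`` points, the sentinels
    (threshold 0 and a value above every score), and the exact optimum.
    """
    fg_sorted, bg_sorted = _pool_scores(posteriors, truths)
    uniq = np.unique(np.concatenate([fg_sorted, bg_sorted]))
    fpr_all, tpr_all = _counts_at(uniq, fg_sorted, bg_sorted)
    f_all = 2.0 - np.sqrt(fpr_all**2 + (1.0 - tpr_all) ** 2)
    # exact optimum; ties broken toward the larger threshold
    best = len(f_all) - 1 - np.argmax(f_all[::-1])
    best_threshold = uniq[best]

    keep = uniq
    if len(uniq) > n_thresholds:
        idx = np.unique(np.linspace(0, len(uniq) - 1, n_thresholds).round().astype(int))
        keep = uniq[idx]
    sentinels = np.array([0.0, np.nextafter(uniq[-1], np.inf)])
    thresholds = np.unique(np.concatenate([keep, [best_threshold], sentinels]))[::-1]
    fpr, tpr = _counts_at(thresholds, fg_sorted, bg_sorted)
    return ROCCurve(
        thresholds=thresholds, fpr=fpr, tpr=tpr, pooled=len(posteriors) > 1
    )


def select_threshold(roc: ROCCurve) -> tuple[float, float]:
    """Pick the threshold with maximal F-score (minimal corner distance).

    Ties are broken toward the larger threshold, i.e. the sparser labeling.
    """
    if len(roc) == 0:
        raise ValueError("empty ROC curve")
    f = roc.f_score
    best = int(np.argmax(f))  # thresholds are sorted descending
    return float(roc.thresholds[best]), float(f[best])


def coarse_segment(posterior: PosteriorMap, threshold: float) -> BinaryMask:
    """Threshold the posterior map into the coarse binary segmentation."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return BinaryMask(
        labels=(posterior.values >= threshold).astype(np.uint8), role="coarse"
    )
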