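"""Performance measures, LOOCV, and the intensity-thresholding baseline.

Metrics follow the segmentation-evaluation conventions the extractor is
judged by:

* tree yield (%)      = 100 * TP / (TP + FN) -- the fraction of true tree
  pixels recovered;
* surface error (%)   = 100 * (FP + FN) / all pixels -- the fraction of the
  whole image mislabeled;
* F-score             = 2 - d_corner at the operating point (ROC-geometric
  score in [0, 2]; unrelated to the precision-recall F1).

Leave-one-out cross-validation trains the noise models and the sensitivity
threshold on N-1 images and evaluates on the held-out image, for every
image.  The comparison baseline thresholds raw normalized intensity, with
its threshold selected by the identical pooled-ROC corner-distance
machinery, and is left unrefined (plain thresholding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_segment import (
    ConfusionCounts,
    PosteriorMap,
    coarse_segment,
    confusion_counts,
    posterior_map,
    roc_from_posteriors,
    select_threshold,
)
from .config import RunConfig
from .filterbank import build_rfs_bank, features_for
from .io_core import BinaryMask, MIPImage, TrainingSet
from .noise_model import train
from .postprocess import refine


@dataclass
class SegmentationMetrics:
    """Yield / surface-error / corner-score bundle for one segmentation."""

    tree_yield_pct: float
    surface_error_pct: float
    f_score: float
    counts: ConfusionCounts


@dataclass
class LoocvReport:
    """Per-fold metrics and across-fold summary of a LOOCV run."""

    per_fold: pd.DataFrame
    summary: dict = field(default_factory=dict)


def compute_metrics(prediction: BinaryMask, truth: BinaryMask) -> SegmentationMetrics:
    """Tree yield, surface error and corner F-score of a binary prediction."""
    counts = confusion_counts(prediction, truth)
    if counts.tp + counts.fn == 0:
        raise ValueError("truth mask has no foreground pixels")
    if counts.fp + counts.tn == 0:
        raise ValueError("truth mask has no background pixels")
    d_corner = float(np.hypot(counts.fpr, 1.0 - counts.tpr))
    return SegmentationMetrics(
        tree_yield_pct=100.0 * counts.tpr,
        surface_error_pct=100.0 * (counts.fp + counts.fn) / counts.total,
        f_score=2.0 - d_corner,
        counts=counts,
    )


def _clamp01(threshold: float) -> float:
    return float(min(max(threshold, 0.0), 1.0))


def select_intensity_threshold(
    training: TrainingSet, n_thresholds: int = 512
) -> float:
    """ROC-optimal threshold on raw normalized intensity over a training set."""
    scores = [img.pixels for img, _ in training]
    truths = [mask for _, mask in training]
    pooled = np.concatenate([s.ravel() for s in scores])
    if np.ptp(pooled) == 0:
        raise ValueError("ROC degeneracy: constant intensity across training pool")
    roc = roc_from_posteriors(scores, truths, n_thresholds=n_thresholds)
    threshold, _ = select_threshold(roc)
    return _clamp01(threshold)


def intensity_baseline(
    image: MIPImage, training: TrainingSet, n_thresholds: int = 512
) -> BinaryMask:
    """Traditional intensity-based segmentation, protocol-matched to DTE.

    Raw normalized intensity plays the role of the posterior: the pooled
    training ROC is swept, the corner-distance-optimal threshold selected,
    and the test image thresholded.  No morphological refinement is applied.
    """
    threshold = select_intensity_threshold(training, n_thresholds=n_thresholds)
    return BinaryMask(
        labels=(image.pixels >= threshold).astype(np.uint8), role="coarse"
    )


def run_loocv(
    dataset: TrainingSet,
    config: RunConfig | None = None,
    refine_output: bool = True,
) -> LoocvReport:
    """Leave-one-out cross-validation of the extractor against the baseline.

    For each fold the noise models and sensitivity threshold come from the
    N-1 training images (pooled counts); the held-out image is segmented,
    refined, and scored against its truth.  Besides the operating-point
    F-score, each fold also reports the best corner F-score of the test
    image's own ROC (the upper bound a per-image threshold could reach).
    MR8 feature stacks are computed once per image and shared across folds.
    """
    if len(dataset) < 2:
        raise ValueError("LOOCV needs at least 2 image/mask pairs")
    cfg = config or RunConfig()
    bank = build_rfs_bank(**cfg.filter.bank_kwargs())
    feats = [
        features_for(img, bank, weber=cfg.filter.weber_normalize)
        for img, _ in dataset
    ]

    rows = []
    for i in range(len(dataset)):
        fold_train = dataset.drop(i)
        fold_feats = [f for j, f in enumerate(feats) if j != i]
        model = train(
            fold_train,
            fraction=cfg.sampling.fraction,
            seed=cfg.sampling.seed,
            ridge=cfg.model.ridge,
            bank=bank,
            features=fold_feats,
        )
        train_posts = [posterior_map(f, model) for f in fold_feats]
        train_truths = [m for j, (_, m) in enumerate(dataset) if j != i]
        roc = roc_from_posteriors(
            train_posts, train_truths, n_thresholds=cfg.roc.n_thresholds
        )
        thr_dte, _ = select_threshold(roc)
        thr_dte = _clamp01(thr_dte)

        test_img, test_truth = dataset[i]
        post = posterior_map(feats[i], model)
        pred = coarse_segment(post, thr_dte)
        if refine_output:
            pred = refine(
                pred,
                open_radius=cfg.post.open_radius,
                close_radius=cfg.post.close_radius,
                accumulator_peak_fraction=cfg.hough.peak_fraction,
                min_length=cfg.hough.min_length,
                max_gap=cfg.hough.max_gap,
                stroke_width=cfg.hough.stroke_width,
                seed=cfg.sampling.seed,
            )
        dte = compute_metrics(pred, test_truth)
        test_roc = roc_from_posteriors([post], [test_truth], cfg.roc.n_thresholds)
        _, dte_f_best = select_threshold(test_roc)

        thr_base = select_intensity_threshold(fold_train, cfg.roc.n_thresholds)
        base_mask = BinaryMask(
            labels=(test_img.pixels >= thr_base).astype(np.uint8), role="coarse"
        )
        base = compute_metrics(base_mask, test_truth)
        base_test_roc = roc_from_posteriors(
            [test_img.pixels], [test_truth], cfg.roc.n_thresholds
        )
        _, base_f_best = select_threshold(base_test_roc)

        rows.append(
            {
                "fold": i,
                "test_image": test_img.source_id,
                "dte_threshold": thr_dte,
                "baseline_threshold": thr_base,
                "dte_yield_pct": dte.tree_yield_pct,
                "dte_error_pct": dte.surface_error_pct,
                "dte_f_operating": dte.f_score,
                "dte_f_best_test": dte_f_best,
                "baseline_yield_pct": base.tree_yield_pct,
                "baseline_error_pct": base.surface_error_pct,
                "baseline_f_operating": base.f_score,
                "baseline_f_best_test": base_f_best,
            }
        )

    per_fold = pd.DataFrame(rows)
    metric_cols = [c for c in per_fold.columns if c not in ("fold", "test_image")]
    summary = {
        col: {
            "mean": float(per_fold[col].mean()),
            "sd": float(per_fold[col].std(ddof=1)),
        }
        for col in metric_cols
    }
    return LoocvReport(per_fold=per_fold, summary=summary)
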