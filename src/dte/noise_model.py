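"""Class-conditional Gaussian noise models of MR8 features.

The pixel classifier assumes the feature vector X at a pixel with label L is
drawn from N(mu_1, Sigma_1) on the tree (L = 1) and N(mu_0, Sigma_0) on the
background (L = 0).  Parameters are the per-class maximum-likelihood
estimates (covariance normalized by n, not n-1) computed from feature vectors
at pixel locations sampled uniformly without replacement from each class of
the ground-truth masks -- by default 30% of each class per image, pooled
over the training set.  The class prior is fixed at 1/2.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .filterbank import FilterBank, build_rfs_bank, features_for
from .io_core import BinaryMask, TrainingSet

DEFAULT_FRACTION = 0.3
MIN_SAMPLES = 9  # must exceed the 8-D feature dimension
_RIDGE_REL = 1e-6  # default ridge: 1e-6 * trace(Sigma) / dim

MODEL_FORMAT_VERSION = 1


@dataclass
class GaussianClassModel:
    """MLE Gaussian model of one class's feature distribution."""

    label: int
    mean: np.ndarray  # (d,)
    covariance: np.ndarray  # (d, d), includes the ridge
    n_samples: int
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        d = self.mean.shape[0]
        if self.covariance.shape != (d, d):
            raise ValueError("covariance shape does not match mean dimension")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance not symmetric")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("covariance (with ridge) not positive definite")
        if self.n_samples < MIN_SAMPLES:
            raise ValueError(
                f"need >= {MIN_SAMPLES} samples, got {self.n_samples}"
            )

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass
class ClassifierModel:
    """Both class models plus the prior and the trained sensitivity threshold."""

    foreground: GaussianClassModel
    background: GaussianClassModel
    prior_fg: float = 0.5
    threshold: float | None = None
    filter_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.prior_fg < 1:
            raise ValueError("prior must lie in (0, 1)")
        if self.threshold is not None and not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        if self.foreground.label != 1 or self.background.label != 0:
            raise ValueError("class model labels must be (fg=1, bg=0)")

    def build_bank(self) -> FilterBank:
        """Rebuild the filter bank this model was trained with."""
        cfg = self.filter_config
        if not cfg:
            return build_rfs_bank()
        return build_rfs_bank(
            support=cfg["support"],
            scales=tuple(tuple(s) for s in cfg["scales"]),
            isotropic_sigma=cfg["isotropic_sigma"],
        )


def per_image_seed(master_seed: int, source_id: str) -> int:
    """Stable per-image sampling seed: mixes the master seed with the image id.

    Tied to the image identity, not its position, so permuting the training
    pairs leaves every image's sample unchanged.
    """
    return (int(master_seed) ^ zlib.crc32(source_id.encode())) % (2**31)


def sample_pixels(
    mask: BinaryMask, fraction: float = DEFAULT_FRACTION, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample class-stratified pixel locations uniformly without replacement.

    Returns ``(fg_locations, bg_locations)`` as integer arrays of shape
    (n, 2) in (row, col) order, with ``floor(fraction * class size)`` entries
    per class (at least one).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    fg = np.argwhere(mask.labels == 1)
    bg = np.argwhere(mask.labels == 0)
    if len(fg) == 0:
        raise ValueError("mask has no foreground pixels to sample")
    if len(bg) == 0:
        raise ValueError("mask has no background pixels to sample")
    rng = np.random.default_rng(seed)
    out = []
    for locs in (fg, bg):
        k = max(1, int(np.floor(fraction * len(locs))))
        idx = rng.choice(len(locs), size=k, replace=False)
        out.append(locs[idx])
    return out[0], out[1]


def fit_gaussian_mle(
    samples: np.ndarray, label: int, ridge: float | None = None
) -> GaussianClassModel:
    """Fit one class model by maximum likelihood.

    ``ridge=None`` applies the default relative ridge
    ``1e-6 * trace(Sigma)/d`` to the diagonal for invertibility; pass an
    explicit value (possibly 0) to override.
    """
    X = np.asarray(samples, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("samples must be a 2-D (n, d) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in samples")
    n, d = X.shape
    if n < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {n}")
    mean = X.mean(axis=0)
    centered = X - mean
    cov = centered.T @ centered / n  # MLE normalizer (1/n)
    if ridge is None:
        ridge = _RIDGE_REL * max(np.trace(cov) / d, np.finfo(float).tiny)
    cov = cov + ridge * np.eye(d)
    return GaussianClassModel(
        label=label, mean=mean, covariance=cov, n_samples=n, ridge=float(ridge)
    )


def train(
    training: TrainingSet,
    fraction: float = DEFAULT_FRACTION,
    seed: int = 0,
    ridge: float | None = None,
    bank: FilterBank | None = None,
    features: list | None = None,
) -> ClassifierModel:
    """Fit both class models from a training set of (image, mask) pairs.

    MR8 features are computed per image (or taken from ``features``, a list
    of precomputed :class:`~dte.filterbank.FeatureStack` matching the pairs,
    which LOOCV uses to avoid refiltering), sampled at class-stratified
    random locations, pooled across images per class, and fit by
    :func:`fit_gaussian_mle`.  The prior is 1/2 and the sensitivity
    threshold is left unset; ROC optimization fills it in later.
    """
    if len(training) < 1:
        raise ValueError("training set is empty")
    if bank is None:
        bank = build_rfs_bank()
    fg_chunks, bg_chunks = [], []
    for i, (image, mask) in enumerate(training):
        stack = features[i] if features is not None else features_for(image, bank)
        fg_loc, bg_loc = sample_pixels(
            mask, fraction=fraction, seed=per_image_seed(seed, image.source_id)
        )
        fg_chunks.append(stack.values[fg_loc[:, 0], fg_loc[:, 1]])
        bg_chunks.append(stack.values[bg_loc[:, 0], bg_loc[:, 1]])
    fg_model = fit_gaussian_mle(np.concatenate(fg_chunks), label=1, ridge=ridge)
    bg_model = fit_gaussian_mle(np.concatenate(bg_chunks), label=0, ridge=ridge)
    return ClassifierModel(
        foreground=fg_model,
        background=bg_model,
        prior_fg=0.5,
        threshold=None,
        filter_config=bank.config_dict(),
    )


def _class_to_dict(m: GaussianClassModel) -> dict:
    return {
        "label": int(m.label),
        "n_samples": int(m.n_samples),
        "ridge": float(m.ridge),
        "mean": [float(v) for v in m.mean],
        "covariance": [float(v) for v in m.covariance.ravel()],  # row-major
    }


def _class_from_dict(d: dict) -> GaussianClassModel:
    for key in ("label", "n_samples", "ridge", "mean", "covariance"):
        if key not in d:
            raise ValueError(f"model file class block missing key {key!r}")
    mean = np.asarray(d["mean"], dtype=np.float64)
    dim = mean.shape[0]
    return GaussianClassModel(
        label=int(d["label"]),
        mean=mean,
        covariance=np.asarray(d["covariance"], dtype=np.float64).reshape(dim, dim),
        n_samples=int(d["n_samples"]),
        ridge=float(d["ridge"]),
    )


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Serialize a trained model to a flat YAML key-value file."""
    doc = {
        "version": MODEL_FORMAT_VERSION,
        "prior_fg": float(model.prior_fg),
        "threshold": None if model.threshold is None else float(model.threshold),
        "filter_config": model.filter_config,
        "foreground": _class_to_dict(model.foreground),
        "background": _class_to_dict(model.background),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_model(path: str | Path) -> ClassifierModel:
    """Load a model file written by :func:`save_model` (or by hand)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"malformed model file {path}")
    missing = [
        k
        for k in ("prior_fg", "threshold", "filter_config", "foreground", "background")
        if k not in doc
    ]
    if missing:
        raise ValueError(f"model file {path} missing keys: {missing}")
    return ClassifierModel(
        foreground=_class_from_dict(doc["foreground"]),
        background=_class_from_dict(doc["background"]),
        prior_fg=float(doc["prior_fg"]),
        threshold=None if doc["threshold"] is None else float(doc["threshold"]),
        filter_config=doc["filter_config"] or {},
    )
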