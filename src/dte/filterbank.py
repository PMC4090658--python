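"""Root Filter Set (RFS) construction and MR8 feature extraction.

The RFS is a bank of 38 texture kernels: oriented first-derivative-of-Gaussian
("edge") and second-derivative-of-Gaussian ("bar") filters at 3 scales and 6
orientations (36 kernels), plus an isotropic Gaussian and a
Laplacian-of-Gaussian.  The MR8 (Maximum Response 8) feature collapses each
(type, scale) sextet of orientations to the per-pixel maximum of the absolute
responses, yielding an 8-dimensional rotation-invariant descriptor per pixel:
6 anisotropic channels plus the 2 signed isotropic responses.

Filter parameters default to the classic Leung-Malik settings: 49x49 support,
anisotropic (sigma_long, sigma_short) in {(3,1), (6,2), (12,4)}, orientations
at 0..150 degrees in 30-degree steps, isotropic sigma 10.  Oriented kernels
are mean-subtracted and L1-normalized; the Gaussian is L1-normalized to sum 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .io_core import MIPImage

DEFAULT_SUPPORT = 49
DEFAULT_SCALES = ((3.0, 1.0), (6.0, 2.0), (12.0, 4.0))
DEFAULT_ISOTROPIC_SIGMA = 10.0
N_ORIENTATIONS = 6

CHANNEL_NAMES = (
    "edge-s1",
    "edge-s2",
    "edge-s3",
    "bar-s1",
    "bar-s2",
    "bar-s3",
    "gaussian",
    "log",
)


@dataclass
class FilterBank:
    """The 38-kernel RFS bank with its grouping into 8 MR8 channels.

    ``groups`` maps each of the 8 output channels to the kernel indices it
    pools: six anisotropic groups of 6 orientations each, then the two
    singleton isotropic groups (Gaussian, LoG).
    """

    kernels: np.ndarray  # (38, support, support)
    groups: list[list[int]]
    support: int
    scales: tuple[tuple[float, float], ...] = DEFAULT_SCALES
    isotropic_sigma: float = DEFAULT_ISOTROPIC_SIGMA
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    @property
    def n_kernels(self) -> int:
        return len(self.kernels)

    @property
    def n_channels(self) -> int:
        return len(self.groups)

    def config_dict(self) -> dict:
        """Parameters needed to rebuild this bank (stored in model files)."""
        return {
            "support": int(self.support),
            "scales": [[float(a), float(b)] for a, b in self.scales],
            "isotropic_sigma": float(self.isotropic_sigma),
        }


@dataclass
class FeatureStack:
    """Per-pixel 8-D MR8 response vectors for one image."""

    values: np.ndarray  # (rows, cols, 8)
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[-1] != len(self.channel_names):
            raise ValueError(f"bad feature stack shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature responses")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.values.shape[-1]

    def as_matrix(self) -> np.ndarray:
        """Flatten to (n_pixels, 8), row-major pixel order."""
        return self.values.reshape(-1, self.values.shape[-1])


def _l1_normalize(kernel: np.ndarray, zero_mean: bool = True) -> np.ndarray:
    if zero_mean:
        kernel = kernel - kernel.mean()
    return kernel / np.abs(kernel).sum()


def _oriented_kernel(
    sigma_long: float, sigma_short: float, theta: float, order: int, support: int
) -> np.ndarray:
    """Gaussian-derivative kernel with its long axis along angle ``theta``.

    The envelope has ``sigma_long`` along the bar direction and the
    ``order``-th derivative of a Gaussian of ``sigma_short`` across it
    (order 1 = edge, order 2 = bar).
    """
    half = support // 2
    rows, cols = np.mgrid[-half : half + 1, -half : half + 1]
    x, y = cols.astype(np.float64), rows.astype(np.float64)
    c, s = np.cos(theta), np.sin(theta)
    u = c * x + s * y  # along the bar
    v = -s * x + c * y  # across the bar
    g_long = np.exp(-(u**2) / (2 * sigma_long**2))
    g_short = np.exp(-(v**2) / (2 * sigma_short**2))
    if order == 1:
        deriv = -v / sigma_short**2
    elif order == 2:
        deriv = (v**2 - sigma_short**2) / sigma_short**4
    else:
        raise ValueError(f"unsupported derivative order {order}")
    return _l1_normalize(g_long * deriv * g_short)


def _gaussian_kernel(sigma: float, support: int) -> np.ndarray:
    half = support // 2
    rows, cols = np.mgrid[-half : half + 1, -half : half + 1]
    g = np.exp(-(rows**2 + cols**2) / (2 * sigma**2))
    return g / g.sum()


def _log_kernel(sigma: float, support: int) -> np.ndarray:
    half = support // 2
    rows, cols = np.mgrid[-half : half + 1, -half : half + 1]
    r2 = (rows**2 + cols**2).astype(np.float64)
    log = (r2 - 2 * sigma**2) / sigma**4 * np.exp(-r2 / (2 * sigma**2))
    return _l1_normalize(log)


def build_rfs_bank(
    support: int = DEFAULT_SUPPORT,
    scales: tuple[tuple[float, float], ...] = DEFAULT_SCALES,
    isotropic_sigma: float = DEFAULT_ISOTROPIC_SIGMA,
) -> FilterBank:
    """Build the 38-kernel RFS bank grouped into the 8 MR8 channels."""
    if support % 2 == 0:
        raise ValueError(f"kernel support must be odd, got {support}")
    if any(s <= 0 for pair in scales for s in pair) or isotropic_sigma <= 0:
        raise ValueError("filter sigmas must be positive")
    if len(scales) != 3:
        raise ValueError(f"expected 3 anisotropic scales, got {len(scales)}")

    thetas = [k * np.pi / N_ORIENTATIONS for k in range(N_ORIENTATIONS)]
    kernels: list[np.ndarray] = []
    groups: list[list[int]] = []
    for order in (1, 2):  # edge then bar
        for sigma_long, sigma_short in scales:
            group = []
            for theta in thetas:
                group.append(len(kernels))
                kernels.append(
                    _oriented_kernel(sigma_long, sigma_short, theta, order, support)
                )
            groups.append(group)
    groups.append([len(kernels)])
    kernels.append(_gaussian_kernel(isotropic_sigma, support))
    groups.append([len(kernels)])
    kernels.append(_log_kernel(isotropic_sigma, support))

    return FilterBank(
        kernels=np.stack(kernels),
        groups=groups,
        support=support,
        scales=tuple(tuple(p) for p in scales),
        isotropic_sigma=isotropic_sigma,
    )


def normalize_image_for_features(image: MIPImage) -> np.ndarray:
    """Standardize an image to zero mean / unit variance for filtering.

    Returns a bare float array (values leave [0, 1] by design).  Raises on a
    constant image, whose features would be undefined up to scale.
    """
    px = image.pixels
    sd = px.std()
    if sd == 0:
        raise ValueError(f"zero variance image {image.source_id!r}")
    return (px - px.mean()) / sd


def _convolve_bank(pixels: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Convolve one image with every kernel, reflect padding, FFT-based.

    Returns an array of shape (n_kernels, rows, cols).  The image FFT is
    computed once and shared across the bank.
    """
    n, support, _ = kernels.shape
    half = support // 2
    padded = np.pad(pixels, half, mode="reflect")
    fr = scipy.fft.next_fast_len(padded.shape[0] + support - 1)
    fc = scipy.fft.next_fast_len(padded.shape[1] + support - 1)
    img_f = scipy.fft.rfft2(padded, s=(fr, fc))
    out = np.empty((n, *pixels.shape), dtype=np.float64)
    for i in range(n):
        ker_f = scipy.fft.rfft2(kernels[i], s=(fr, fc))
        full = scipy.fft.irfft2(img_f * ker_f, s=(fr, fc))
        out[i] = full[
            support - 1 : support - 1 + pixels.shape[0],
            support - 1 : support - 1 + pixels.shape[1],
        ]
    return out


def compute_mr8(
    image: MIPImage | np.ndarray, bank: FilterBank | None = None
) -> FeatureStack:
    """Compute the 8-channel MR8 feature stack of an image.

    Each anisotropic channel holds, per pixel, the maximum over the 6
    orientations of the absolute oriented-filter responses at that
    type/scale; the two isotropic channels keep their signed responses.
    The input is used as-is: standardize first (see
    :func:`normalize_image_for_features`) when fitting or applying the
    statistical noise models.
    """
    if bank is None:
        bank = build_rfs_bank()
    pixels = image.pixels if isinstance(image, MIPImage) else np.asarray(image, float)
    if min(pixels.shape) < bank.support:
        raise ValueError(
            f"image {pixels.shape} smaller than kernel support {bank.support}"
        )
    responses = _convolve_bank(pixels, bank.kernels)
    channels = []
    for group in bank.groups:
        if len(group) == 1:  # isotropic: keep sign
            channels.append(responses[group[0]])
        else:
            channels.append(np.abs(responses[group]).max(axis=0))
    return FeatureStack(values=np.stack(channels, axis=-1))


def weber_normalize(stack: FeatureStack, cutoff: float = 0.03) -> FeatureStack:
    """Per-pixel Weber-style contrast normalization of feature vectors.

    Rescales each pixel's 8-vector F by log(1 + L/cutoff) / L with L = ||F||2
    (texton-classification convention).  Off by default in this pipeline:
    the Gaussian noise models are fit on raw MR8 responses.
    """
    L = np.linalg.norm(stack.values, axis=-1, keepdims=True)
    scale = np.where(L > 0, np.log1p(L / cutoff) / np.where(L > 0, L, 1.0), 1.0)
    return FeatureStack(values=stack.values * scale, channel_names=stack.channel_names)


def features_for(
    image: MIPImage, bank: FilterBank | None = None, weber: bool = False
) -> FeatureStack:
    """Standardize an image and compute its MR8 stack (the model pipeline)."""
    stack = compute_mr8(normalize_image_for_features(image), bank=bank)
    return weber_normalize(stack) if weber else stack
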