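"""Raster I/O and the shared image/mask containers.

Conventions used throughout the package: rasters are row-major 2-D arrays
indexed ``(row, col)`` with the origin at the top-left, 0-based.  Intensity
images are stored as float64 normalized to [0, 1]; binary masks are uint8
arrays with values strictly in {0, 1} (written to disk as 0/255 for visual
inspectability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger("dte")

MIN_SIDE = 16

#: valid roles for a BinaryMask
MASK_ROLES = ("ground_truth", "coarse", "refined", "soma", "edit_add", "edit_remove")

# Rec. 709 luminance weights, used when a color raster sneaks in.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class MIPImage:
    """A 2-D maximum-intensity-projection image, normalized to [0, 1].

    Parameters
    ----------
    pixels : ndarray
        2-D float array of intensities in [0, 1].
    source_id : str
        Free-text label identifying where the image came from.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2-D MIP, got ndim={self.pixels.ndim}")
        if self.height < MIN_SIDE or self.width < MIN_SIDE:
            raise ValueError(
                f"image too small: {self.pixels.shape}, need >= {MIN_SIDE} per side"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("image pixels must lie in [0, 1] after loading")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A binary labeling paired with a :class:`MIPImage` of the same shape."""

    labels: np.ndarray
    role: str = "ground_truth"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"expected 2-D mask, got ndim={self.labels.ndim}")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; valid: {MASK_ROLES}")
        vals = np.unique(self.labels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be strictly in {0, 1}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.labels.sum())

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)


@dataclass
class TrainingSet:
    """Ordered (image, ground-truth mask) pairs used to fit the noise models."""

    pairs: list[tuple[MIPImage, BinaryMask]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for img, mask in self.pairs:
            if img.shape != mask.shape:
                raise ValueError(
                    f"image/mask shape mismatch for {img.source_id!r}: "
                    f"{img.shape} vs {mask.shape}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return TrainingSet(self.pairs[i])
        return self.pairs[i]

    def drop(self, index: int) -> "TrainingSet":
        """Return a copy with pair ``index`` removed (LOOCV helper)."""
        return TrainingSet([p for j, p in enumerate(self.pairs) if j != index])


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    return np.asarray(arr)


def _to_single_channel(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        logger.warning("reducing color raster %s to luminance", path)
        rgb = arr[..., :3].astype(np.float64)
        return rgb @ _LUMA
    raise ValueError(
        f"expected 2-D MIP, got array of shape {arr.shape} from {path} "
        "(3-D stacks must be projected before use)"
    )


def load_image(path: str | Path, bit_depth_hint: int | None = None) -> MIPImage:
    """Load a single-channel TIFF/PNG raster and normalize it to [0, 1].

    Integer rasters are divided by the container full-scale value (255 for
    8-bit, 65535 for 16-bit, and generally ``2**bits - 1``); float rasters
    with a maximum above 1 are divided by their data maximum, while floats
    already within [0, 1] are taken as-is so that float round-trips are
    value-preserving.  ``bit_depth_hint`` overrides the container scale.
    """
    path = Path(path)
    raw = _read_raster(path)
    arr = np.asarray(_to_single_channel(raw, path))
    # scale by the container's dtype, not the post-luminance dtype
    if np.issubdtype(raw.dtype, np.integer):
        if bit_depth_hint is not None:
            scale = float(2**bit_depth_hint - 1)
        else:
            scale = float(np.iinfo(raw.dtype).max)
        pixels = arr.astype(np.float64) / scale
    else:
        pixels = arr.astype(np.float64)
        if not np.all(np.isfinite(pixels)):
            raise ValueError(f"non-finite pixels in {path}")
        mx = pixels.max()
        if mx > 1.0:
            pixels = pixels / mx
        if pixels.min() < 0:
            raise ValueError(f"negative float intensities in {path}")
    return MIPImage(pixels=pixels, source_id=path.stem)


def save_image(image: MIPImage, path: str | Path) -> None:
    """Write an image as float32 TIFF or 16-bit PNG depending on suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image.pixels.astype(np.float32))
    else:
        iio.imwrite(str(path), np.round(image.pixels * 65535).astype(np.uint16))


def load_mask(
    path: str | Path,
    expected_shape: tuple[int, int] | None = None,
    role: str = "ground_truth",
) -> BinaryMask:
    """Load a mask raster; any nonzero pixel maps to 1."""
    path = Path(path)
    arr = _to_single_channel(_read_raster(path), path)
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise ValueError(
            f"mask shape {tuple(arr.shape)} does not match expected "
            f"{tuple(expected_shape)} ({path})"
        )
    return BinaryMask(labels=(arr != 0).astype(np.uint8), role=role)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit raster with foreground = 255."""
    path = Path(path)
    out = (mask.labels * np.uint8(255)).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), out)
    else:
        iio.imwrite(str(path), out)


def load_training_set(
    image_paths: Sequence[str | Path], mask_paths: Sequence[str | Path]
) -> TrainingSet:
    """Pair up image and ground-truth mask files, in the order given."""
    if len(image_paths) != len(mask_paths):
        raise ValueError(
            f"{len(image_paths)} images vs {len(mask_paths)} masks"
        )
    pairs = []
    for ip, mp in zip(image_paths, mask_paths):
        img = load_image(ip)
        mask = load_mask(mp, expected_shape=img.shape)
        pairs.append((img, mask))
    return TrainingSet(pairs)
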