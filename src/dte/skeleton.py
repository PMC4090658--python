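"""Skeletonization of the refined segmentation by morphological thinning.

Thinning repeatedly matches hit-or-miss templates over the mask and deletes
matched foreground pixels until a fixed point: a one-pixel-wide skeleton that
preserves 8-connectivity.  The template machinery is the standard Guo-Hall
two-subiteration scheme (``skimage.morphology.thin``), run here one pass at a
time so convergence is observable and capped at the image diagonal.

Blob-like somas thinned together with the branches collapse into spurious
loops, so a soma mask, when available, is subtracted before thinning and
OR-ed back afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import thin as _thin_pass

from .io_core import BinaryMask

logger = logging.getLogger("dte")

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structure


@dataclass
class Skeleton:
    """A thinned, one-pixel-wide tree labeling."""

    labels: np.ndarray
    iterations_run: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("skeleton must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)

    def as_mask(self) -> BinaryMask:
        return BinaryMask(labels=self.labels, role="refined")


def thin(mask: BinaryMask, soma: BinaryMask | None = None) -> Skeleton:
    """Thin a mask to its skeleton, with optional soma removal/re-integration.

    The soma region is subtracted before thinning (preventing artificial
    loops around the blob) and OR-ed back into the result.  Iteration stops
    at the thinning fixed point, capped at the image diagonal in pixels.
    """
    work = mask.as_bool()
    if soma is not None:
        if soma.shape != mask.shape:
            raise ValueError("soma mask shape mismatch")
        work = work & ~soma.as_bool()
    elif work.any():
        logger.info("no soma mask supplied; blob regions may thin into loops")

    cap = int(np.ceil(np.hypot(*mask.shape)))
    iterations = 0
    while iterations < cap:
        nxt = _thin_pass(work, max_num_iter=1)
        iterations += 1
        if np.array_equal(nxt, work):
            break
        work = nxt

    if soma is not None:
        work = work | soma.as_bool()
    return Skeleton(labels=work.astype(np.uint8), iterations_run=iterations)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def skeleton_summary(skel: Skeleton) -> dict[str, int]:
    """Structural summary: components, branch points, endpoints, length.

    Components use 8-connectivity; an endpoint is a skeleton pixel with
    exactly 1 skeleton neighbor; total length is the foreground pixel count.
    High-degree pixels (>= 3 neighbors) form small clusters around a
    junction on a digital grid, so a branch point is counted as one
    8-connected cluster of such pixels — a T of two lines has one branch
    point, not four.
    """
    s = skel.as_bool()
    if not s.any():
        return {
            "n_components": 0,
            "n_branch_points": 0,
            "n_endpoints": 0,
            "total_length_px": 0,
        }
    _, n_components = ndimage.label(s, structure=_EIGHT)
    neighbors = _neighbor_counts(s)
    _, n_branch = ndimage.label(s & (neighbors >= 3), structure=_EIGHT)
    return {
        "n_components": int(n_components),
        "n_branch_points": int(n_branch),
        "n_endpoints": int(np.count_nonzero(s & (neighbors == 1))),
        "total_length_px": int(s.sum()),
    }
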