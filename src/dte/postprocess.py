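"""Refinement of the coarse segmentation.

Three stages, in pipeline order: (1) morphological opening then closing to
drop isolated pixels and fill small holes; (2) Hough-transform detection of
strong straight-line structures in the cleaned mask, which are stroked back
into it to reinforce broken branches; (3) optional user edit masks that add
or remove regions (remove wins by construction).

Structuring elements: the opening uses a disk (tubular branch cross-sections
are disk-open, so opening leaves intact branches untouched while deleting
speckle smaller than the disk); the closing uses a square of side
``2 * close_radius + 1``.  A square fits into the right-angle inner corners
at branch junctions, so closing bridges genuine gaps up to ``2 *
close_radius`` pixels without depositing fillet pixels at every junction,
which any disk-shaped closing provably does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as draw_line
from skimage.morphology import closing, dilation, disk, opening
from skimage.transform import hough_line, probabilistic_hough_line

from .io_core import BinaryMask

DEFAULT_OPEN_RADIUS = 1
DEFAULT_CLOSE_RADIUS = 2
DEFAULT_PEAK_FRACTION = 0.5
DEFAULT_MIN_LENGTH = 25
DEFAULT_MAX_GAP = 3
DEFAULT_STROKE_WIDTH = 2


@dataclass
class HoughLineSet:
    """Strong straight-line segments detected in a binary mask.

    Segments are ((r0, c0), (r1, c1)) pixel coordinates.  A segment is kept
    iff its accumulator support reaches ``accumulator_peak_fraction`` of the
    global standard-Hough accumulator maximum and its length is at least
    ``min_length``; gaps up to ``max_gap`` pixels are tolerated inside one
    segment.
    """

    lines: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    accumulator_peak_fraction: float = DEFAULT_PEAK_FRACTION
    min_length: int = DEFAULT_MIN_LENGTH
    max_gap: int = DEFAULT_MAX_GAP

    def __len__(self) -> int:
        return len(self.lines)


def morphological_clean(
    mask: BinaryMask,
    open_radius: int = DEFAULT_OPEN_RADIUS,
    close_radius: int = DEFAULT_CLOSE_RADIUS,
) -> BinaryMask:
    """Open with a disk, then close with a square; radius 0 skips a step."""
    if open_radius < 0 or close_radius < 0:
        raise ValueError("structuring-element radii must be >= 0")
    out = mask.as_bool()
    if open_radius > 0:
        out = opening(out, disk(open_radius))
    if close_radius > 0:
        side = 2 * close_radius + 1
        out = closing(out, np.ones((side, side), dtype=bool))
    return BinaryMask(labels=out.astype(np.uint8), role="refined")


def detect_lines(
    mask: BinaryMask,
    accumulator_peak_fraction: float = DEFAULT_PEAK_FRACTION,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_gap: int = DEFAULT_MAX_GAP,
    seed: int = 0,
) -> HoughLineSet:
    """Probabilistic Hough detection of strong straight lines in a mask.

    The vote threshold is ``accumulator_peak_fraction`` times the global
    maximum of the standard Hough accumulator of the mask, so "strong" is
    relative to the most prominent line in the image.
    """
    if not 0 < accumulator_peak_fraction <= 1:
        raise ValueError("accumulator_peak_fraction must lie in (0, 1]")
    img = mask.as_bool()
    if not img.any():
        return HoughLineSet(
            lines=[],
            accumulator_peak_fraction=accumulator_peak_fraction,
            min_length=min_length,
            max_gap=max_gap,
        )
    accumulator, _, _ = hough_line(img)
    votes = max(1, int(accumulator_peak_fraction * accumulator.max()))
    segments = probabilistic_hough_line(
        img,
        threshold=votes,
        line_length=min_length,
        line_gap=max_gap,
        rng=seed,
    )
    # skimage returns (x, y) = (col, row) endpoints; store (row, col)
    lines = [((p0[1], p0[0]), (p1[1], p1[0])) for p0, p1 in segments]
    return HoughLineSet(
        lines=lines,
        accumulator_peak_fraction=accumulator_peak_fraction,
        min_length=min_length,
        max_gap=max_gap,
    )


def reinforce_lines(
    mask: BinaryMask, lines: HoughLineSet, stroke_width: int = DEFAULT_STROKE_WIDTH
) -> BinaryMask:
    """Union the mask with each detected line rasterized at ``stroke_width``.

    The output is a pixelwise superset of the input.  Stroke thickness is
    realized by dilating the 1-px rasterized line with a disk of radius
    ``stroke_width // 2`` (so widths round up to the next odd integer).
    """
    if stroke_width < 1:
        raise ValueError("stroke_width must be >= 1")
    strokes = np.zeros(mask.shape, dtype=bool)
    for (r0, c0), (r1, c1) in lines.lines:
        rr, cc = draw_line(r0, c0, r1, c1)
        strokes[rr.clip(0, mask.height - 1), cc.clip(0, mask.width - 1)] = True
    radius = stroke_width // 2
    if strokes.any() and radius > 0:
        strokes = dilation(strokes, disk(radius))
    return BinaryMask(labels=(mask.as_bool() | strokes).astype(np.uint8), role="refined")


def apply_edits(
    mask: BinaryMask,
    add: BinaryMask | None = None,
    remove: BinaryMask | None = None,
) -> BinaryMask:
    """Apply user edit masks: ``(mask OR add) AND NOT remove``.

    Overlapping add/remove pixels are rejected as ambiguous intent.
    """
    out = mask.as_bool()
    if add is not None and add.shape != mask.shape:
        raise ValueError("add mask shape mismatch")
    if remove is not None and remove.shape != mask.shape:
        raise ValueError("remove mask shape mismatch")
    if add is not None and remove is not None:
        if np.any(add.as_bool() & remove.as_bool()):
            raise ValueError("add and remove edit masks overlap")
    if add is not None:
        out = out | add.as_bool()
    if remove is not None:
        out = out & ~remove.as_bool()
    return BinaryMask(labels=out.astype(np.uint8), role="refined")


def refine(
    coarse: BinaryMask,
    open_radius: int = DEFAULT_OPEN_RADIUS,
    close_radius: int = DEFAULT_CLOSE_RADIUS,
    accumulator_peak_fraction: float = DEFAULT_PEAK_FRACTION,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_gap: int = DEFAULT_MAX_GAP,
    stroke_width: int = DEFAULT_STROKE_WIDTH,
    add: BinaryMask | None = None,
    remove: BinaryMask | None = None,
    seed: int = 0,
) -> BinaryMask:
    """Full refinement: clean, detect strong lines, reinforce, apply edits."""
    cleaned = morphological_clean(coarse, open_radius, close_radius)
    lines = detect_lines(
        cleaned,
        accumulator_peak_fraction=accumulator_peak_fraction,
        min_length=min_length,
        max_gap=max_gap,
        seed=seed,
    )
    reinforced = reinforce_lines(cleaned, lines, stroke_width=stroke_width)
    return apply_edits(reinforced, add=add, remove=remove)
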