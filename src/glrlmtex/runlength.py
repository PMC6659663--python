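"""Whole-image forward run-length computation.

For a direction ``(dx, dy)``, the run length array RLArr holds at each
pixel the length of the maximal equal-intensity run *starting* at that
pixel and walking forward along the direction, unbounded by any ROI.  It
obeys the recurrence

    RLArr[p] = 1 + RLArr[p + (dx, dy)]   if the successor is in-image and
                                          has the same intensity,
             = 1                          otherwise,

so it is filled by traversing the image opposite to the direction,
anchored at the ending pixels (those with no in-image successor).  The
implementation below vectorizes the recurrence one image row/column at a
time, which is equivalent to walking every direction line from its
ending pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import Direction, GrayImage

__all__ = ["RunLengthArray", "ending_pixels", "compute_run_length_array"]


@dataclass(frozen=True)
class RunLengthArray:
    """Per-pixel forward run length along one direction; same shape as the image."""

    values: np.ndarray
    direction: Direction


def ending_pixels(height: int, width: int, direction: Direction) -> set[tuple[int, int]]:
    """Pixels with no in-image successor along ``(dx, dy)``, as (row, col) pairs.

    H0 -> last column; V90 -> first row; AD45 -> last column plus first
    row; D135 -> first column plus first row.
    """
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    dx, dy = direction.dx, direction.dy
    out: set[tuple[int, int]] = set()
    for y in range(height):
        for x in range(width):
            nx, ny = x + dx, y + dy
            if not (0 <= nx < width and 0 <= ny < height):
                out.add((y, x))
    return out


def compute_run_length_array(image: GrayImage, direction: Direction) -> RunLengthArray:
    """Fill RLArr for the whole image in time linear in the pixel count."""
    px = image.pixels
    h, w = px.shape
    rl = np.ones((h, w), dtype=np.int64)
    dx, dy = direction.dx, direction.dy

    if (dx, dy) == (1, 0):
        # successor is one column right; sweep columns right to left
        for x in range(w - 2, -1, -1):
            same = px[:, x] == px[:, x + 1]
            rl[same, x] = rl[same, x + 1] + 1
    elif (dx, dy) == (0, -1):
        # successor is one row up; sweep rows top to bottom
        for y in range(1, h):
            same = px[y, :] == px[y - 1, :]
            rl[y, same] = rl[y - 1, same] + 1
    elif (dx, dy) == (1, -1):
        # successor is right and up
        for y in range(1, h):
            if w > 1:
                same = px[y, : w - 1] == px[y - 1, 1:]
                rl[y, : w - 1][same] = rl[y - 1, 1:][same] + 1
    elif (dx, dy) == (-1, -1):
        # successor is left and up
        for y in range(1, h):
            if w > 1:
                same = px[y, 1:] == px[y - 1, : w - 1]
                rl[y, 1:][same] = rl[y - 1, : w - 1][same] + 1
    else:  # pragma: no cover - Direction invariant excludes this
        raise ValueError(f"unsupported direction ({dx}, {dy})")

    rl.setflags(write=False)
    return RunLengthArray(values=rl, direction=direction)
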