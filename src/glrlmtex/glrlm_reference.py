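"""Reference GLRLM engines: per-ROI brute force and the optimized sequential scan.

Two independent constructions of the same object:

* :func:`glrlm_single_roi` walks every direction line of one ROI pixel
  by pixel and tallies maximal equal-intensity runs.  It is deliberately
  simple — the ground-truth oracle the other engines are validated
  against.
* :func:`glrlm_all_rois_sequential` first computes the whole-image run
  length array once, then for each ROI reads the pre-computed run length
  at every line starting pixel, truncates it to the pixels remaining
  inside the ROI, and jumps directly over the run to the next starting
  pixel — avoiding the per-ROI rescans of the naive approach.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .glrlm_batch import SparseGLRLMBatch, encode_key
from .image_model import Direction, GrayImage, ROISpec, roi_positions
from .runlength import compute_run_length_array

__all__ = [
    "GLRLMSingle",
    "glrlm_single_roi",
    "glrlm_all_rois_sequential",
    "glrlm_all_rois_oracle",
]


@dataclass(frozen=True)
class GLRLMSingle:
    """Sparse GLRLM of one ROI: {(gray, run): count} with only non-null entries."""

    entries: dict[tuple[int, int], int]
    roi_index: int
    direction: Direction

    @property
    def total_runs(self) -> int:
        return sum(self.entries.values())

    def run_pixel_total(self) -> int:
        """Sum of run * count over all entries; equals N for a valid matrix."""
        return sum(run * c for (_, run), c in self.entries.items())


def _runs_in_window(
    px: np.ndarray, top: int, left: int, h: int, w: int, dx: int, dy: int
) -> Counter:
    """Tally maximal runs on every direction line of the window (brute force).

    Works for any nonzero step (dx, dy), which lets reversal invariance
    be exercised directly with negated vectors.
    """
    counts: Counter = Counter()
    for r in range(h):
        for c in range(w):
            # line starting pixels: predecessor lies outside the window
            if 0 <= r - dy < h and 0 <= c - dx < w:
                continue
            rr, cc = r, c
            while 0 <= rr < h and 0 <= cc < w:
                val = px[top + rr, left + cc]
                run = 0
                while 0 <= rr < h and 0 <= cc < w and px[top + rr, left + cc] == val:
                    run += 1
                    rr += dy
                    cc += dx
                counts[(int(val), run)] += 1
    return counts


def glrlm_single_roi(
    image: GrayImage,
    top_row: int,
    top_col: int,
    spec: ROISpec,
    direction: Direction,
) -> GLRLMSingle:
    """Brute-force sparse GLRLM of the ROI whose top-left pixel is (top_row, top_col)."""
    h, w = spec.roi_height, spec.roi_width
    if not (
        0 <= top_row <= image.height - h and 0 <= top_col <= image.width - w
    ):
        raise GeometryError(
            f"ROI {h}x{w} at ({top_row}, {top_col}) not inside "
            f"{image.height}x{image.width} image"
        )
    counts = _runs_in_window(
        image.pixels, top_row, top_col, h, w, direction.dx, direction.dy
    )
    return GLRLMSingle(
        entries=dict(counts),
        roi_index=top_row * image.width + top_col,
        direction=direction,
    )


def glrlm_all_rois_sequential(
    image: GrayImage, spec: ROISpec, direction: Direction
) -> SparseGLRLMBatch:
    """Sequential all-ROI engine built on the whole-image run length array.

    For each ROI and each of its direction lines: start at the pixel
    whose predecessor lies outside the ROI, read RLArr there, truncate to
    the pixels remaining on the line, record the (gray, run) pair and
    skip forward by the run — consecutive equal pixels are never
    revisited.  A truncated run ends the segment at the ROI edge; the
    next in-ROI pixel on the line, if any, starts a fresh run.
    """
    rl = compute_run_length_array(image, direction).values
    px = image.pixels
    dx, dy = direction.dx, direction.dy
    h, w = spec.roi_height, spec.roi_width
    g = image.gl_resolution
    roi_len = spec.roi_length

    tally: Counter = Counter()
    for top, left, roi_index in roi_positions(image, spec):
        for r0 in range(h):
            for c0 in range(w):
                if 0 <= r0 - dy < h and 0 <= c0 - dx < w:
                    continue  # not a line starting pixel
                r, c = r0, c0
                while 0 <= r < h and 0 <= c < w:
                    # pixels remaining on this line inside the ROI (closed form)
                    remaining = min(
                        r + 1 if dy < 0 else (h - r if dy > 0 else h + w),
                        c + 1 if dx < 0 else (w - c if dx > 0 else h + w),
                    )
                    run = min(int(rl[top + r, left + c]), remaining)
                    tally[
                        int(
                            encode_key(
                                roi_index, px[top + r, left + c], run, g, roi_len
                            )
                        )
                    ] += 1
                    r += dy * run
                    c += dx * run

    keys = np.fromiter(sorted(tally), dtype=np.int64, count=len(tally))
    counts = np.array([tally[int(k)] for k in keys], dtype=np.int64)
    return SparseGLRLMBatch(
        keys=keys,
        counts=counts,
        spec=spec,
        gl_resolution=g,
        direction=direction,
    )


def glrlm_all_rois_oracle(
    image: GrayImage, spec: ROISpec, direction: Direction
) -> SparseGLRLMBatch:
    """Assemble per-ROI brute-force oracles into one sparse batch.

    Quadratic in work compared to the other engines; exists so the three
    engines can be compared on identical key/count arrays.
    """
    g = image.gl_resolution
    roi_len = spec.roi_length
    tally: Counter = Counter()
    for top, left, roi_index in roi_positions(image, spec):
        single = glrlm_single_roi(image, top, left, spec, direction)
        for (gray, run), c in single.entries.items():
            tally[int(encode_key(roi_index, gray, run, g, roi_len))] += c
    keys = np.fromiter(sorted(tally), dtype=np.int64, count=len(tally))
    counts = np.array([tally[int(k)] for k in keys], dtype=np.int64)
    return SparseGLRLMBatch(
        keys=keys, counts=counts, spec=spec, gl_resolution=g, direction=direction
    )
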