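"""Image container, direction conventions and ROI geometry.

Everything downstream — the per-ROI oracle, the whole-image sequential
engine and the key-encode/sort/reduce batch engine — shares the types
defined here, so the conventions are written down once:

* pixels are indexed ``(row y, column x)`` with ``(0, 0)`` the top-left
  corner; the positive x axis points right and the positive y axis points
  down;
* the four principal directions are expressed as ``(dx, dy)`` steps in
  that frame, so 45° (anti-diagonal) is ``(1, -1)``: one column right,
  one row up;
* an ROI is any fully contained ``roi_height x roi_width`` window, and is
  identified by ``roi_index = top_row * image_width + top_col`` — sparse
  in ``[0, width * height)`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, RangeError, ShapeError

__all__ = [
    "GrayImage",
    "Direction",
    "ROISpec",
    "DIRECTIONS",
    "validate_image",
    "roi_positions",
]


@dataclass(frozen=True)
class Direction:
    """One of the four principal run directions.

    ``dx`` is the column step and ``dy`` the row step of the *forward*
    direction; a run is a maximal set of equal-intensity pixels reachable
    by repeated ``(x + dx, y + dy)`` steps.
    """

    name: str
    dx: int
    dy: int

    @property
    def degrees(self) -> int:
        return {"H0": 0, "AD45": 45, "V90": 90, "D135": 135}[self.name]


#: The canonical direction set: horizontal 0°, anti-diagonal 45°,
#: vertical 90°, diagonal 135°.
DIRECTIONS: dict[str, Direction] = {
    "H0": Direction("H0", 1, 0),
    "AD45": Direction("AD45", 1, -1),
    "V90": Direction("V90", 0, -1),
    "D135": Direction("D135", -1, -1),
}


@dataclass(frozen=True)
class GrayImage:
    """Validated 2-D integer intensity grid.

    ``gl_resolution`` is the number of gray levels G; every intensity
    must lie in ``[0, G - 1]``.  Construct through :func:`validate_image`.
    """

    pixels: np.ndarray
    gl_resolution: int

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ROISpec:
    """ROI geometry and the constants derived from it.

    ``roi_length`` is the key multiplier used by the integer encodings:
    ``max(roi_width, roi_height)``, an upper bound on any run length
    inside the ROI (for the diagonal directions the attainable maximum is
    ``min(roi_width, roi_height)``, but the larger bound keeps one
    multiplier valid for all four directions).  ``level_offset`` is added
    to raw intensities when computing gray-level-weighted features so
    intensity 0 does not meet a 1/i^2 weight; the default is 1.
    """

    roi_width: int
    roi_height: int
    level_offset: int = 1

    def __post_init__(self) -> None:
        if self.roi_width < 1 or self.roi_height < 1:
            raise GeometryError(
                f"ROI dimensions must be >= 1, got {self.roi_height}x{self.roi_width}"
            )
        if self.level_offset < 0:
            raise ValueError("level_offset must be non-negative")

    @property
    def roi_length(self) -> int:
        return max(self.roi_width, self.roi_height)

    @property
    def n_pixels(self) -> int:
        """Total pixels N per ROI."""
        return self.roi_width * self.roi_height


def validate_image(raw_grid, gl_resolution: int) -> GrayImage:
    """Validate a 2-D integer grid and wrap it as a :class:`GrayImage`.

    Raises :class:`ShapeError` for empty or ragged input and
    :class:`RangeError` (naming the offending coordinate) for any value
    outside ``[0, gl_resolution)``.
    """
    if gl_resolution < 1:
        raise ValueError(f"gl_resolution must be >= 1, got {gl_resolution}")
    try:
        arr = np.asarray(raw_grid)
        if arr.dtype == object:
            raise ValueError("ragged")
        arr = arr.astype(np.int64, casting="safe") if arr.dtype.kind in "iu" else arr
    except (ValueError, TypeError) as exc:
        raise ShapeError(f"input grid is not rectangular: {exc}") from None
    if arr.ndim != 2:
        raise ShapeError(f"expected a 2-D grid, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ShapeError("image must have height >= 1 and width >= 1")
    if arr.dtype.kind not in "iu":
        if not np.all(arr == np.floor(arr)):
            raise RangeError("image contains non-integer values")
        arr = arr.astype(np.int64)
    arr = np.ascontiguousarray(arr, dtype=np.int64)
    bad = (arr < 0) | (arr >= gl_resolution)
    if np.any(bad):
        y, x = np.argwhere(bad)[0]
        raise RangeError(
            f"intensity {arr[y, x]} at (row {y}, col {x}) outside [0, {gl_resolution - 1}]"
        )
    arr.setflags(write=False)
    return GrayImage(pixels=arr, gl_resolution=int(gl_resolution))


def roi_positions(image: GrayImage, spec: ROISpec) -> list[tuple[int, int, int]]:
    """Enumerate all fully contained ROI positions.

    Returns ``(top_row, top_col, roi_index)`` triples ordered by
    ``roi_index = top_row * width + top_col`` ascending.  Only windows
    entirely inside the image are produced — no padding, no partial
    windows — so there are
    ``(height - roi_height + 1) * (width - roi_width + 1)`` of them.
    """
    h, w = image.height, image.width
    if spec.roi_height > h or spec.roi_width > w:
        raise GeometryError(
            f"ROI {spec.roi_height}x{spec.roi_width} does not fit in image {h}x{w}"
        )
    return [
        (i, j, i * w + j)
        for i in range(h - spec.roi_height + 1)
        for j in range(w - spec.roi_width + 1)
    ]


def num_rois(image: GrayImage, spec: ROISpec) -> int:
    """Count of fully contained ROI positions."""
    if spec.roi_height > image.height or spec.roi_width > image.width:
        raise GeometryError(
            f"ROI {spec.roi_height}x{spec.roi_width} does not fit in image "
            f"{image.height}x{image.width}"
        )
    return (image.height - spec.roi_height + 1) * (image.width - spec.roi_width + 1)
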