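"""Batch GLRLM construction for all ROIs at once.

The construction is a five-step key-encode / reduce / sort / reduce
pipeline expressed here as plain array-primitive contracts (NumPy
scatter, adjacent reduce-by-key, sort, unique-with-counts):

1. *Expand*: every pixel of every ROI is scattered into one long array,
   direction line by direction line — all first lines of all ROIs, then
   all second lines, and so on — so that each line stays contiguous and
   different lines never touch.  While scattering, the ROI identity is
   folded into the value: ``key_IG = roi_index * G + gray``.
2. *Reduce runs*: collapsing maximal blocks of equal adjacent ``key_IG``
   counts the run length of every gray-level run of every ROI in one
   pass, because equal adjacent keys occur exactly where the same ROI
   has the same gray value consecutively on one line.
3. *Combine*: fold the run length in as well:
   ``key_IGL = key_IG * roi_length + run - 1``.
4. *Sort* the ``key_IGL`` array; ROI index occupies the most significant
   bits, so each ROI's entries (and within them each (gray, run) pair)
   cluster together.
5. *Count*: a second reduce-by-key over the sorted keys yields the
   sparse GLRLMs of every ROI — unique keys plus positive counts, with
   null entries never materialized.

Keys are 64-bit; ``width * height * G * roi_length < 2**63`` is asserted
up front.  Scatter addresses use the dense rank of each ROI (its
position in roi_index order) so the address map is a bijection onto the
output buffer; the key itself carries the sparse ``roi_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, ConsistencyError
from .image_model import Direction, GrayImage, ROISpec, num_rois

__all__ = [
    "RowLayout",
    "SparseGLRLMBatch",
    "line_layout",
    "expand_rois",
    "reduce_runs",
    "combine_keys",
    "sort_and_count",
    "glrlm_all_rois_batch",
    "decode_keys",
    "encode_key",
]


@dataclass(frozen=True)
class RowLayout:
    """Sizes of one ROI's direction lines and their prefix sums.

    ``line_sizes[k]`` (R_k) is the number of pixels on the (k+1)-th line
    of the ROI along the direction; ``prefix[k]`` (N_k) is the number of
    pixels on the first k lines.  ``row_offsets``/``col_offsets`` give,
    for the flattened (line, position) order, each pixel's offset from
    the ROI's top-left corner — the geometry the scatter needs.
    """

    line_sizes: np.ndarray
    prefix: np.ndarray
    row_offsets: np.ndarray = field(repr=False)
    col_offsets: np.ndarray = field(repr=False)

    @property
    def n_pixels(self) -> int:
        return int(self.line_sizes.sum())


@dataclass(frozen=True)
class SparseGLRLMBatch:
    """GLRLMs of every ROI, as sorted unique 64-bit keys with counts.

    ``keys[m]`` encodes (roi_index, gray, run) as
    ``(roi_index * G + gray) * roi_length + run - 1`` and the aligned
    ``counts[m] >= 1`` is the matrix entry P_ij of that ROI.  Keys are
    strictly increasing, so each ROI's entries form one contiguous
    segment.
    """

    keys: np.ndarray
    counts: np.ndarray
    spec: ROISpec
    gl_resolution: int
    direction: Direction

    def decode(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return aligned (roi_index, gray, run) arrays."""
        return decode_keys(self)

    def entries_for_roi(self, roi_index: int) -> dict[tuple[int, int], int]:
        """The one ROI's sparse GLRLM as a {(gray, run): count} mapping."""
        roi, gray, run = self.decode()
        sel = roi == roi_index
        return {
            (int(g), int(r)): int(c)
            for g, r, c in zip(gray[sel], run[sel], self.counts[sel])
        }

    def verify_conservation(self) -> None:
        """Check per-ROI run-pixel conservation: sum of run*count equals N.

        Every pixel of an ROI belongs to exactly one run, so for each ROI
        the run lengths weighted by their counts must add up to
        roi_width * roi_height.  Raises ConsistencyError otherwise.
        """
        roi, _, run = self.decode()
        uniq, inv = np.unique(roi, return_inverse=True)
        totals = np.bincount(inv, weights=run * self.counts)
        n = self.spec.n_pixels
        if not np.all(totals == n):
            bad = uniq[np.nonzero(totals != n)[0][0]]
            raise ConsistencyError(
                f"ROI {bad}: sum of run*count = {totals[np.argmax(uniq == bad)]}, "
                f"expected {n}"
            )


def encode_key(roi_index, gray, run, gl_resolution: int, roi_length: int):
    """Pack (roi_index, gray, run) into a single sortable 64-bit key."""
    return (
        np.asarray(roi_index, dtype=np.int64) * gl_resolution + gray
    ) * roi_length + run - 1


def _check_capacity(image: GrayImage, spec: ROISpec) -> None:
    bound = image.width * image.height * image.gl_resolution * spec.roi_length
    if bound >= 2**63:
        raise CapacityError(
            f"key bound width*height*G*roi_length = {bound} >= 2**63; "
            "keys would overflow 64-bit signed integers"
        )


def line_layout(spec: ROISpec, direction: Direction) -> RowLayout:
    """Geometry of one ROI's direction lines.

    H0 yields roi_height lines of length roi_width; V90 yields roi_width
    lines of length roi_height; the two diagonal directions yield
    roi_width + roi_height - 1 lines of lengths 1, 2, ..., min(w, h),
    ..., 2, 1.  Pixels on a line are ordered along the direction vector
    starting from the pixel whose predecessor falls outside the ROI.
    """
    w, h = spec.roi_width, spec.roi_height
    name = direction.name
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    if name == "H0":
        for k in range(h):
            rows.append(np.full(w, k))
            cols.append(np.arange(w))
    elif name == "V90":
        # walk (0,-1): start at the bottom row, go up
        for k in range(w):
            rows.append(np.arange(h - 1, -1, -1))
            cols.append(np.full(h, k))
    elif name == "AD45":
        # lines of constant r+c, walked (r-1, c+1) from the bottom-left end
        for k in range(w + h - 1):
            r0 = min(k, h - 1)
            size = r0 - max(0, k - (w - 1)) + 1
            ll = np.arange(size)
            rows.append(r0 - ll)
            cols.append(k - r0 + ll)
    elif name == "D135":
        # lines of constant r-c, walked (r-1, c-1) from the bottom-right end
        for d in range(-(w - 1), h):
            r0 = min(h - 1, w - 1 + d)
            size = r0 - max(0, d) + 1
            ll = np.arange(size)
            rows.append(r0 - ll)
            cols.append(r0 - d - ll)
    else:  # pragma: no cover
        raise ValueError(f"unknown direction {name}")

    sizes = np.array([len(r) for r in rows], dtype=np.int64)
    prefix = np.concatenate([[0], np.cumsum(sizes[:-1])])
    return RowLayout(
        line_sizes=sizes,
        prefix=prefix,
        row_offsets=np.concatenate(rows).astype(np.int64),
        col_offsets=np.concatenate(cols).astype(np.int64),
    )


def expand_rois(image: GrayImage, spec: ROISpec, direction: Direction) -> np.ndarray:
    """Step 1: scatter every ROI pixel, tagged with its ROI, into one array.

    The (l+1)-th pixel of the (k+1)-th line of the ROI with dense rank q
    lands at address ``N_k * num_ROIs + R_k * q + l`` and holds
    ``key_IG = roi_index * G + gray``.  Output length is num_ROIs * N and
    every address is written exactly once.
    """
    _check_capacity(image, spec)
    layout = line_layout(spec, direction)
    h, w = image.height, image.width
    g = image.gl_resolution
    n_rows = h - spec.roi_height + 1
    n_cols = w - spec.roi_width + 1
    n_roi = n_rows * n_cols

    tops_r = np.repeat(np.arange(n_rows), n_cols)
    tops_c = np.tile(np.arange(n_cols), n_rows)
    roi_index = tops_r * w + tops_c  # sparse id, row-major == rank order
    rank = np.arange(n_roi, dtype=np.int64)

    out = np.empty(n_roi * spec.n_pixels, dtype=np.int64)
    pos = 0
    for k, (r_k, n_k) in enumerate(zip(layout.line_sizes, layout.prefix)):
        offs_r = layout.row_offsets[pos : pos + r_k]
        offs_c = layout.col_offsets[pos : pos + r_k]
        pos += r_k
        # all ROIs' (k+1)-th lines at once: (n_roi, R_k) gather
        gray = image.pixels[
            tops_r[:, None] + offs_r[None, :], tops_c[:, None] + offs_c[None, :]
        ]
        addr = n_k * n_roi + r_k * rank[:, None] + np.arange(r_k)[None, :]
        out[addr] = roi_index[:, None] * g + gray
    return out


def reduce_runs(
    keys: np.ndarray, segment_starts: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Step 2: collapse maximal blocks of equal adjacent keys.

    Returns one key per block plus the block length, which — on the
    expanded layout — is exactly the run length of each gray-level run.

    ``segment_starts`` marks head positions at which a new block always
    begins regardless of key equality.  The interleaved layout keeps
    lines of *different* ROIs apart through their distinct ROI tags, but
    when the image holds a single ROI its consecutive lines become
    adjacent in the buffer, so the line boundaries are enforced
    explicitly (the head-flag form of segmented reduce-by-key).
    """
    keys = np.asarray(keys, dtype=np.int64)
    if keys.size == 0:
        return keys[:0], keys[:0]
    head = np.empty(keys.size, dtype=bool)
    head[0] = True
    head[1:] = keys[1:] != keys[:-1]
    if segment_starts is not None:
        head[np.asarray(segment_starts, dtype=np.int64)] = True
    starts = np.flatnonzero(head)
    runs = np.diff(np.concatenate([starts, [keys.size]]))
    return keys[starts], runs


def combine_keys(keys: np.ndarray, runs: np.ndarray, roi_length: int) -> np.ndarray:
    """Step 3: fold each run length into its key: key_IG * roi_length + run - 1."""
    runs = np.asarray(runs, dtype=np.int64)
    if runs.size and int(runs.max()) > roi_length:
        raise ConsistencyError(
            f"run length {int(runs.max())} exceeds roi_length {roi_length}; "
            "the expanded layout must bound runs by the line length"
        )
    return np.asarray(keys, dtype=np.int64) * roi_length + runs - 1


def sort_and_count(
    keys: np.ndarray,
    spec: ROISpec,
    gl_resolution: int,
    direction: Direction,
) -> SparseGLRLMBatch:
    """Steps 4-5: sort the combined keys and merge equal ones with counts."""
    uniq, counts = np.unique(np.asarray(keys, dtype=np.int64), return_counts=True)
    return SparseGLRLMBatch(
        keys=uniq,
        counts=counts.astype(np.int64),
        spec=spec,
        gl_resolution=gl_resolution,
        direction=direction,
    )


def glrlm_all_rois_batch(
    image: GrayImage, spec: ROISpec, direction: Direction
) -> SparseGLRLMBatch:
    """Full five-step batch construction for every ROI of the image."""
    n_roi = num_rois(image, spec)  # geometry check
    expanded = expand_rois(image, spec, direction)
    layout = line_layout(spec, direction)
    # head flags: every (line, ROI) segment begins a fresh run
    starts = (
        layout.prefix[:, None] * n_roi
        + layout.line_sizes[:, None] * np.arange(n_roi)[None, :]
    ).ravel()
    keys_ig, runs = reduce_runs(expanded, segment_starts=starts)
    keys_igl = combine_keys(keys_ig, runs, spec.roi_length)
    return sort_and_count(keys_igl, spec, image.gl_resolution, direction)


def decode_keys(batch: SparseGLRLMBatch) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert the key packing: roi = (key / L) / G, gray = (key / L) % G,
    run = key % L + 1 (integer arithmetic)."""
    ig = batch.keys // batch.spec.roi_length
    run = batch.keys % batch.spec.roi_length + 1
    return ig // batch.gl_resolution, ig % batch.gl_resolution, run
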