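"""Readers and writers: grayscale images in, CSV triplets and feature maps out.

Accepted image inputs are 8-bit grayscale PNG, PGM (plain P2 or binary
P5) and plain comma-separated integer matrices.  All outputs are CSV
(comma separator, header row, LF endings, no quoting) so they diff
cleanly and round-trip bit-exactly; PNG renderings of feature maps are
display artifacts only.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .errors import GLRLMError, RangeError
from .features import FEATURE_NAMES, FeatureMaps
from .glrlm_batch import SparseGLRLMBatch, encode_key
from .image_model import Direction, GrayImage, ROISpec, validate_image

__all__ = [
    "read_image",
    "write_image_csv",
    "write_glrlm_triplets",
    "read_glrlm_triplets",
    "write_feature_maps",
]


class UnreadableImageError(GLRLMError):
    """The input file could not be decoded as a grayscale image."""


def read_image(path: str | Path, gl_resolution: int = 256) -> GrayImage:
    """Decode a PNG/PGM/CSV file into a validated :class:`GrayImage`."""
    path = Path(path)
    if not path.exists():
        raise UnreadableImageError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in {".csv", ".txt"}:
        try:
            arr = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
        except ValueError as exc:
            raise UnreadableImageError(f"{path}: not an integer CSV matrix ({exc})") from None
    else:
        from PIL import Image

        try:
            with Image.open(path) as im:
                if im.mode in ("L", "I", "I;16", "P", "1"):
                    arr = np.asarray(im.convert("I"), dtype=np.int64)
                else:
                    raise UnreadableImageError(
                        f"{path}: mode {im.mode} is not grayscale; convert first"
                    )
        except (OSError, SyntaxError) as exc:
            raise UnreadableImageError(f"{path}: cannot decode ({exc})") from None
    try:
        return validate_image(arr, gl_resolution)
    except RangeError as exc:
        raise RangeError(f"{path}: {exc}") from None


def write_image_csv(image: GrayImage, path: str | Path) -> None:
    """Write an image as a comma-separated integer matrix."""
    np.savetxt(path, image.pixels, fmt="%d", delimiter=",", newline="\n")


def write_glrlm_triplets(batch: SparseGLRLMBatch, path: str | Path) -> None:
    """Serialize a batch in decoded form, one non-null entry per row.

    Columns are roi_index, gray_level, run_length, count; rows keep key
    order (ascending), so the file is a lossless, diffable rendering of
    the sparse batch.
    """
    roi, gray, run = batch.decode()
    with open(path, "w", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["roi_index", "gray_level", "run_length", "count"])
        for row in zip(roi, gray, run, batch.counts):
            writer.writerow([int(v) for v in row])


def read_glrlm_triplets(
    path: str | Path,
    spec: ROISpec,
    gl_resolution: int,
    direction: Direction,
) -> SparseGLRLMBatch:
    """Inverse of :func:`write_glrlm_triplets`."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, dtype=np.int64, ndmin=2)
    if data.size == 0:
        keys = np.empty(0, dtype=np.int64)
        counts = np.empty(0, dtype=np.int64)
    else:
        keys = encode_key(data[:, 0], data[:, 1], data[:, 2], gl_resolution, spec.roi_length)
        counts = data[:, 3]
        order = np.argsort(keys)
        keys, counts = keys[order], counts[order]
    return SparseGLRLMBatch(
        keys=keys, counts=counts, spec=spec, gl_resolution=gl_resolution, direction=direction
    )


def write_feature_maps(
    maps: FeatureMaps,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("csv",),
) -> list[Path]:
    """Write one file per feature per requested format.

    CSV files carry full double precision (``%.17g``) and are the
    normative output.  PNG files are min-max normalized 16-bit grayscale
    renderings for visual inspection only.  Filenames use degree labels,
    e.g. ``SRE_d045.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"d{maps.direction.degrees:03d}"
    written: list[Path] = []
    for name in (n for n in FEATURE_NAMES if n in maps.maps):
        grid = maps.maps[name]
        if "csv" in formats:
            p = out_dir / f"{name}_{tag}.csv"
            np.savetxt(p, grid, fmt="%.17g", delimiter=",", newline="\n")
            written.append(p)
        if "png" in formats:
            from PIL import Image

            lo, hi = float(np.nanmin(grid)), float(np.nanmax(grid))
            scale = (grid - lo) / (hi - lo) if hi > lo else np.zeros_like(grid)
            img = Image.fromarray((scale * 65535).astype(np.uint16))
            p = out_dir / f"{name}_{tag}.png"
            img.save(p)
            written.append(p)
    return written
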