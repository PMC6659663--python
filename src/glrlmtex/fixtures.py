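"""Embedded worked example and deterministic synthetic image generators.

The worked example is a 5x5 ROI with five distinct gray values whose
four directional GLRLMs are known exactly; it exercises every engine
end to end with no external data.  The synthetic generators produce
patterns with closed-form GLRLMs (constant, checkerboard, stripes) plus
seeded uniform noise for randomized cross-engine checks.  The random
generator is NumPy's PCG64 (``np.random.default_rng(seed)``) drawing
``integers(0, gl_resolution)`` — fixed here so seeded property tests are
reproducible across machines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import GrayImage, validate_image

__all__ = [
    "Fixture",
    "table1_fixture",
    "synth_constant",
    "synth_checkerboard",
    "synth_stripes",
    "synth_random",
]


@dataclass(frozen=True)
class Fixture:
    """A named image with, optionally, its known GLRLMs per direction."""

    name: str
    image: GrayImage
    expected: dict[str, dict[tuple[int, int], int]] | None = None


# The 5x5 worked ROI (five distinct gray values: 0, 42, 113, 128, 255).
_WORKED_ROI = [
    [0, 255, 113, 113, 42],
    [255, 42, 113, 113, 0],
    [128, 113, 255, 0, 42],
    [113, 255, 0, 128, 42],
    [42, 113, 128, 255, 255],
]

# Known sparse GLRLMs of the worked ROI, {(gray, run): count} per direction.
_WORKED_GLRLMS: dict[str, dict[tuple[int, int], int]] = {
    "H0": {
        (0, 1): 4,
        (42, 1): 5,
        (113, 1): 3,
        (113, 2): 2,
        (128, 1): 3,
        (255, 1): 4,
        (255, 2): 1,
    },
    "AD45": {
        (0, 1): 1,
        (0, 3): 1,
        (42, 1): 5,
        (113, 1): 3,
        (113, 4): 1,
        (128, 1): 1,
        (128, 2): 1,
        (255, 1): 2,
        (255, 2): 2,
    },
    "V90": {
        (0, 1): 4,
        (42, 1): 3,
        (42, 2): 1,
        (113, 1): 3,
        (113, 2): 2,
        (128, 1): 3,
        (255, 1): 6,
    },
    "D135": {
        (0, 1): 4,
        (42, 1): 5,
        (113, 1): 3,
        (113, 2): 2,
        (128, 1): 3,
        (255, 1): 6,
    },
}


def table1_fixture() -> Fixture:
    """The embedded 5x5 worked ROI with its four known GLRLMs."""
    return Fixture(
        name="worked-roi-5x5",
        image=validate_image(_WORKED_ROI, gl_resolution=256),
        expected={k: dict(v) for k, v in _WORKED_GLRLMS.items()},
    )


def synth_constant(height: int, width: int, value: int, gl_resolution: int = 256) -> GrayImage:
    """Single-intensity image; every direction line is one maximal run."""
    return validate_image(np.full((height, width), value, dtype=np.int64), gl_resolution)


def synth_checkerboard(
    height: int, width: int, v0: int, v1: int, gl_resolution: int = 256
) -> GrayImage:
    """Two-color checkerboard; no two adjacent pixels match, so all runs
    have length 1 in every direction."""
    yy, xx = np.indices((height, width))
    return validate_image(np.where((yy + xx) % 2 == 0, v0, v1), gl_resolution)


def synth_stripes(
    height: int, width: int, period: int, values, gl_resolution: int = 256
) -> GrayImage:
    """Vertical stripes: column x has intensity values[(x // period) % len(values)]."""
    if period < 1:
        raise ValueError("period must be >= 1")
    values = np.asarray(values, dtype=np.int64)
    cols = values[(np.arange(width) // period) % len(values)]
    return validate_image(np.tile(cols, (height, 1)), gl_resolution)


def synth_random(height: int, width: int, gl_resolution: int, seed: int) -> GrayImage:
    """Seeded i.i.d. uniform intensities over [0, gl_resolution)."""
    if gl_resolution < 2:
        raise ValueError("gl_resolution must be >= 2 for random images")
    rng = np.random.default_rng(seed)
    return validate_image(
        rng.integers(0, gl_resolution, size=(height, width)), gl_resolution
    )
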