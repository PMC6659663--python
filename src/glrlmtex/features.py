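"""The 11 run-length texture features, computed per ROI from a sparse batch.

With P_ij the count of runs of gray level i and length j in one ROI,
S = sum_ij P_ij the ROI's total run count and N its pixel count, the
features are

    SRE   = sum P_ij / j^2 / S      LGRE  = sum P_ij / i^2 / S
    LRE   = sum j^2 P_ij / S        HGRE  = sum i^2 P_ij / S
    GLN   = sum_i (sum_j P_ij)^2 / S
    RLN   = sum_j (sum_i P_ij)^2 / S
    RP    = S / N
    SRLGE = sum P_ij / (i^2 j^2) / S    SRHGE = sum i^2 P_ij / j^2 / S
    LRLGE = sum j^2 P_ij / i^2 / S      LRHGE = sum i^2 j^2 P_ij / S

The gray level i entering the weights is ``intensity + level_offset``
(offset 1 by default, so intensity 0 is representable under the
inverse-square weights; offset 0 applies the weights to raw intensities
and raises an explicit error if intensity 0 occurs under a 1/i^2 term).

The summations fall into three shapes, each a keyed reduction over the
sorted batch: plain segment sums per ROI (S and all numerators of the
emphasis features), and for GLN/RLN an inner reduce over (roi, gray) or
(roi, run) groups followed by a square and an outer segment sum.
Dropping the run length from a key preserves key order; dropping the
gray level does not, so the RLN path re-sorts within ROI segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import CompletenessError, DivisionDomainError
from .glrlm_batch import SparseGLRLMBatch
from .image_model import Direction, ROISpec

__all__ = [
    "FEATURE_NAMES",
    "EMPHASIS_POWERS",
    "FeatureTable",
    "FeatureMaps",
    "roi_denominators",
    "weighted_feature",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "extract_all_features",
    "assemble_feature_maps",
]

#: Canonical feature order.
FEATURE_NAMES = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
)

#: (gray power a, run power b) of the weight i^a * j^b for each
#: emphasis-type feature.
EMPHASIS_POWERS: dict[str, tuple[int, int]] = {
    "SRE": (0, -2),
    "LRE": (0, 2),
    "LGRE": (-2, 0),
    "HGRE": (2, 0),
    "SRLGE": (-2, -2),
    "SRHGE": (2, -2),
    "LRLGE": (-2, 2),
    "LRHGE": (2, 2),
}


@dataclass(frozen=True)
class FeatureTable:
    """One value of each of the 11 features per ROI, for one direction."""

    roi_index: np.ndarray
    values: dict[str, np.ndarray]
    direction: Direction
    level_offset: int

    def __post_init__(self) -> None:
        assert set(self.values) == set(FEATURE_NAMES)

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: one row per ROI, one column per feature."""
        df = pd.DataFrame({"roi_index": self.roi_index})
        for name in FEATURE_NAMES:
            df[name] = self.values[name]
        return df


@dataclass(frozen=True)
class FeatureMaps:
    """Dense per-feature grids; cell (i, j) is the ROI with top-left pixel (i, j)."""

    maps: dict[str, np.ndarray]
    direction: Direction
    log_transformed: frozenset = field(default_factory=frozenset)


def _roi_segments(batch: SparseGLRLMBatch):
    """Unique roi indices and the inverse map for segment reductions."""
    roi, gray, run = batch.decode()
    uniq, inv = np.unique(roi, return_inverse=True)
    return roi, gray, run, uniq, inv


def roi_denominators(batch: SparseGLRLMBatch) -> tuple[np.ndarray, np.ndarray]:
    """Total run count S per ROI: a segment sum of counts over roi groups.

    Returns (roi_index ascending, S) aligned arrays.
    """
    _, _, _, uniq, inv = _roi_segments(batch)
    s = np.bincount(inv, weights=batch.counts, minlength=len(uniq))
    return uniq, s


def weighted_feature(
    batch: SparseGLRLMBatch,
    gray_power: int,
    run_power: int,
    s: np.ndarray,
) -> np.ndarray:
    """Per-ROI value of sum i^a j^b P_ij / S for the given powers.

    The gray level is offset by the batch's ``level_offset`` before
    weighting.  A negative gray power with level 0 present raises
    :class:`DivisionDomainError` naming the first affected ROI.
    """
    roi, gray, run, uniq, inv = _roi_segments(batch)
    level = gray + batch.spec.level_offset
    if gray_power < 0 and np.any(level == 0):
        bad = roi[np.flatnonzero(level == 0)[0]]
        raise DivisionDomainError(
            f"gray level 0 in ROI {bad} under a 1/i^2 weight; "
            "use level_offset >= 1 or mask zero intensities"
        )
    weight = np.ones(len(batch.keys), dtype=np.float64)
    if gray_power:
        weight *= level.astype(np.float64) ** gray_power
    if run_power:
        weight *= run.astype(np.float64) ** run_power
    num = np.bincount(inv, weights=weight * batch.counts, minlength=len(uniq))
    return num / s


def gray_level_nonuniformity(batch: SparseGLRLMBatch, s: np.ndarray) -> np.ndarray:
    """GLN: drop the run length from each key (order is preserved), reduce
    the counts over (roi, gray) groups, square, segment-sum per ROI, / S."""
    key_ig = batch.keys // batch.spec.roi_length  # sorted already
    uniq_ig, inv_ig = np.unique(key_ig, return_inverse=True)
    inner = np.bincount(inv_ig, weights=batch.counts, minlength=len(uniq_ig))
    roi_of_ig = uniq_ig // batch.gl_resolution
    uniq_roi, inv_roi = np.unique(roi_of_ig, return_inverse=True)
    num = np.bincount(inv_roi, weights=inner**2, minlength=len(uniq_roi))
    return num / s


def run_length_nonuniformity(batch: SparseGLRLMBatch, s: np.ndarray) -> np.ndarray:
    """RLN: dropping the gray level breaks key order, so re-key by
    (roi, run), sort/group, reduce, square, segment-sum per ROI, / S."""
    roi, _, run, uniq_roi, _ = _roi_segments(batch)
    key_ir = roi * batch.spec.roi_length + (run - 1)
    uniq_ir, inv_ir = np.unique(key_ir, return_inverse=True)
    inner = np.bincount(inv_ir, weights=batch.counts, minlength=len(uniq_ir))
    roi_of_ir = uniq_ir // batch.spec.roi_length
    uniq2, inv2 = np.unique(roi_of_ir, return_inverse=True)
    num = np.bincount(inv2, weights=inner**2, minlength=len(uniq2))
    return num / s


def run_percentage(s: np.ndarray, spec: ROISpec) -> np.ndarray:
    """RP = S / N; equals 1 exactly when every run has length 1."""
    return s / spec.n_pixels


def extract_all_features(batch: SparseGLRLMBatch, spec: ROISpec | None = None) -> FeatureTable:
    """All 11 features for every ROI in the batch.

    The shared denominator S is computed once and reused by every
    feature, as every numerator divides by the same total run count.
    """
    spec = spec if spec is not None else batch.spec
    uniq, s = roi_denominators(batch)
    values: dict[str, np.ndarray] = {}
    for name, (a, b) in EMPHASIS_POWERS.items():
        values[name] = weighted_feature(batch, a, b, s)
    values["GLN"] = gray_level_nonuniformity(batch, s)
    values["RLN"] = run_length_nonuniformity(batch, s)
    values["RP"] = run_percentage(s, spec)
    return FeatureTable(
        roi_index=uniq,
        values=values,
        direction=batch.direction,
        level_offset=batch.spec.level_offset,
    )


def assemble_feature_maps(
    table: FeatureTable,
    image_shape: tuple[int, int],
    spec: ROISpec,
    log_transform: Iterable[str] = (),
) -> FeatureMaps:
    """Dense feature maps of shape (height - roi_height + 1, width - roi_width + 1).

    Cell (i, j) holds the feature of the ROI whose top-left pixel is
    (i, j); the table must cover every ROI position.  ``log_transform``
    names features to pass through a natural log — a display aid for
    features whose dynamic range hides texture, never a default.
    """
    height, width = image_shape
    n_rows = height - spec.roi_height + 1
    n_cols = width - spec.roi_width + 1
    rows = table.roi_index // width
    cols = table.roi_index % width
    expected = n_rows * n_cols
    if len(table.roi_index) != expected or np.any(rows >= n_rows) or np.any(cols >= n_cols):
        raise CompletenessError(
            f"feature table covers {len(table.roi_index)} ROIs, map needs {expected}"
        )
    log_set = frozenset(log_transform)
    unknown = log_set - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features for log transform: {sorted(unknown)}")
    maps: dict[str, np.ndarray] = {}
    for name in FEATURE_NAMES:
        grid = np.full((n_rows, n_cols), np.nan)
        grid[rows, cols] = table.values[name]
        if name in log_set:
            grid = np.log(grid)
        maps[name] = grid
    return FeatureMaps(maps=maps, direction=table.direction, log_transformed=log_set)
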