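# Methods

## Model

A gray level run along direction `(dx, dy)` is a maximal set of
consecutive, collinear pixels sharing one intensity; the GLRLM of an ROI
is the sparse 2-D histogram `P_ij` of (gray level `i`, run length `j`)
over all runs on all direction lines intersecting the ROI. The image
frame follows the usual imaging convention: `(0, 0)` is the top-left
pixel, x grows rightward (columns), y grows downward (rows), so the four
principal directions are `(1, 0)` for 0°, `(1, -1)` for 45°, `(0, -1)`
for 90° and `(-1, -1)` for 135°.

ROIs are every fully contained `roi_height × roi_width` window, slid one
pixel at a time. Windows that would overhang the image are not padded or
clipped — partial windows would break the per-ROI conservation law
`Σ_ij j·P_ij = N` (`N = roi_width × roi_height`), which the package
checks wherever a batch is produced. Each ROI is identified by
`roi_index = top_row × image_width + top_col`; these indices are sparse
in `[0, width × height)` and feature tables are keyed by them, with dense
maps assembled separately.

Runs are truncated at the ROI boundary: a whole-image run that crosses
the window edge contributes only its in-window pixels, and the next
in-window pixel on that line (if the run re-enters, which cannot happen
for straight lines) would start a new run. Reversing a direction vector
leaves the GLRLM unchanged (runs are sets of pixels), which is why four
directions rather than eight suffice; the test suite checks this
directly with negated vectors.

## Engines

**Per-ROI oracle.** For one window, the line starting pixels are those
whose predecessor along `(dx, dy)` falls outside the window; from each,
walk the line and tally maximal equal-intensity segments. Cost is
`O(num_ROIs × N)` overall. It exists to be obviously correct.

**Sequential engine.** The forward run length at every pixel of the
whole image is computed once per direction into the run length array
(RLArr), by the recurrence `RLArr[p] = 1 + RLArr[p + (dx, dy)]` when the
successor exists and matches, else 1 — filled by sweeping the image
opposite to the direction, anchored at the ending pixels (those with no
in-image successor). Per ROI, the engine reads `RLArr` at each line
starting pixel, takes `min(RLArr[p], pixels remaining in the window)`,
records the pair and jumps over the run.

**Batch engine.** All ROIs at once, in five array-primitive steps:
scatter every ROI pixel into one buffer (line by line, all first lines
of all ROIs, then all second lines, …) with the ROI identity folded into
the value as `key_IG = roi_index × G + gray`; collapse equal adjacent
keys (the block lengths are the run lengths); fold the run in as
`key_IGL = key_IG × roi_length + run − 1` with
`roi_length = max(roi_width, roi_height)`; sort; collapse equal keys
again, keeping counts. The sorted unique keys plus counts are the sparse
GLRLMs of every ROI. Two addressing details matter:

* The scatter address of the `(l+1)`-th pixel of the `(k+1)`-th line of
  the ROI with dense rank `q` is `N_k × num_ROIs + R_k × q + l`, where
  `R_k` is the line length and `N_k = Σ_{i<k} R_i`. The *dense rank* (the
  ROI's position in roi_index order) is used for addressing so the map is
  a bijection onto `[0, num_ROIs × N)`; the sparse `roi_index` would
  leave holes and overflow the buffer. The key itself carries the sparse
  index.
* The interleaved layout keeps lines of different ROIs separated by their
  distinct key tags, but when the image contains a single ROI its
  consecutive lines become adjacent in the buffer and a line-final pixel
  can merge with an equal line-initial pixel. The run-counting reduce
  therefore takes explicit head flags at every (line, ROI) segment start
  — the head-flag form of a segmented reduce-by-key. Without flags the
  reduce has plain adjacency semantics.

`roi_length` is a valid upper bound on any run length in the window for
all four directions (for the diagonals the attainable maximum is
`min(roi_width, roi_height)`, strictly smaller when the window is not
square; the larger bound simply leaves unused key space). Keys are
64-bit signed; `width × height × G × roi_length < 2^63` is asserted
before expansion and violated inputs fail loudly. The sort need not be
stable: after combining, all information lives inside the key.

## Features

All 11 features divide by the same denominator `S = Σ P_ij`, computed
once per ROI as a segment sum over the sorted batch. The eight
emphasis-type features are weights `i^a j^b` with `a, b ∈ {−2, 0, 2}`
applied entry-wise and segment-summed. GLN needs the inner sums
`Σ_j P_ij`: dropping the run length from each key
(`key ÷ roi_length`) preserves key order, so one adjacent reduce
suffices. RLN needs `Σ_i P_ij`: dropping the gray level destroys the
order, so the entries are re-keyed by (roi, run) and re-grouped (the
segmented-sort step) before reducing, squaring and summing.

`level_offset` (default 1) shifts intensities before gray-level
weighting: `i = intensity + offset`. Offset 0 applies the textbook
formulas to raw intensities and raises an explicit error when intensity
0 meets a `1/i²` weight, rather than silently producing infinities —
whether published feature maps on images containing 0 used an offset, a
mask or tolerated infinities is not determinable, so the choice is left
to the caller with a safe default. All feature arithmetic is double
precision.

Feature maps are dense grids of shape
`(height − roi_height + 1, width − roi_width + 1)` with cell `(i, j)`
holding the feature of the ROI anchored at top-left `(i, j)`
(center-anchoring is not provided). An optional natural-log transform
for LGRE/LRHGE/LRLGE/SRLGE exists purely for display — those features
crowd near 0 or grow with the square of the gray level, hiding texture
in linear renderings — and never alters the CSV values unless requested.

## Synthetic data and what tests show

The generators produce constant images (one run per line), two-color
checkerboards, periodic stripes, and seeded i.i.d. uniform noise (NumPy
PCG64 via `default_rng(seed)`, fixed so property tests reproduce across
machines). These exercise run-length structure exhaustively but share
none of real MRI's spatial correlation, noise or intensity
inhomogeneity; passing tests validate the combinatorics and the engine
contracts, not clinical feature values.

One caveat the degenerate patterns expose: on a two-color checkerboard,
axis-adjacent cells always differ so every 0°/90° run has length 1
(RP = SRE = LRE = 1 exactly), but `(row + col)` parity is invariant
under diagonal steps, so 45°/135° lines are constant-valued and carry
full-length runs. The unit-run closed forms hold only along the axes and
are tested there.

## Numerical and design choices

* Exactness over speed: engine-equivalence tests compare keys and counts
  with integer equality, no tolerance; feature tests compare the keyed
  reductions against a dense double-loop evaluation at 1e-12 relative.
* Randomized cross-engine checks use 32×48 images with G ∈ {8, 256} and
  square ROIs of sizes {2, 3, 5, 8, 12} (25 seeded images covering every
  combination), plus a derandomized hypothesis sweep over small shapes;
  sizes chosen to cover every layout branch (ROI wider/taller than long,
  single-ROI degenerate case) while keeping the pure-Python oracle the
  bottleneck at a few tens of seconds.
* CSV outputs use comma separation, LF endings and `%.17g` floats so
  round-trips are bit-exact and files diff cleanly; direction tags in
  filenames are degree labels (`d000` … `d135`).
* PNG feature images are min-max normalized 16-bit renderings for
  inspection only; CSV is normative.

## Limitations

2-D single images only: no 3-D volumes, no direction sets beyond the
four principal ones, no gray-level re-binning of inputs (images must
already lie in `[0, G)`), no DICOM/NIfTI readers, no incremental GLRLM
updates between overlapping ROIs, and no direction-averaged or
rotation-invariant feature aggregation.
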