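# glrlmtex

Sliding-window **gray level run length matrix (GLRLM)** texture features for
2-D grayscale images, with three mutually validating construction engines.

GLRLM features are a classical radiomics family: a *run* is a maximal set of
consecutive, collinear pixels of one gray level along a direction, and the
GLRLM of a region of interest (ROI) is the 2-D histogram `P_ij` counting runs
of gray level `i` and length `j`. This package slides a rectangular ROI one
pixel at a time over an image (every fully contained window), builds the
sparse GLRLM of every ROI for each of the four principal directions
(0°, 45°, 90°, 135°), and derives the 11 classical run-length features per
ROI — producing one dense feature map per feature and direction. Typical
inputs are texture-bearing biomedical images such as brain MRI slices.

## The features

With `S = Σ_ij P_ij` the ROI's total run count and `N` its pixel count
(`Σ_ij j·P_ij = N` always — every pixel belongs to exactly one run):

| Feature | Definition |
|---|---|
| SRE / LRE | `Σ P_ij / j² / S`, `Σ j² P_ij / S` |
| GLN | `Σ_i (Σ_j P_ij)² / S` |
| RLN | `Σ_j (Σ_i P_ij)² / S` |
| RP | `S / N` |
| LGRE / HGRE | `Σ P_ij / i² / S`, `Σ i² P_ij / S` |
| SRLGE, SRHGE, LRLGE, LRHGE | joint `i²`/`j²` weightings |

The gray level `i` entering the weights is `intensity + level_offset`
(default offset 1, so intensity 0 is representable under `1/i²`).

## The three engines

* **oracle** — per-ROI brute force: walk every direction line of every
  window. Simple, slow, trusted.
* **sequential** — compute a whole-image *run length array* once (forward
  run length at every pixel), then per ROI read it at each line start,
  truncate at the ROI boundary, and skip over runs.
* **batch** — build all ROIs' matrices at once by scattering every ROI
  pixel into one array keyed `roi_index ⊕ gray`, counting runs with an
  adjacent reduce-by-key, folding the run length into the key
  (`key ⊕ run`), then sort + reduce-by-key. The result is a pair of
  arrays: sorted unique 64-bit keys and their counts — the sparse GLRLMs
  of every ROI with no null entries stored.

The engines produce bit-identical sparse output; the test suite enforces
this exactly on randomized images.

## Worked example

The package embeds a 5×5 ROI with five distinct gray values
{0, 42, 113, 128, 255} and its four known directional GLRLMs:

```python
from glrlmtex import DIRECTIONS, ROISpec, glrlm_all_rois_batch, extract_all_features
from glrlmtex.fixtures import table1_fixture

fx = table1_fixture()
spec = ROISpec(roi_width=5, roi_height=5)
batch = glrlm_all_rois_batch(fx.image, spec, DIRECTIONS["H0"])
print(batch.entries_for_roi(0))
table = extract_all_features(batch, spec)
print(table.to_frame().round(6).iloc[0])
```

prints (horizontal direction):

```
{(0, 1): 4, (42, 1): 5, (113, 1): 3, (113, 2): 2, (128, 1): 3, (255, 1): 4, (255, 2): 1}
roi_index        0.000000
SRE              0.897727
LRE              1.409091
GLN              4.545455
RLN             16.818182
RP               0.880000
LGRE             0.181970
HGRE         20537.818182
SRLGE            0.181964
SRHGE        17417.545455
LRLGE            0.181993
LRHGE        33018.909091
Name: 0, dtype: float64
```

The 22 runs of the window (RP = 22/25 = 0.88) are mostly length 1
(SRE ≈ 0.90 close to 1), and HGRE is large because bright runs
(levels 114, 129, 256 after the +1 offset) dominate.

The same pipeline runs from a shell:

```sh
glrlmtex --image roi.csv --roi-width 5 --roi-height 5 \
         --directions 0,45,90,135 --engine batch --out out/
```

writing one GLRLM triplet CSV (`roi_index,gray_level,run_length,count`)
and 11 feature-map CSVs per direction.

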