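# Methods

This note records the mathematical conventions, models and numerical choices
implemented in `enteroquant`. Every statement here describes what the code
computes; nothing is an empirical claim about biological data.

## Image model and calibration

Images are 2D multi-channel rasters with an isotropic physical pixel size
(µm/px) taken from TIFF resolution metadata (ImageJ unit aware) or supplied
explicitly. A placeholder resolution of 1 pixel/unit with TIFF
`ResolutionUnit = none` and no ImageJ unit is treated as *uncalibrated* and
defaults to 1.0 µm/px with a warning. Anisotropic calibration is rejected.

All physical positions are pixel-center coordinates times the pixel size;
areas are pixel counts times the squared pixel size.

Before segmentation, images are resampled (bilinear; anti-aliased when
downsampling) to a species working resolution: 0.568 µm/px for mouse and rat,
0.9 µm/px for human tissue. Label maps are resampled nearest-neighbor so
labels never mix, and results are mapped back to the native grid.

## Baseline segmentation

The built-in detector targets bright, roughly round somata on a dark
background without trained weights:

1. percentile normalisation to [0, 1] (default 1st–99.8th percentile, clipped);
2. scale-normalised Laplacian-of-Gaussian responses, max-projected over a
   scale range (default σ = 3–8 µm, 6 steps);
3. local maxima of the response above a score threshold, at a minimum mutual
   distance (default 6 µm), restricted to a foreground mask;
4. marker-controlled watershed on the inverted smoothed intensity;
5. area filtering (default 40–1200 µm²) and per-label morphological opening.

The detector is deterministic. External segmentations (label TIFFs or ImageJ
ROI archives) can be imported instead.

## Edge-to-edge distances and proximal neighbors

The gap between two labelled cells is defined on pixel centers:

```
gap(i, j) = max(0, min over pixel pairs of ‖p_i − p_j‖ − 1 px) · pixel size
```

so 8-adjacent masks have gap 0 and one empty pixel column between two cells
is a 1-px gap. Gaps are computed exactly with a per-label cropped Euclidean
distance transform and returned for all pairs within a search radius
(default 4× the threshold).

A *proximal neighbor* of cell *i* is any cell *j* with gap(i, j) ≤ T
(inclusive), default T = 6.5 µm. Outputs are per-cell PN counts, the raw and
normalised count histogram, cross-type counts (restricting neighbors and/or
centers to marker-positive cells), and a neighbor-count map in which each
cell is painted with its count (background −1; stored in TIFF as count + 1).

## Local thickness and threshold estimation

Local thickness LT(p) of a binary mask is the diameter of the largest disc
that is fully contained in the mask (pixels as unit squares, the outside of
the raster counts as background) and covers the center of pixel p. Disc
centers are searched on the half-integer refined grid covering pixel corners,
centers and edge midpoints; the inscribed radius at each center is its exact
Euclidean distance to the nearest background. Consequences of this exact
convention: a one-pixel line has LT = 1, a 4×20 rectangle has LT = 4 across
its interior, and a rasterized disc of radius 10 px has maximum LT slightly
below 20 because rasterization removes boundary material.

`estimate_threshold` applies LT to the inter-cell space inside ganglion
outlines (`ganglia AND NOT cells`) and reports the mean ± sd thickness in µm
plus a suggested neighbor threshold: the mean rounded up to the next 0.5 µm.

## Ganglia

With no fiber/glial channel, ganglia are approximated by dilating every cell
by a disc of radius *r* (default: half the mean cell equivalent diameter) and
merging: two cells belong to one ganglion **exactly when** their gap is
strictly smaller than 2r, or their masks are 8-adjacent (so r = 0 gives
connected components). The mask is the exact Euclidean dilation; where pixel
sampling would disconnect a merged pair, a 1-px bridge along the
closest-point segment keeps each ganglion one 8-connected component.
Alternatively an external probability map is thresholded (default ≥ 0.8).

Cells are assigned to the ganglion of maximal pixel overlap; statistics are
per-ganglion areas and cell counts, their mean and median, and assigned cells
per mm² of ganglionic area.

## Markers

Two calling modes per marker: *label overlap* (positive when ≥ f of the
cell's pixels are covered by any subtype label, default f = 0.5, inclusive)
and *intensity* (positive when the cell's mean channel intensity reaches
median + k·MAD of the non-cell background, default k = 3). Boolean
combinations (AND/OR/XOR/A_NOT_B/B_NOT_A) report counts and percentages of
the total Hu count.

## Evaluation metrics

Instance detection uses a one-to-one assignment between ground-truth and
predicted objects maximising total IoU (Hungarian algorithm); a pair is a
true positive when its IoU ≥ τ. Because one assignment is thresholded at all
τ, the F1-over-τ curve is non-increasing by construction. Percentage count
error is 100·|N_gt − N_pred|/N_gt.

Partition metrics are computed over ground-truth foreground pixels, with
predicted background inside that foreground treated as one extra segment.
Adapted Rand error is 1 − F-score of distinct-unordered-pair counting
(Σn² − n). Variation of information is split into base-2 conditional
entropies: `voi_split = H(pred | gt)` grows when ground-truth objects are
fragmented, `voi_merge = H(gt | pred)` grows when they are merged; an
undivided two-object merge costs exactly 1 bit of `voi_merge`.

## Synthetic scene generator

Scenes are built from star-convex polygons: K ∈ [8, 16] radial knots with a
low-frequency harmonic perturbation of the radius (amplitudes 0.15 and 0.10
on the first two harmonics). The soma radius is a truncated normal whose
*realized* (post-truncation) moments are solved numerically so that the mean
rasterized polygon area hits the calibration target of 701.2 px² at the
default 0.568 µm/px working resolution (cv 0.13, truncated at ±2.5 σ).

Cells are placed in ganglion clusters: each new cell draws **one**
edge-to-edge gap from a truncated normal (default mean 6.32, sd 5.17,
truncation ≥ 0.5 µm — underlying parameters again solved so the realized
moments match the programmed ones) and is anchored to a random previous cell
at that gap, retrying only direction and shape on collision so the drawn gap
distribution is not biased by rejection. Ganglion centers sit on a jittered
grid with a minimum separation, guaranteeing feasibility deterministically.
Marker flags are independent Bernoulli draws per marker; channels are
rendered by painting per-cell intensities, Gaussian blur (1 µm) and Gaussian
noise (sd 0.7/SNR, default SNR 10).

Ground-truth ganglion outlines are the union of the ganglion's cells dilated
by half the programmed mean gap, with 1-px bridges where pixel sampling would
split a ganglion. The generator records programmed versus realized values of
every quantity (counts, gaps, areas, marker proportions).

`stretch_scene` re-renders the same specimen with all positions and outlines
scaled by (sx, sy) ≥ 1: polygon areas scale by sx·sy, density by 1/(sx·sy),
and the per-cell arrangement is unchanged — the oracle for stretch-robustness
tests of the proximal-neighbor statistics.

## Tile sampling

The field is partitioned into an equal grid of square-ish tiles of
approximately the requested area (rejected below 60 000 µm²). Each repeat
draws n tiles without replacement and estimates density as cells in the drawn
tiles over their total area; the experiment reports the per-repeat estimates,
their mean and sd, and the relative error against the full-field density.
Drawing all tiles recovers the full-field density exactly.

## Determinism

All stochastic components (generator, tile sampling) consume explicit integer
seeds through `numpy.random.default_rng`; pipeline reruns with the same
configuration produce byte-identical tables. Run configurations are TOML with
a `schema_version` and unknown keys rejected at every table; each run writes a
`run_log.json` with the resolved configuration, package version, seed and
stage timings.

## Limitations

- **Threshold estimation from expansion-derived ganglia is biased low.** When
  the ganglion outline is itself constructed by dilating the cells by radius
  r, the inter-cell space handed to the local-thickness estimator is clipped:
  the peripheral band has thickness ≈ r and channels between cells are only
  included where the gap is < 2r. On synthetic scenes with programmed mean
  gap 6.32 µm and r = 3.16 µm the estimator returns ≈ 2.9 µm. The estimator
  itself is validated on constructed scenes whose mask covers exactly the
  inter-cell space (a constant 6 µm slab is recovered within ±15%); the bias
  is a property of the mask construction, not of the estimator, and the
  corresponding acceptance test is intentionally left failing to document it.
  In practice the threshold should be estimated from independently delineated
  ganglia (e.g. a fiber/glial channel), not from outlines derived by dilating
  the very cells being measured.
- Pixel calibration must be isotropic; Z-stacks must be projected upstream.
- The baseline detector is a classical method intended for validation and
  fallback; for difficult tissue, import segmentations from trained models.
- Even with a full inter-cell mask, local thickness measures pocket widths
  between ≥3 cells, which exceed pairwise gaps in dense clusters; the
  estimate should be read as spacing, not as a pairwise gap mean.
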