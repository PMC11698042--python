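# enteroquant

Quantification of enteric neurons, ganglia and their spatial organisation in
2D wholemount fluorescence images.

## The problem

The enteric nervous system is studied in flat "wholemount" preparations of gut
tissue in which every neuron soma is labelled by the pan-neuronal marker
Hu (HuC/D), and subpopulations are labelled by additional neurochemical
markers (nNOS, calbindin, calretinin, …). Typical questions are: how many
neurons are there per ganglion and per mm², what fraction expresses each
marker, and how are the cells arranged — in particular, how many *proximal
neighbors* (cells whose edge-to-edge gap is at or below a physical threshold,
default 6.5 µm) each cell has. Manual counting is slow and subjective;
`enteroquant` provides a reproducible, scriptable pipeline:

- **imgio** — calibrated TIFF, ImageJ ROI-zip and cell-table CSV input/output;
- **scaling** — normalisation to the species working resolution
  (0.568 µm/px for mouse/rat, 0.9 µm/px for human);
- **segment** — a classical LoG-seed + watershed baseline detector for Hu
  somata, or import of label maps from external tools (StarDist, Cellpose, …);
- **ganglia** — ganglion outlines by cell-outline expansion (two cells merge
  exactly when their gap is smaller than twice the expansion radius) or from a
  probability map;
- **markers** — per-cell marker positivity by subtype-label overlap or by
  robust intensity thresholding, with boolean marker combinations;
- **spatial** — exact edge-to-edge distance graphs, proximal-neighbor counts
  and histograms, neighbor-count maps, and a local-thickness based estimator
  of the neighbor threshold from inter-cell spacing;
- **metrics** — instance-matching F1 over IoU thresholds, percentage count
  error, mask IoU, Adapted Rand error and split/merge variation of
  information, for validating segmentations against ground truth;
- **synth** — a calibrated synthetic scene generator with complete ground
  truth (labels, ganglia, marker flags, programmed gap distribution), used for
  all verification;
- **pipeline** — a TOML-configured end-to-end run (`quantify`) plus
  multi-image aggregation and a tile-sampling density experiment.

## Worked example

Generate a synthetic field with known ground truth, quantify it end-to-end,
and score the built-in segmentation against the ground truth:

```sh
enteroquant simulate --seed 7 --out scene --markers "calb=0.3,nnos=0.4"
# wrote scene with 54 cells in 3 ganglia to scene
```

`run.toml`:

```toml
schema_version = 1
seed = 7

[input]
image = "scene/image.tif"

[segmentation]
source = "baseline"

[ganglia]
mode = "expand"

[spatial]
threshold_um = 6.5

[[markers]]
name = "calb"
mode = "intensity"
channel = "calb"

[[markers]]
name = "nnos"
mode = "intensity"
channel = "nnos"

[output]
dir = "out"
```

```sh
enteroquant quantify --config run.toml
# 54 cells, 3 ganglia -> out
```

`out/summary.json` (abridged):

```json
{
  "n_cells_hu": 54,
  "n_ganglia": 3,
  "mean_cells_per_ganglion": 18.0,
  "ganglionic_area_um2": 39297.86,
  "neurons_per_mm2": 1374.12,
  "count_calb": 19,
  "percent_calb": 35.19,
  "count_nnos": 21,
  "percent_nnos": 38.89,
  "pn_2_raw": 17,
  "pn_3_raw": 17
}
```

The scene's ground truth has exactly 19 calbindin-positive and 21
nNOS-positive cells out of 54 (`scene/gt_flags.csv`), so the intensity-based
marker calls are exact here. Scoring the baseline segmentation against the
ground-truth labels:

```sh
enteroquant evaluate --gt scene/gt_cells.tif --pred out/labels.tif --out eval
```

```json
{
  "n_gt": 54,
  "n_pred": 54,
  "percent_count_error": 0.0,
  "f1_at_0.5": 1.0,
  "mask_iou": 0.7355,
  "adapted_rand_error": 0.000267,
  "voi_split": 0.00101,
  "voi_merge": 0.00102
}
```

All 54 cells are detected and matched one-to-one at IoU ≥ 0.5; the residual
boundary disagreement shows up only in the semantic mask IoU and the
near-zero partition metrics.

The same workflow runs on real calibrated TIFFs: point `[input] image` at a
multi-channel file (the Hu channel is selected by name), or import an
external segmentation with `[segmentation] source = "import"` and
`labels = "stardist_labels.tif"`.

## Reproduction

Run the test suite (unit, property and acceptance tests; ~30 s):

```sh
python -m pytest -o addopts= -p no:cacheprovider -q
```

Expected state: all tests pass except one acceptance test,
`test_criterion_6_threshold_recovery`, which is a documented known failure:
estimating the neighbor threshold from dilation-derived ganglion outlines is
structurally biased low (see the "Limitations" section of
`docs/methods.md`). It is kept failing rather than weakened.

Compute the acceptance targets (defaults plus the pooled synthetic mean cell
area over 20 seeded scenes; ~15 s):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which reports `t1 = 6.5` (µm neighbor threshold), `t2 = 0.568` and
`t3 = 0.9` (µm/px working resolutions), and at `--seed 1`
`t4 ≈ 689.7` px² mean ground-truth cell area over `n = 1051` pooled cells
(calibration target 701.2 px², −1.6%).

## Layout

```
src/enteroquant/   imgio, scaling, segment, ganglia, markers,
                   spatial, metrics, synth, pipeline, cli
tests/             pytest suite incl. brute-force oracles (tests/oracles.py)
                   and the acceptance suite (tests/test_acceptance.py)
scripts/           acceptance.py — acceptance target computation
docs/methods.md    methods note: models, conventions, numerical choices
```
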