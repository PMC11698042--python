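"""Cell segmentation: a classical multi-scale blob + watershed baseline, label
filtering, and construction of the per-cell measurement table.

The baseline detector targets the same objects as the deep-learning models the
wider workflow is designed around — bright-to-dim, roughly round neuron somata
on a dark background — without requiring trained weights: percentile
normalisation, scale-normalised Laplacian-of-Gaussian maxima as seeds, and a
marker-controlled watershed on the inverted smoothed intensity restricted to a
foreground mask.  Externally produced segmentations (e.g. StarDist or Cellpose
label maps, or ImageJ ROI archives) can be imported instead via
:mod:`enteroquant.imgio` and fed straight to :func:`build_cell_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max

from .imgio import LabelMap, CalibratedImage, compact_labels

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "normalize_image",
    "segment_cells_baseline",
    "filter_labels",
    "build_cell_table",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Baseline detector parameters (lengths in µm, areas in µm²).

    ``score_threshold`` plays the role of the tunable detection "probability":
    raising it keeps only stronger blob responses.  The default area bounds
    bracket the normalised training-set mean soma area (≈226 µm², i.e.
    701.2 px² at 0.568 µm/px) with a broad margin.
    """

    pmin: float = 1.0
    pmax: float = 99.8
    sigma_min_um: float = 3.0
    sigma_max_um: float = 8.0
    n_sigma: int = 6
    score_threshold: float = 0.05
    min_distance_um: float = 6.0
    fg_threshold: float = 0.15
    min_area_um2: float = 40.0
    max_area_um2: float = 1200.0
    smooth_radius_um: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.pmin < self.pmax <= 100):
            raise ValueError("need 0 <= pmin < pmax <= 100")
        if self.sigma_min_um > self.sigma_max_um:
            raise ValueError("sigma_min_um must be <= sigma_max_um")
        if self.min_area_um2 >= self.max_area_um2:
            raise ValueError("min_area_um2 must be < max_area_um2")
        if self.n_sigma < 1:
            raise ValueError("n_sigma must be >= 1")


def normalize_image(channel: np.ndarray, pmin: float = 1.0, pmax: float = 99.8) -> np.ndarray:
    """Percentile normalisation to [0, 1]: (I − q_pmin) / (q_pmax − q_pmin), clipped.

    A constant (or otherwise degenerate) raster normalises to all zeros with a
    warning instead of dividing by zero.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty raster")
    lo, hi = np.percentile(channel, [pmin, pmax])
    if hi == lo:
        logger.warning("degenerate intensity range (q%.6g == q%.6g); returning zeros", pmin, pmax)
        return np.zeros_like(channel)
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0)


def _log_response(norm: np.ndarray, sigmas_px: np.ndarray) -> np.ndarray:
    """Max projection of scale-normalised −σ²∇²G responses over the scale range."""
    stack = [
        -(s**2) * ndimage.gaussian_laplace(norm, sigma=s, mode="nearest")
        for s in sigmas_px
    ]
    return np.max(np.stack(stack), axis=0)


def segment_cells_baseline(
    channel: np.ndarray,
    pixel_size_um: float,
    params: SegmentationParams | None = None,
) -> LabelMap:
    """Segment round somata with LoG seeds + marker-controlled watershed.

    Deterministic for a fixed input.  An image with no foreground pixels
    yields an empty label map.
    """
    params = params or SegmentationParams()
    px = pixel_size_um
    norm = normalize_image(channel, params.pmin, params.pmax)
    fg = norm >= params.fg_threshold
    if not fg.any():
        return LabelMap(np.zeros(norm.shape, dtype=np.int32), px)

    sigmas_px = np.linspace(params.sigma_min_um / px, params.sigma_max_um / px, params.n_sigma)
    response = _log_response(norm, sigmas_px)
    min_dist_px = max(1, int(round(params.min_distance_um / px)))
    seeds = peak_local_max(
        response,
        min_distance=min_dist_px,
        threshold_abs=params.score_threshold,
        exclude_border=False,
        labels=fg.astype(np.int32),
    )
    if len(seeds) == 0:
        return LabelMap(np.zeros(norm.shape, dtype=np.int32), px)
    markers = np.zeros(norm.shape, dtype=np.int32)
    markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)

    smooth_sigma_px = max(params.smooth_radius_um / px, 0.5)
    surface = -ndimage.gaussian_filter(norm, smooth_sigma_px, mode="nearest")
    labels = segmentation.watershed(surface, markers=markers, mask=fg)

    labels = filter_labels(
        LabelMap(labels, px), params.min_area_um2, params.max_area_um2
    ).labels

    # per-label morphological opening to smooth ragged watershed boundaries
    if params.smooth_radius_um > 0:
        selem = morphology.disk(max(1, int(round(params.smooth_radius_um / px))))
        out = np.zeros_like(labels)
        for region in measure.regionprops(labels):
            r0, c0, r1, c1 = region.bbox
            pad = selem.shape[0] // 2 + 1
            r0p, c0p = max(0, r0 - pad), max(0, c0 - pad)
            r1p, c1p = min(labels.shape[0], r1 + pad), min(labels.shape[1], c1 + pad)
            crop = labels[r0p:r1p, c0p:c1p] == region.label
            opened = ndimage.binary_opening(crop, structure=selem)
            out[r0p:r1p, c0p:c1p][opened] = region.label
        labels = out
        labels = filter_labels(LabelMap(labels, px), params.min_area_um2, params.max_area_um2).labels

    return LabelMap(compact_labels(labels), px)


def filter_labels(
    labels: LabelMap,
    min_area_um2: float = 0.0,
    max_area_um2: float = np.inf,
    exclude_edge: bool = False,
) -> LabelMap:
    """Drop labels outside the area bounds (and optionally those on the border);
    survivors are compacted to 1..n.  Never increases the object count and is
    idempotent."""
    arr = labels.labels
    px2 = labels.pixel_size_um**2
    n_max = int(arr.max()) + 1
    areas = np.bincount(arr.ravel(), minlength=n_max) * px2
    keep = (areas >= min_area_um2) & (areas <= max_area_um2)
    keep[0] = False
    if exclude_edge:
        edge_ids = np.unique(
            np.concatenate([arr[0], arr[-1], arr[:, 0], arr[:, -1]])
        )
        keep[edge_ids[edge_ids > 0]] = False
    lut = np.zeros(n_max, dtype=arr.dtype)
    kept_ids = np.flatnonzero(keep)
    lut[kept_ids] = np.arange(1, len(kept_ids) + 1, dtype=arr.dtype)
    return LabelMap(lut[arr], labels.pixel_size_um)


def _outline_polygon(mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Outer boundary of a binary mask as (x, y) vertices (marching squares)."""
    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:  # degenerate single-pixel objects
        rr, cc = np.nonzero(mask)
        y, x = rr[0] + offset[0], cc[0] + offset[1]
        return np.array([[x - 0.5, y - 0.5], [x + 0.5, y - 0.5], [x + 0.5, y + 0.5], [x - 0.5, y + 0.5]], float)
    contour = max(contours, key=len)  # outer boundary is the longest
    ys = contour[:, 0] - 1 + offset[0]
    xs = contour[:, 1] - 1 + offset[1]
    return np.column_stack([xs, ys])


def build_cell_table(labels: LabelMap, image: CalibratedImage | None = None) -> pd.DataFrame:
    """Per-cell measurements: centroid (µm), area (µm²), outline polygon, and
    mean intensity per channel of ``image`` when given.

    Label ids are compacted to consecutive 1..n; centroids are pixel-center
    coordinates times the pixel size; polygons are (x, y) vertices in pixel
    units following the marching-squares convention.
    """
    if image is not None:
        if image.shape != labels.shape:
            raise ValueError("image and labels must share a shape")
        if not np.isclose(image.pixel_size_um, labels.pixel_size_um, rtol=1e-6):
            raise ValueError("image and labels must share a pixel size")
    arr = compact_labels(labels.labels)
    px = labels.pixel_size_um
    regions = measure.regionprops(arr)
    ids = [region.label for region in regions]
    channel_means = {}
    if image is not None and ids:
        for name in image.channel_names:
            channel_means[name] = ndimage.mean(image.channel(name), labels=arr, index=ids)
    rows = []
    for n, region in enumerate(regions):
        cy, cx = region.centroid
        r0, c0, _, _ = region.bbox
        poly = _outline_polygon(region.image, (r0, c0))
        row = {
            "id": region.label,
            "centroid_x_um": cx * px,
            "centroid_y_um": cy * px,
            "area_um2": region.area * px**2,
            "polygon": poly,
        }
        for name, means in channel_means.items():
            row[f"mean_int_{name}"] = float(means[n])
        rows.append(row)
    columns = ["id", "centroid_x_um", "centroid_y_um", "area_um2", "polygon"]
    if image is not None:
        columns += [f"mean_int_{n}" for n in image.channel_names]
    return pd.DataFrame(rows, columns=columns)
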