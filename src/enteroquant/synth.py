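"""Synthetic myenteric-wholemount scene generator with full ground truth.

Scenes emulate Hu-labelled 2D wholemount fields: clustered star-convex somata
grouped into ganglia, optional neurochemical-marker channels rendered only for
flagged cells, Gaussian optical blur and additive Gaussian noise.  Every draw
is governed by a single seed, and the programmed quantities (cell counts,
radii, inter-cell edge gaps, marker proportions) are stored so that each
analysis stage can be tested against known truth without any external data.

Calibration defaults mirror the normalised training conditions of the
reference workflow: pixel size 0.568 µm/px, mean soma area 701.2 px²
(sd 195.9 px²) at that pixel size, and inter-cell edge gaps with mean 6.32 µm
and sd 5.17 µm (truncated at 0.5 µm; the truncated distribution is
moment-matched so the realised mean/sd equal the programmed ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage, optimize, stats
from shapely import affinity
from shapely.geometry import Polygon
from shapely.ops import nearest_points
from skimage.draw import line as _draw_line

from .ganglia import GangliaMask
from .imgio import CalibratedImage, LabelMap

__all__ = ["SceneSpec", "SyntheticScene", "generate_scene", "stretch_scene", "truth_summary"]

# calibration constants of the normalised training conditions
_DEFAULT_PX = 0.568
_TARGET_AREA_PX2 = 701.2
_TARGET_AREA_SD_PX2 = 195.9
_GAP_MEAN_UM = 6.32
_GAP_SD_UM = 5.17


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic wholemount field."""

    shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = _DEFAULT_PX
    n_ganglia: int = 3
    cells_per_ganglion_mean: float = 18.0
    cells_per_ganglion_sd: float = 5.0
    cells_per_ganglion_min: int = 4
    target_area_um2: float = _TARGET_AREA_PX2 * _DEFAULT_PX**2
    target_area_sd_um2: float = _TARGET_AREA_SD_PX2 * _DEFAULT_PX**2
    gap_mean_um: float = _GAP_MEAN_UM
    gap_sd_um: float = _GAP_SD_UM
    gap_min_um: float = 0.5
    marker_proportions: dict[str, float] = field(default_factory=dict)
    snr: float = 10.0
    blur_sigma_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0 <= p <= 1) for p in self.marker_proportions.values()):
            raise ValueError("marker proportions must lie in [0, 1]")
        if self.n_ganglia < 1 or self.cells_per_ganglion_min < 1:
            raise ValueError("need at least one ganglion and one cell")
        if self.gap_min_um <= 0 or self.gap_mean_um <= self.gap_min_um:
            raise ValueError("gap distribution must sit above its truncation bound")


@dataclass
class SyntheticScene:
    """A generated field plus every ground-truth quantity used by the tests."""

    spec: SceneSpec
    image: CalibratedImage
    gt_cells: LabelMap
    gt_ganglia: GangliaMask
    gt_flags: pd.DataFrame  # one row per cell id, one bool column per marker
    polygons: list[Polygon]  # pixel units, index = cell id − 1
    cell_ganglion: np.ndarray  # programmed ganglion id per cell (1-based)
    hu_intensity: np.ndarray
    marker_intensity: dict[str, np.ndarray]
    anchor: np.ndarray  # index of the cell each cell was placed against (−1 for firsts)
    drawn_gaps_um: np.ndarray  # edge gap drawn for each anchored placement
    truth: dict

    @property
    def n_cells(self) -> int:
        return len(self.polygons)

    def subtype_labels(self, marker: str) -> LabelMap:
        """Ground-truth subtype segmentation: the cells flagged for ``marker``."""
        flags = self.gt_flags[marker].to_numpy()
        keep = np.zeros(self.n_cells + 1, dtype=self.gt_cells.labels.dtype)
        keep[1:][flags] = np.arange(1, self.n_cells + 1)[flags]
        return LabelMap(keep[self.gt_cells.labels], self.spec.pixel_size_um)


def _truncnorm_loc_scale(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Underlying (loc, scale) whose lower-truncated normal has the given moments."""

    def moments(params):
        loc, log_scale = params
        scale = math.exp(log_scale)
        a = (lower - loc) / scale
        d = stats.truncnorm(a, np.inf, loc=loc, scale=scale)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.fsolve(moments, x0=[mean, math.log(sd)], full_output=False)
    loc, scale = float(sol[0]), math.exp(float(sol[1]))
    return loc, scale


_PERT_AMPS = (0.15, 0.10)  # max multiplicative radius perturbation per harmonic (h = 2, 3)


def _shape_factor(K: int) -> float:
    """E[polygon area] / E[R²] for a K-gon with the harmonic radius perturbation."""
    dtheta = 2.0 * math.pi / K
    corr = 1.0 + sum((c**2 / 3.0) * 0.5 * math.cos((h + 2) * dtheta) for h, c in enumerate(_PERT_AMPS))
    return 0.5 * K * math.sin(dtheta) * corr


def _mean_radius_um(spec: SceneSpec) -> tuple[float, float]:
    """Calibrate the soma radius distribution to the target mean area.

    Radii are truncated-normal with cv 0.13 (symmetric ±2.5 sd truncation);
    solve E[area] = c̄ · E[R²] = target for the mean radius.
    """
    c_bar = float(np.mean([_shape_factor(k) for k in range(8, 17)]))
    cv = 0.13
    d = stats.truncnorm(-2.5, 2.5)
    var_factor = d.var()  # variance of the standardised truncated normal
    # E[R²] = mu² (1 + cv² · var_factor)
    mu = math.sqrt(spec.target_area_um2 / (c_bar * (1.0 + cv**2 * var_factor)))
    return mu, cv * mu


def _cell_polygon(rng: np.random.Generator, radius_px: float) -> Polygon:
    """Star-convex soma outline: K radial knots with low-frequency perturbation."""
    K = int(rng.integers(8, 17))
    theta = np.linspace(0.0, 2.0 * math.pi, K, endpoint=False)
    m = np.ones(K)
    for h, amp_max in zip((2, 3), _PERT_AMPS):
        amp = rng.uniform(0.0, amp_max)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        m += amp * np.cos(h * theta + phase)
    m = np.clip(m, 0.6, 1.4)
    r = radius_px * m
    return Polygon(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


def _place_cells(
    rng: np.random.Generator,
    spec: SceneSpec,
    centers_px: np.ndarray,
    counts: np.ndarray,
    gap_loc: float,
    gap_scale: float,
    radius_mu_um: float,
    radius_sd_um: float,
    cluster_r_px: float,
) -> tuple[list[Polygon], np.ndarray, np.ndarray, np.ndarray]:
    """Dart-throwing placement honoring drawn edge gaps inside each ganglion."""
    px = spec.pixel_size_um
    H, W = spec.shape
    gap_min_px = spec.gap_min_um / px
    polygons: list[Polygon] = []
    cell_gid: list[int] = []
    anchors: list[int] = []
    drawn_gaps: list[float] = []

    def draw_radius() -> float:
        r = rng.normal(radius_mu_um, radius_sd_um)
        lo, hi = radius_mu_um - 2.5 * radius_sd_um, radius_mu_um + 2.5 * radius_sd_um
        while not (lo <= r <= hi):
            r = rng.normal(radius_mu_um, radius_sd_um)
        return r / px  # px

    def draw_gap_px() -> float:
        a = (spec.gap_min_um - gap_loc) / gap_scale
        g = float(stats.truncnorm.rvs(a, np.inf, loc=gap_loc, scale=gap_scale, random_state=rng))
        return g / px

    def in_bounds(poly: Polygon) -> bool:
        minx, miny, maxx, maxy = poly.bounds
        return minx >= 2 and miny >= 2 and maxx <= W - 3 and maxy <= H - 3

    for gid, (center, n_cells) in enumerate(zip(centers_px, counts), start=1):
        placed_idx: list[int] = []
        # first cell sits at the ganglion center
        base = _cell_polygon(rng, draw_radius())
        first = affinity.translate(base, xoff=center[0], yoff=center[1])
        if not in_bounds(first):
            raise RuntimeError("ganglion placement too close to the border; enlarge shape or reduce n_ganglia")
        polygons.append(first)
        cell_gid.append(gid)
        anchors.append(-1)
        placed_idx.append(len(polygons) - 1)

        for _ in range(int(n_cells) - 1):
            ok = False
            # the gap is drawn once and kept across retries: rejecting and
            # redrawing would bias the realised gap distribution upward
            # (small gaps collide with third cells more often)
            g_px = draw_gap_px()
            for _attempt in range(300):
                anchor_i = int(rng.choice(placed_idx))
                anchor_poly = polygons[anchor_i]
                psi = rng.uniform(0.0, 2.0 * math.pi)
                direction = np.array([math.cos(psi), math.sin(psi)])
                cand_base = _cell_polygon(rng, draw_radius())
                acx, acy = anchor_poly.centroid.x, anchor_poly.centroid.y
                # start at sum of equivalent radii + gap and refine along the ray
                dist0 = (
                    math.sqrt(anchor_poly.area / math.pi)
                    + math.sqrt(cand_base.area / math.pi)
                    + g_px
                )
                pos = np.array([acx, acy]) + direction * dist0
                cand = affinity.translate(cand_base, xoff=pos[0], yoff=pos[1])
                for _refine in range(4):
                    d = anchor_poly.distance(cand)
                    if abs(d - g_px) < 0.05:
                        break
                    pos = pos + direction * (g_px - d)
                    cand = affinity.translate(cand_base, xoff=pos[0], yoff=pos[1])
                if not in_bounds(cand):
                    continue
                # keep clusters inside their reserved radius so programmed
                # ganglia can never run into one another
                if math.hypot(pos[0] - center[0], pos[1] - center[1]) > cluster_r_px:
                    continue
                if any(
                    cand.distance(polygons[k]) < gap_min_px for k in placed_idx if k != anchor_i
                ):
                    continue
                if anchor_poly.distance(cand) < gap_min_px:
                    continue
                polygons.append(cand)
                cell_gid.append(gid)
                anchors.append(anchor_i)
                drawn_gaps.append(anchor_poly.distance(cand) * px)
                placed_idx.append(len(polygons) - 1)
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    "cell placement failed: cells_per_ganglion too high for the gap distribution / shape"
                )
    return polygons, np.asarray(cell_gid), np.asarray(anchors), np.asarray(drawn_gaps)


def _rasterize_polygons(polygons: list[Polygon], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.int32)
    for i, poly in enumerate(polygons, start=1):
        minx, miny, maxx, maxy = poly.bounds
        c0, c1 = max(0, int(math.floor(minx))), min(shape[1] - 1, int(math.ceil(maxx)))
        r0, r1 = max(0, int(math.floor(miny))), min(shape[0] - 1, int(math.ceil(maxy)))
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        inside = shapely.intersects_xy(poly, cols.ravel().astype(float), rows.ravel().astype(float))
        view = out[r0 : r1 + 1, c0 : c1 + 1]
        sel = inside.reshape(rows.shape) & (view == 0)
        view[sel] = i
    return out


def _render_channel(
    labels: np.ndarray,
    intensities: np.ndarray,  # per label id, index 0 unused
    blur_sigma_px: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    img = intensities[labels]
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px, mode="nearest")
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img.astype(np.float32)


def _ganglia_truth(
    polygons: list[Polygon],
    cell_gid: np.ndarray,
    anchors: np.ndarray,
    labels: np.ndarray,
    expand_px: float,
    pixel_size_um: float,
) -> GangliaMask:
    """Union of cells dilated by half the mean gap, labelled by programmed ganglion.

    Anchored pairs whose dilations may not meet on the pixel grid get a 1-px
    bridge so every programmed ganglion stays one 8-connected component.
    """
    dist, (nr, nc) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    owner = labels[nr, nc]
    mask = dist <= expand_px
    gid_of = np.concatenate([[0], cell_gid]).astype(np.int32)
    out = np.zeros_like(labels, dtype=np.int32)
    out[mask] = gid_of[owner[mask]]

    anchored = np.flatnonzero(anchors >= 0)
    for k in anchored:
        a = anchors[k]
        pa, pb = nearest_points(polygons[a], polygons[k])
        gap_px = polygons[a].distance(polygons[k])
        if gap_px <= 2.0 * expand_px - 2.5:
            continue  # dilations provably meet on the grid
        rr, cc = _draw_line(
            int(round(pa.y)), int(round(pa.x)), int(round(pb.y)), int(round(pb.x))
        )
        inb = (rr >= 0) & (rr < out.shape[0]) & (cc >= 0) & (cc < out.shape[1])
        rr, cc = rr[inb], cc[inb]
        sel = out[rr, cc] == 0
        out[rr[sel], cc[sel]] = int(cell_gid[k])
    return GangliaMask(LabelMap(out, pixel_size_um), "imported")


def generate_scene(spec: SceneSpec | None = None, seed: int | None = None) -> SyntheticScene:
    """Generate a calibrated scene; deterministic for a fixed spec (and seed)."""
    spec = spec or SceneSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    H, W = spec.shape

    gap_loc, gap_scale = _truncnorm_loc_scale(spec.gap_mean_um, spec.gap_sd_um, spec.gap_min_um)
    radius_mu_um, radius_sd_um = _mean_radius_um(spec)

    counts = np.maximum(
        spec.cells_per_ganglion_min,
        np.round(rng.normal(spec.cells_per_ganglion_mean, spec.cells_per_ganglion_sd, spec.n_ganglia)).astype(int),
    )

    # ganglion centers by dart throwing with a separation guaranteeing disjoint
    # clusters; cluster radius from hexagonal packing at the programmed pitch
    # with 60% slack for the randomness of anchored placement
    pitch_um = 2.0 * radius_mu_um + spec.gap_mean_um
    cluster_r_um = 1.6 * math.sqrt(counts.max() * 0.866 * pitch_um**2 / math.pi) + pitch_um
    margin_px = (cluster_r_um + spec.gap_mean_um) / px + 4
    sep_px = (2.0 * cluster_r_um + 2.0 * spec.gap_mean_um + 10.0) / px
    if 2 * margin_px >= min(H, W):
        raise RuntimeError("shape too small for the requested ganglion size (n_ganglia / cells_per_ganglion)")
    # jittered grid of slots: slot pitch >= sep even after jitter, so any
    # subset of slots keeps the clusters disjoint
    ux, uy = W - 2 * margin_px, H - 2 * margin_px
    nx = int(ux // sep_px) + 1
    ny = int(uy // sep_px) + 1
    if nx * ny < spec.n_ganglia:
        raise RuntimeError("could not place all ganglia: n_ganglia too high for the field shape")
    sx = ux / (nx - 1) if nx > 1 else 0.0
    sy = uy / (ny - 1) if ny > 1 else 0.0
    jx = max(0.0, (sx - sep_px) / 2) if nx > 1 else ux / 2
    jy = max(0.0, (sy - sep_px) / 2) if ny > 1 else uy / 2
    slots = np.array(
        [
            (margin_px + (i * sx if nx > 1 else ux / 2), margin_px + (j * sy if ny > 1 else uy / 2))
            for i in range(nx)
            for j in range(ny)
        ]
    )
    chosen = rng.choice(len(slots), size=spec.n_ganglia, replace=False)
    centers = slots[chosen] + rng.uniform([-jx, -jy], [jx, jy], size=(spec.n_ganglia, 2))

    polygons, cell_gid, anchors, drawn_gaps = _place_cells(
        rng, spec, centers, counts, gap_loc, gap_scale, radius_mu_um, radius_sd_um,
        cluster_r_um / px,
    )
    n = len(polygons)
    labels = _rasterize_polygons(polygons, spec.shape)

    hu_int = np.concatenate([[0.0], rng.uniform(0.4, 1.0, n)])
    blur_px = spec.blur_sigma_um / px
    noise_sd = 0.7 / spec.snr if spec.snr > 0 else 0.0
    channels = [_render_channel(labels, hu_int, blur_px, noise_sd, rng)]
    names = ["hu"]

    flags = {}
    marker_int: dict[str, np.ndarray] = {}
    for marker, p in spec.marker_proportions.items():
        f = rng.random(n) < p
        flags[marker] = f
        amp = np.concatenate([[0.0], np.where(f, rng.uniform(0.4, 1.0, n), 0.0)])
        marker_int[marker] = amp
        channels.append(_render_channel(labels, amp, blur_px, noise_sd, rng))
        names.append(marker)

    gt_flags = pd.DataFrame(flags, index=pd.RangeIndex(1, n + 1, name="id"), dtype=bool)
    expand_px = (spec.gap_mean_um / 2.0) / px
    gt_ganglia = _ganglia_truth(polygons, cell_gid, anchors, labels, expand_px, px)

    # realised nearest edge gap per cell (within its programmed ganglion)
    nearest_gap = np.full(n, np.nan)
    for gid in np.unique(cell_gid):
        idx = np.flatnonzero(cell_gid == gid)
        for i in idx:
            others = [polygons[j] for j in idx if j != i]
            if others:
                nearest_gap[i] = min(polygons[i].distance(o) for o in others) * px

    areas_px2 = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    truth = {
        "n_cells": n,
        "cells_per_ganglion": {int(g): int(c) for g, c in zip(range(1, spec.n_ganglia + 1), counts)},
        "programmed_gap_mean_um": spec.gap_mean_um,
        "programmed_gap_sd_um": spec.gap_sd_um,
        "drawn_gap_mean_um": float(drawn_gaps.mean()) if len(drawn_gaps) else float("nan"),
        "drawn_gap_sd_um": float(drawn_gaps.std()) if len(drawn_gaps) else float("nan"),
        "realized_nearest_gap_mean_um": float(np.nanmean(nearest_gap)) if n > 1 else float("nan"),
        "programmed_marker_proportions": dict(spec.marker_proportions),
        "realized_marker_proportions": {m: float(f.mean()) for m, f in flags.items()},
        "target_area_px2": spec.target_area_um2 / px**2,
        "realized_mean_area_px2": float(areas_px2.mean()) if n else float("nan"),
    }

    image = CalibratedImage(np.stack(channels), px, names)
    return SyntheticScene(
        spec=spec,
        image=image,
        gt_cells=LabelMap(labels, px),
        gt_ganglia=gt_ganglia,
        gt_flags=gt_flags,
        polygons=polygons,
        cell_ganglion=cell_gid,
        hu_intensity=hu_int,
        marker_intensity=marker_int,
        anchor=anchors,
        drawn_gaps_um=drawn_gaps,
        truth=truth,
    )


def stretch_scene(scene: SyntheticScene, sx: float, sy: float) -> SyntheticScene:
    """Re-render the scene with cell positions and outlines scaled by (sx, sy).

    Emulates imaging the same specimen under tissue stretch: polygon areas
    scale by sx·sy, ganglionic density by 1/(sx·sy), while the spatial
    arrangement of cells is unchanged.  The raster grows to hold the stretched
    field; noise is redrawn deterministically from the scene seed and the
    stretch factors.
    """
    if sx < 1 or sy < 1:
        raise ValueError("stretch factors must be >= 1")
    spec = scene.spec
    px = spec.pixel_size_um
    H, W = spec.shape
    new_shape = (int(math.ceil(H * sy)), int(math.ceil(W * sx)))
    polys = [affinity.scale(p, xfact=sx, yfact=sy, origin=(0, 0)) for p in scene.polygons]
    labels = _rasterize_polygons(polys, new_shape)

    rng = np.random.default_rng([spec.seed, int(round(sx * 1e6)), int(round(sy * 1e6))])
    blur_px = spec.blur_sigma_um / px
    noise_sd = 0.7 / spec.snr if spec.snr > 0 else 0.0
    channels = [_render_channel(labels, scene.hu_intensity, blur_px, noise_sd, rng)]
    names = ["hu"]
    for marker, amp in scene.marker_intensity.items():
        channels.append(_render_channel(labels, amp, blur_px, noise_sd, rng))
        names.append(marker)

    iso = math.sqrt(sx * sy)
    expand_px = (spec.gap_mean_um * iso / 2.0) / px
    gt_ganglia = _ganglia_truth(polys, scene.cell_ganglion, scene.anchor, labels, expand_px, px)

    areas_px2 = np.bincount(labels.ravel(), minlength=len(polys) + 1)[1:]
    truth = dict(scene.truth)
    truth.update(
        {
            "stretch": (sx, sy),
            "programmed_gap_mean_um": spec.gap_mean_um * iso,
            "drawn_gap_mean_um": scene.truth["drawn_gap_mean_um"] * iso,
            "realized_mean_area_px2": float(areas_px2.mean()) if len(polys) else float("nan"),
        }
    )
    new_spec = replace(spec, shape=new_shape, gap_mean_um=spec.gap_mean_um * iso, gap_sd_um=spec.gap_sd_um * iso)
    return SyntheticScene(
        spec=new_spec,
        image=CalibratedImage(np.stack(channels), px, names),
        gt_cells=LabelMap(labels, px),
        gt_ganglia=gt_ganglia,
        gt_flags=scene.gt_flags.copy(),
        polygons=polys,
        cell_ganglion=scene.cell_ganglion.copy(),
        hu_intensity=scene.hu_intensity.copy(),
        marker_intensity={m: a.copy() for m, a in scene.marker_intensity.items()},
        anchor=scene.anchor.copy(),
        drawn_gaps_um=scene.drawn_gaps_um * iso,
        truth=truth,
    )


def truth_summary(scene: SyntheticScene) -> pd.DataFrame:
    """Programmed-versus-realised table: the oracle side of every recovery test."""
    t = scene.truth
    rows = [
        ("n_cells", sum(t["cells_per_ganglion"].values()), t["n_cells"]),
        ("mean_area_px2", t["target_area_px2"], t["realized_mean_area_px2"]),
        ("gap_mean_um", t["programmed_gap_mean_um"], t["drawn_gap_mean_um"]),
        ("gap_sd_um", t["programmed_gap_sd_um"], t["drawn_gap_sd_um"]),
        ("nearest_gap_mean_um", t["programmed_gap_mean_um"], t["realized_nearest_gap_mean_um"]),
    ]
    for m, p in t["programmed_marker_proportions"].items():
        rows.append((f"marker_{m}_proportion", p, t["realized_marker_proportions"][m]))
    return pd.DataFrame(rows, columns=["quantity", "programmed", "realized"])
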