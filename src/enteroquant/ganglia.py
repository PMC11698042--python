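"""Ganglia delineation and per-ganglion statistics.

Where no fiber/glial marker outlines the ganglia, they are approximated by
expanding every neuron outline by a user-chosen distance and merging the
expanded cells: two cells belong to the same ganglion exactly when their
edge-to-edge gap is smaller than twice the expansion radius (or when their
masks are pixel-adjacent, so expansion 0 reduces to connected components).
With the default expansion — half the mean cell equivalent diameter — this
realises the demarcation rule that separates two ganglia when the gap between
them exceeds the diameter of a single cell.

Alternatively an external ganglia probability map (e.g. from a semantic
segmentation network) is thresholded, by default at 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as _draw_line

from .imgio import LabelMap
from .spatial import SpatialConfig, edge_distance_graph

__all__ = [
    "GangliaMask",
    "GanglionStats",
    "default_expand_um",
    "ganglia_by_expansion",
    "ganglia_from_probability",
    "assign_cells",
    "ganglia_stats",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class GangliaMask:
    labels: LabelMap
    source: str  # expansion | probability | imported

    @property
    def n_ganglia(self) -> int:
        return self.labels.n_objects

    @property
    def ids(self) -> np.ndarray:
        return self.labels.ids


@dataclass
class GanglionStats:
    per_ganglion: pd.DataFrame  # columns: ganglion_id, area_um2, n_cells
    n_ganglia: int
    mean_cells_per_ganglion: float
    median_cells_per_ganglion: float
    total_area_um2: float
    neurons_per_mm2: float
    n_assigned: int = 0
    n_unassigned: int = 0


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def default_expand_um(cell_labels: LabelMap) -> float:
    """Half the mean cell equivalent diameter of the current image."""
    ids, areas_px = np.unique(cell_labels.labels, return_counts=True)
    areas_px = areas_px[ids > 0]
    if len(areas_px) == 0:
        return 0.0
    areas_um2 = areas_px * cell_labels.pixel_size_um**2
    eq_diam = 2.0 * np.sqrt(areas_um2 / np.pi)
    return float(np.mean(eq_diam)) / 2.0


def _adjacent_pairs(labels: np.ndarray) -> set[tuple[int, int]]:
    """Pairs of distinct labels whose masks are 8-adjacent."""
    pairs: set[tuple[int, int]] = set()
    H, W = labels.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0a, r1a = 0, H - dr
        r0b, r1b = dr, H
        if dc >= 0:
            c0a, c1a, c0b, c1b = 0, W - dc, dc, W
        else:
            c0a, c1a, c0b, c1b = -dc, W, 0, W + dc
        a = labels[r0a:r1a, c0a:c1a]
        b = labels[r0b:r1b, c0b:c1b]
        both = (a > 0) & (b > 0) & (a != b)
        if both.any():
            av, bv = a[both], b[both]
            lo = np.minimum(av, bv)
            hi = np.maximum(av, bv)
            pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def _closest_pixel_pair(labels: np.ndarray, i: int, j: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Pixel pair (one of each label) realising the minimum center distance."""
    sli = ndimage.find_objects((labels == i).astype(np.int8))[0]
    slj = ndimage.find_objects((labels == j).astype(np.int8))[0]
    r0 = min(sli[0].start, slj[0].start)
    r1 = max(sli[0].stop, slj[0].stop)
    c0 = min(sli[1].start, slj[1].start)
    c1 = max(sli[1].stop, slj[1].stop)
    crop = labels[r0:r1, c0:c1]
    dist, (ir, ic) = ndimage.distance_transform_edt(crop != i, return_indices=True)
    jj = np.argwhere(crop == j)
    d = dist[jj[:, 0], jj[:, 1]]
    k = int(np.argmin(d))
    pj = (int(jj[k, 0]), int(jj[k, 1]))
    pi = (int(ir[pj]), int(ic[pj]))
    return (pi[0] + r0, pi[1] + c0), (pj[0] + r0, pj[1] + c0)


def ganglia_by_expansion(cell_labels: LabelMap, expand_um: float | None = None) -> GangliaMask:
    """Approximate ganglia by dilating each cell by a disc of radius ``expand_um``.

    Cells are merged into one ganglion exactly when their edge-to-edge gap is
    strictly smaller than ``2 * expand_um`` (or when the undilated masks are
    8-adjacent, so ``expand_um = 0`` returns the connected components of the
    cell union).  The mask is the exact Euclidean dilation; where pixel
    sampling would disconnect two merged cells, a 1-px bridge along their
    closest-point segment keeps each ganglion a single 8-connected component.
    """
    labels = cell_labels.labels
    px = cell_labels.pixel_size_um
    if expand_um is None:
        expand_um = default_expand_um(cell_labels)
    if expand_um < 0:
        raise ValueError("expand_um must be >= 0")
    ids = [int(i) for i in np.unique(labels) if i > 0]
    if not ids:
        return GangliaMask(LabelMap(np.zeros_like(labels, dtype=np.int32), px), "expansion")

    # group cells: gap < 2*expand, or pixel adjacency
    uf = _UnionFind(ids)
    merged_pairs: list[tuple[int, int]] = []
    expand_px_bound = expand_um / px
    if len(ids) > 1:
        search = max(2.0 * expand_um, 2.0 * px)
        graph = edge_distance_graph(cell_labels, SpatialConfig(threshold_um=search, search_radius_um=search))
        for (i, j), gap in graph.gaps.items():
            if gap < 2.0 * expand_um:
                uf.union(i, j)
                # pixel sampling provably connects the two dilations when the
                # gap is well below 2*expand; only boundary cases need bridging
                if gap / px > 2.0 * expand_px_bound - 2.5:
                    merged_pairs.append((i, j))
        for i, j in _adjacent_pairs(labels):
            uf.union(i, j)

    # dilated mask and nearest-cell ownership
    expand_px = expand_um / px
    dist, (nr, nc) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    mask = dist <= expand_px
    owner = labels[nr, nc]
    group_of = {i: uf.find(i) for i in ids}
    lut = np.zeros(max(ids) + 1, dtype=np.int32)
    for i in ids:
        lut[i] = group_of[i]
    out = np.zeros_like(labels, dtype=np.int32)
    out[mask] = lut[owner[mask]]

    # bridge merged pairs whose dilations do not meet on the pixel grid
    for i, j in merged_pairs:
        pi, pj = _closest_pixel_pair(labels, i, j)
        rr, cc = _draw_line(pi[0], pi[1], pj[0], pj[1])
        out[rr, cc] = np.where(out[rr, cc] == 0, group_of[i], out[rr, cc])

    # compact group ids to 1..n while keeping one id per group
    return GangliaMask(LabelMap(out, px).compacted(), "expansion")


def ganglia_from_probability(
    prob_map: np.ndarray,
    threshold: float = 0.8,
    min_area_um2: float = 0.0,
    pixel_size_um: float = 1.0,
) -> GangliaMask:
    """Threshold an external ganglia probability map at ``threshold`` (>=)."""
    prob = np.asarray(prob_map, dtype=float)
    if prob.ndim != 2:
        raise ValueError("probability map must be 2D")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability values must lie in [0, 1]")
    binary = prob >= threshold
    lab, _ = ndimage.label(binary, structure=_EIGHT)
    if min_area_um2 > 0:
        ids, counts = np.unique(lab, return_counts=True)
        too_small = ids[(ids > 0) & (counts * pixel_size_um**2 < min_area_um2)]
        lab[np.isin(lab, too_small)] = 0
    return GangliaMask(LabelMap(lab, pixel_size_um).compacted(), "probability")


def assign_cells(cells: pd.DataFrame, cell_labels: LabelMap, ganglia: GangliaMask) -> pd.DataFrame:
    """Fill ``ganglion_id``: the ganglion with maximal pixel overlap per cell.

    Ties break toward the lowest ganglion id; cells with no overlap stay
    unassigned (pandas NA).  Returns a copy of the cell table.
    """
    if ganglia.labels.shape != cell_labels.shape:
        raise ValueError("cell labels and ganglia mask must share a shape")
    labels = cell_labels.labels
    glab = ganglia.labels.labels
    cells = cells.copy()
    assignment: dict[int, int] = {}
    fg = (labels > 0) & (glab > 0)
    if fg.any():
        keys, counts = np.unique(np.stack([labels[fg], glab[fg]]), axis=1, return_counts=True)
        # iterate in (cell, ganglion) order so ties keep the lowest ganglion id
        order = np.lexsort((keys[1], keys[0]))
        best: dict[int, tuple[int, int]] = {}
        for idx in order:
            cid, gid, n = int(keys[0, idx]), int(keys[1, idx]), int(counts[idx])
            if cid not in best or n > best[cid][1]:
                best[cid] = (gid, n)
        assignment = {cid: gid for cid, (gid, _) in best.items()}
    cells["ganglion_id"] = pd.array(
        [assignment.get(int(i)) for i in cells["id"]], dtype="Int64"
    )
    return cells


def ganglia_stats(cells: pd.DataFrame, ganglia: GangliaMask) -> GanglionStats:
    """Per-ganglion cell counts and areas plus the summary statistics.

    Density is assigned cells per mm² of total ganglionic area.  The median
    cells/ganglion is reported alongside the mean because single giant ganglia
    inflate the mean.
    """
    px = ganglia.labels.pixel_size_um
    ids, areas_px = np.unique(ganglia.labels.labels, return_counts=True)
    keep = ids > 0
    ids, areas_px = ids[keep], areas_px[keep]
    areas_um2 = areas_px * px**2

    if "ganglion_id" not in cells:
        raise ValueError("cells must be assigned first (assign_cells)")
    assigned = cells["ganglion_id"].dropna().astype(int)
    counts = assigned.value_counts()
    per = pd.DataFrame(
        {
            "ganglion_id": ids.astype(int),
            "area_um2": areas_um2,
            "n_cells": [int(counts.get(int(g), 0)) for g in ids],
        }
    )
    total_area = float(areas_um2.sum())
    n_assigned = int(per["n_cells"].sum())
    density = n_assigned / (total_area / 1e6) if total_area > 0 else 0.0
    return GanglionStats(
        per_ganglion=per,
        n_ganglia=len(ids),
        mean_cells_per_ganglion=float(per["n_cells"].mean()) if len(per) else 0.0,
        median_cells_per_ganglion=float(per["n_cells"].median()) if len(per) else 0.0,
        total_area_um2=total_area,
        neurons_per_mm2=float(density),
        n_assigned=n_assigned,
        n_unassigned=int(len(cells) - len(cells["ganglion_id"].dropna())),
    )
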